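# Methods

This note documents the models implemented in `ratiomics`, the design
of the synthetic cohort generators, and the numerical and design
choices made where the problem left them open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Discovery model

**Features.** Fasting metabolite concentrations are strictly positive
(µmol/l). Single-metabolite features are log-transformed and z-scaled
per metabolite (SD convention: denominator n − 1 everywhere). Ratio
features are log(m₁/m₂) = log m₁ − log m₂ for every unordered pair,
in the canonical order (i, j), i < j, of the input column order; each
ratio feature is z-scaled before regression, so effects are per SD of
the standardised log-ratio. Reversing a pair negates the feature and
leaves |z| and p invariant.

**Quality control.** A metabolite is retained when its missingness is
≤ `max_missing_frac` (default 0.3) and the fraction of values above
the detection floor is ≥ `min_detectable_frac` (default 0.5). The
published panel reports only the surviving count (143 of 188), so the
thresholds are explicit configuration with a full audit log rather
than fixed constants.

**Phenotypes.** The six clamp phenotypes are rank-based
inverse-normal transformed before analysis: Φ⁻¹((r − 0.5)/n) with
average ranks for ties. The (r − 0.5)/n offset was chosen over Blom's
(r − 3/8)/(n + 1/4) for simplicity; it is a documented constant, and
the difference is far below the sampling noise at n ≈ 130.

**Regression.** All discovery regressions are identity-link Gaussian
GEE with an exchangeable working correlation and the robust sandwich
variance, clustered by family (the family, not the twin pair, is the
independent unit). The solver iterates between moment updates of the
scale and intra-cluster correlation ρ (Pearson-residual cross-products
over pairs, denominator N_pairs − p) and a generalized-least-squares
coefficient update using the closed-form compound-symmetry inverse,
until the maximum absolute coefficient change is < 1e-8 (max 50
iterations; non-convergence raises with the last ρ). With all clusters
of size one the estimator is exactly OLS with HC0 standard errors,
which the tests assert to 1e-10; on clustered data it matches
`statsmodels.GEE` to 1e-8 (independent cross-check). p-values are
two-sided Wald-normal — ~54 clusters are treated as large-sample;
with few clusters sandwich-based Wald tests are known to be slightly
anti-conservative, which the null-calibration test bounds by binomial
Monte-Carlo error rather than hides.

The adjusted model is: phenotype ~ feature + age + sex + BMI +
glucose-tolerance status + insulin sensitivity index, where the
insulin sensitivity covariate is included for every phenotype except
itself. Complete-case analysis; dropped samples are counted in the
result. Timepoint contrasts stack two clamp stages long-format and
regress log-concentration on a stage indicator + age + sex + BMI with
the same GEE machinery; identical profiles at both stages are reported
as an exact null contrast rather than fed to the solver (the working
correlation would degenerate to 1).

## Screening

p_gain = min(p₁, p₂)/p_ratio with the single p-values floored at
2.2 × 10⁻¹⁶ (numerical saturation of reported p-values); the ratio's
p-value is never floored. All screening arithmetic runs on natural-log
p-values, so ratio p-values below ~1e-300 and p_gain values above
float overflow remain exact and comparable. The hit set is the
conjunction of the Bonferroni criterion (α over n_ratios ×
n_phenotypes) and p_gain > M/(2α), where M is the number of
metabolites entering ratios — not the number of ratios; this
convention reproduces the conventional critical value 10·M at
α = 0.05 (1350 for M = 135).

## Validation models

Standard fits are delegated to mature libraries behind the module
surface: OLS (statsmodels, classical SEs, t-based p), logistic
maximum likelihood (statsmodels, Wald SEs; separation raises), and
Cox partial likelihood with Efron tie handling (lifelines; Efron
rather than Breslow because moderate ties are expected with rounded
follow-up times). The Cox score test at β = 0 is computed in-package
and is algebraically the log-rank test for one binary covariate
without ties — asserted against `lifelines.statistics.logrank_test`.

OGTT surrogate indices use the standard literature definitions
(glucose mmol/l, insulin pmol/l, curves at 0/30/60/120 min):

* AUC by trapezoid over 0–120 min;
* insulinogenic index (I₃₀ − I₀)/(G₃₀ − G₀), undefined (NaN, flagged
  missing) when G₃₀ = G₀;
* corrected insulin response 100·I₃₀/(G₃₀·(G₃₀ − 3.89)), missing when
  G₃₀ ≤ 3.89 mmol/l;
* HOMA-IR = G₀ · (I₀/6.945)/22.5, the 6.945 pmol/l per µU/ml insulin
  conversion being a configurable module constant.

Fixed-effects meta-analysis pools with inverse-variance weights;
heterogeneity (Q, I²) is reported but never gates anything. Ratios
missing from a study are pooled over available studies with the study
count recorded; single-study rows are flagged.

## Prediction increment

Discrimination at a horizon (default 7 years, matching the average
follow-up the incident design emulates) is the Uno-style IPCW
cumulative/dynamic AUC (scikit-survival), whose weights collapse to 1
without censoring, making it equal to the Mann–Whitney binary AUC —
an exact oracle used in the tests. The NRI is the category-free
(continuous) version; ties contribute zero, samples censored before
the horizon are excluded (their status is unknown). Cross-validation
uses k = 10 outcome-stratified folds fixed by seed; held-out risk
scores are pooled before the pooled AUC, and per-fold AUCs are
reported where defined. A training fold without events triggers a
reshuffle or an error per configuration.

Adding both single metabolites to a Cox model spans the ratio
(log m₁ − log m₂ is a linear combination), so the singles-augmented
model matches the ratio-augmented apparent AUC up to estimation noise;
the ratio's advantage over the single-metabolite *pair* is parsimony,
while its advantage over each single alone is large and is what p_gain
measures.

## Synthetic cohorts

The generators emulate the study designs the pipeline targets, with
one planted signal pair.

* **Concentrations** are multivariate log-normal with block covariance
  by chemical class (default within-class correlation 0.4, between
  0.1): the problem statement gives no distributional form, and
  positivity plus right skew is typical of targeted metabolomics.
  The default panel mix mirrors a 135-metabolite quantified panel
  (12 acylcarnitines, 21 amino acids, 8 biogenic amines, 38 + 31
  phosphatidylcholines, 11 lysoPCs, 13 sphingomyelins, hexose).
* **Planted pair** (default Val and PC ae C32:2): their log-scale
  correlation is overridden to the component-dilution value (default
  0.6). With equal log-SDs, each single metabolite's correlation with
  the phenotype is √((1 − ρ)/2) ≈ 0.45 of the ratio's, so the expected
  squared z of the ratio exceeds either single's — the mechanism
  behind p_gain > 1, verified by simulation.
* **Clamp cohort**: 54 families with sizes 2–3 (mean ≈ 2.4, ~130
  subjects); the first two members of a multi-member family are twins
  (MZ with probability ½), the rest siblings. Each phenotype is
  β·z_ratio + covariate effects + family effect + noise with unit
  total residual variance; a shared family effect (variance 0.25)
  plus an extra shared MZ-pair effect (0.25) doubles the MZ
  correlation relative to DZ/siblings. Because the analysis
  quantile-normalises the phenotype, the recoverable coefficient is
  β/sd(phenotype) = β/√(β² + var_cov + 1); the generator stores this
  analysis-scale truth alongside the raw β. Timepoint dynamics are
  class-level multiplicative factors per stage (amino acids and
  acylcarnitines fall after glucose and further after GLP-1; hexose
  rises; four lysoPC species — the C14:0/C16:0/C16:1/C20:4 acyls —
  respond only to the arginine bolus), not mechanistic kinetics: the
  emulated results report direction and responder counts only.
* **OGTT cohort** (default n = 340): the log insulin AUC is built with
  unit variance and regression coefficient 0.455 on the standardised
  planted ratio, then distributed over a canonical response shape
  (relative insulin 1:5:4:2 at 0/30/60/120 min) with small per-point
  noise; glucose curves peak at 30–60 min and are floored at
  3 mmol/l.
* **Case-control cohort** (default 306 cases / 4619 controls): logistic
  outcome model with slope 0.97 per SD of the ratio; sampling continues
  until both quotas are met exactly (outcome-dependent sampling).
  Perfect separation by the planted ratio is detected and warned.
* **Incident cohort** (default n = 4277): exponential
  proportional-hazards event times with log-HR 0.45 per SD, baseline
  hazard 0.035/year (≈ 20% events by 7 years), staggered
  administrative censoring (uniform 0.7–1.3 × the 7-year follow-up)
  plus random exponential censoring calibrated to a 15% censoring
  fraction. Survival times are exponential by default; the baseline
  hazard of the emulated cohorts is unknown.

The planted effect sizes (0.999 SD on second-phase GSIS, 0.455 on log
AUC_insulin, logistic 0.97, log-HR 0.45) are the headline scenario of
the emulated study and are fixed defaults, not tuning knobs.

**What the generators do not emulate** — and hence what passing tests
do not show about real data: mechanistic beta-cell/insulin kinetics,
infusion pharmacokinetics, real cohorts' joint covariate
distributions, batch effects, missing-not-at-random patterns, and
measurement error correlated with concentration. The clamp phenotypes
are generated latently rather than computed from insulin curves, since
their exact computational definitions are not part of the emulated
main text.

## Problem sizes in the test suite

Stochastic properties are asserted at sizes chosen to give stable
Monte-Carlo verdicts at interactive runtimes: discovery-design
parameter recovery and null calibration use 300 replicates of the 54
family / ~130-subject design on an 8-metabolite panel (the recovery
property concerns one ratio, not the panel width); prediction
properties use 40 replicates of n = 4000 incident cohorts with ~20%
events; exhaustive-screen pipeline tests use a 10-metabolite panel
(270 ratio × phenotype GEE fits), with the 135-metabolite ratio count
asserted arithmetically (C(135,2) = 9045). Null-calibration bands are
±3 binomial SDs around the nominal α; coverage thresholds are ≥ 93%
of replicates within ±2 SE. All simulations are seeded; hypothesis
property tests run derandomised.

## Known limitations

* The exchangeable working correlation and Wald-normal inference are
  conventions; the emulated analysis does not state its choices, and
  no claim is made that they match.
* The p_gain critical value M/(2α) is one published convention for the
  procedure; it reproduces the printed 1350 but other derivations
  exist.
* Logistic/Cox "study-specific covariates" of the emulated cohorts are
  unknown and represented only by the shared covariate set.
* The GEE sandwich is slightly anti-conservative at ~54 clusters; no
  small-sample correction (e.g. Mancl–DeRouen) is applied.
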