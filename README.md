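# ratiomics

Pairwise metabolite-ratio biomarker discovery and epidemiological
validation, as a tested, reusable pipeline.

## The problem

Targeted metabolomics panels (Biocrates-style flow injection assays)
quantify on the order of 10² plasma metabolites — acylcarnitines, amino
acids, biogenic amines, phosphatidylcholines, lysophosphatidylcholines,
sphingolipids and hexose. Ratios between two metabolites can index flux
through a shared pathway and often associate with a phenotype far more
strongly than either metabolite alone, because biological and technical
variation common to both cancels in the ratio. `ratiomics` implements
the full discovery → validation workflow for such ratio biomarkers of
insulin secretion and type 2 diabetes risk:

1. **Discovery** on a family/twin cohort phenotyped with a modified 3 h
   hyperglycaemic clamp (glucose, GLP-1 and arginine stimulation;
   metabolites at t = 0, 30, 120, 180, 190 min): all C(M, 2) pairwise
   log-ratios log(m₁/m₂) are screened against six clamp phenotypes
   (first/second-phase GSIS, GLP-1-SIS, arginine-SIS, disposition
   index, insulin sensitivity index) with Gaussian GEE regressions
   (exchangeable working correlation, robust sandwich variance) that
   account for family clustering.
2. **Validation** of candidate ratios against OGTT surrogate indices
   (AUC_glucose, AUC_insulin, their ratio, insulinogenic index,
   corrected insulin response, HOMA-IR), prevalent-diabetes logistic
   models, incident-diabetes Cox models (Efron ties), inverse-variance
   fixed-effects meta-analysis across cohorts, and prediction-increment
   evaluation (time-dependent ROC AUC with IPCW, continuous NRI,
   cross-validation).

Because no individual-level cohort data of this kind are public, the
package ships first-class synthetic cohort generators with a *planted*
ratio effect: a pair (A, B) whose log-ratio carries the signal while a
positive log-scale correlation between A and B dilutes each component's
marginal association. Every downstream stage is exercised and tested
against this known ground truth.

## The statistics at the core

For a ratio with association p-value p_ratio and component metabolite
p-values p₁, p₂, the screening statistic is

    p_gain = min(p₁, p₂) / p_ratio ,

with the single p-values floored at 2.2 × 10⁻¹⁶ (and all internal
arithmetic in log space, so p-values below float underflow survive). A
ratio is reported when it passes both

* the Bonferroni threshold α / (n_ratios × n_phenotypes), and
* the critical p_gain value  M / (2α)  for M metabolites — 1350 for a
  135-metabolite panel at α = 0.05.

Fixed-effects pooling across k studies uses weights wᵢ = 1/SEᵢ²:
β̂ = Σwᵢβᵢ / Σwᵢ, SE = (Σwᵢ)^(−1/2), with Cochran's Q and I² reported
as diagnostics.

## Worked example

```python
>>> import ratiomics as rm
>>> rm.compute_p_gain(1.01e-27, 2.2e-16, 2.2e-16)   # ratio vs saturated singles
217821782178.21783                                   # ~2.2e11: ratio >> singles
>>> rm.p_gain_critical(alpha=0.05, n_metabolites=135)
1350.0
>>> m = rm.fixed_effects_meta([1.022, 0.609, 1.100], [0.283, 0.180, 0.110])
>>> round(m.beta, 3), round(m.se, 3)
(0.972, 0.089)                    # pooled log-odds per SD of the ratio
>>> import numpy as np; round(float(np.exp(m.beta)), 2)
2.64                              # odds ratio of prevalent disease per SD
```

The numbered drivers under `analysis/` run the full pipeline on
synthetic cohorts (a 40-metabolite demonstration panel; the machinery
is size-independent). `python analysis/02_discovery_screen.py` prints,
among 4680 ratio × phenotype tests:

```
ratio screen: 4680 ratio x phenotype tests, 12 pass both Bonferroni and p_gain criteria
  Val_PC ae C32:2  second_phase_gsis  beta +0.633 (SE 0.070)  p 1.46e-19  p_gain 2.65e+15
```

— the planted Val / PC ae C32:2 ratio is the top hit, with a p_gain far
above the critical value because both single metabolites are nearly
null. `python analysis/04_prediction_increment.py` then shows the
prediction increment on an incident cohort (n = 4277, 879 events by
7 years):

```
base model AUC(7y)            0.530 (cross-validated 0.505)
+ Val/PC ae C32:2 ratio       0.637 (cross-validated 0.627), delta +0.106
continuous NRI (ratio model)  0.334 (events +0.147, non-events +0.187)
```

## Command line

A thin CLI wraps the same library calls:

```bash
ratiomics simulate --seed 1 --out scratch/cohort
ratiomics discover --seed 1 --out results/discovery
ratiomics validate --seed 1 --candidates "Val_PC ae C32:2" --out results/validation
```

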