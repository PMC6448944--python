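"""Synthetic cohort generators with planted ground-truth effects.

Every cohort type consumed by the discovery/validation pipeline can be
simulated here: a family-clustered hyperglycaemic-clamp cohort with
five-timepoint metabolite dynamics and six insulin-secretion phenotypes,
an OGTT cohort with glucose/insulin curves, a prevalent-diabetes
case-control cohort, and an incident-diabetes cohort with censored
event times.

The central construction is the *planted ratio*: one metabolite pair
(A, B) whose log-ratio carries the phenotype signal while a positive
A-B log-scale correlation ("component dilution") makes each single
metabolite a weaker predictor than the ratio — the mechanism that
produces p_gain > 1 downstream.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import ARGININE_RESPONSIVE_LYSOPC, PanelSpec

CLAMP_TIMEPOINTS = (0, 30, 120, 180, 190)
CLAMP_PHENOTYPES = (
    "first_phase_gsis",
    "second_phase_gsis",
    "glp1_sis",
    "arginine_sis",
    "disposition_index",
    "insulin_sensitivity_index",
)
OGTT_TIMEPOINTS = (0, 30, 60, 120)

# Multiplicative concentration shifts relative to fasting (t = 0), by class.
# Amino acids and acylcarnitines fall after glucose and further after GLP-1;
# most lipids move less; hexose rises under the clamp; a lysoPC subset
# responds only to the arginine bolus (applied separately below).
DEFAULT_CLAMP_DYNAMICS: dict[str, dict[int, float]] = {
    "amino acid": {30: 0.90, 120: 0.80, 180: 0.70, 190: 0.72},
    "acylcarnitine": {30: 0.92, 120: 0.82, 180: 0.72, 190: 0.74},
    "biogenic amine": {30: 0.93, 120: 0.85, 180: 0.78, 190: 0.78},
    "phosphatidylcholine-aa": {30: 0.96, 120: 0.90, 180: 0.87, 190: 0.86},
    "phosphatidylcholine-ae": {30: 0.96, 120: 0.90, 180: 0.87, 190: 0.86},
    "sphingolipid": {30: 0.96, 120: 0.90, 180: 0.90, 190: 0.90},
    "lysophosphatidylcholine": {30: 1.0, 120: 1.0, 180: 1.0, 190: 1.0},
    "sugar": {30: 1.35, 120: 1.35, 180: 1.30, 190: 1.30},
}
ARGININE_LYSOPC_FACTOR = 1.20  # t=190 only, for ARGININE_RESPONSIVE_LYSOPC


@dataclass
class EffectSpec:
    """Planted ground truth shared by all cohort simulators.

    Effect sizes are per SD of the standardised log-ratio log(A/B).
    Defaults are the headline scenario of the pipeline: a Val / PC ae C32:2
    style pair with a strong ratio signal diluted in its components.
    """

    pair: tuple[str, str] = ("Val", "PC ae C32:2")
    component_dilution_corr: float = 0.6
    clamp_effects: dict[str, float] = field(
        default_factory=lambda: {"second_phase_gsis": 0.999}
    )
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.10, "sex": -0.10, "bmi": 0.10}
    )
    ogtt_effect: float = 0.455
    logistic_beta: float = 0.97
    logistic_intercept: float = -2.75
    log_hr: float = 0.45
    baseline_hazard: float = 0.035  # events per person-year at zero predictors
    censoring_rate: float = 0.15  # P(random censoring before follow-up end)

    def __post_init__(self) -> None:
        if not (0 < self.component_dilution_corr < 1):
            raise ValueError("component_dilution_corr must be in (0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")


@dataclass
class CohortBundle:
    """One simulated cohort: metabolites, covariates, clustering, outcomes."""

    metabolites: pd.DataFrame  # fasting values, samples x metabolites, > 0
    covariates: pd.DataFrame
    family_id: pd.Series
    zygosity: pd.Series
    truth: dict
    phenotypes: pd.DataFrame | None = None  # clamp six-vector
    longitudinal: dict[int, pd.DataFrame] | None = None  # minute -> matrix
    ogtt_glucose: pd.DataFrame | None = None  # mmol/l at OGTT_TIMEPOINTS
    ogtt_insulin: pd.DataFrame | None = None  # pmol/l at OGTT_TIMEPOINTS
    outcome: pd.DataFrame | None = None  # 'status' or ('time', 'event')

    def __post_init__(self) -> None:
        if (self.metabolites.values <= 0).any():
            raise ValueError("metabolite concentrations must be positive")
        if self.outcome is not None and "event" in self.outcome:
            if (self.outcome["time"] <= 0).any():
                raise ValueError("event times must be positive")
            if not set(self.outcome["event"].unique()) <= {0, 1}:
                raise ValueError("event indicator must be 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.metabolites)

    def write(self, outdir: str | Path) -> None:
        """Persist as plain CSV/JSON (10 significant digits)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        if self.longitudinal is not None:
            for t, mat in self.longitudinal.items():
                mat.to_csv(outdir / f"metabolites_t{t}.csv", float_format=fmt,
                           index_label="sample_id")
        else:
            self.metabolites.to_csv(outdir / "metabolites.csv", float_format=fmt,
                                    index_label="sample_id")
        cov = self.covariates.copy()
        cov["family_id"] = self.family_id
        cov["zygosity"] = self.zygosity
        cov.to_csv(outdir / "covariates.csv", float_format=fmt,
                   index_label="sample_id")
        pheno_parts = [
            df for df in (self.phenotypes, self.ogtt_glucose, self.ogtt_insulin,
                          self.outcome)
            if df is not None
        ]
        if pheno_parts:
            pd.concat(pheno_parts, axis=1).to_csv(
                outdir / "phenotypes.csv", float_format=fmt, index_label="sample_id"
            )
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=str, sort_keys=True)


def _dilute_panel(panel: PanelSpec, effects: EffectSpec) -> PanelSpec:
    """Return a panel with the planted pair's correlation overridden."""
    a, b = effects.pair
    for m in (a, b):
        if m not in panel.names:
            raise ValueError(f"planted metabolite {m!r} not in panel")
    return dataclasses.replace(
        panel,
        pair_corr_overrides={
            **panel.pair_corr_overrides,
            (a, b): effects.component_dilution_corr,
        },
    )


def _true_zratio(panel: PanelSpec, effects: EffectSpec,
                 log_values: np.ndarray) -> np.ndarray:
    """Planted log-ratio standardised by its *true* moments."""
    a, b = effects.pair
    ia, ib = panel.names.index(a), panel.names.index(b)
    cov = panel.log_covariance()
    mu = panel.mean_vector()
    lr = log_values[:, ia] - log_values[:, ib]
    var = cov[ia, ia] + cov[ib, ib] - 2 * cov[ia, ib]
    return (lr - (mu[ia] - mu[ib])) / np.sqrt(var)


def _draw_log_metabolites(panel: PanelSpec, n: int,
                          rng: np.random.Generator) -> np.ndarray:
    return rng.multivariate_normal(
        panel.mean_vector(), panel.log_covariance(), size=n, method="cholesky"
    )


def _draw_covariates(n: int, rng: np.random.Generator,
                     age_loc: float = 32.0, bmi_loc: float = 24.5,
                     igt_rate: float = 0.046,
                     lipid_rate: float = 0.05) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": np.clip(rng.normal(age_loc, 8.0, n), 18, 80),
            "sex": rng.integers(0, 2, n),
            "bmi": np.clip(rng.normal(bmi_loc, 3.0, n), 16, 45),
            "glucose_tolerance": (rng.random(n) < igt_rate).astype(int),
            "lipid_lowering": (rng.random(n) < lipid_rate).astype(int),
        }
    )


def _covariate_signal(cov: pd.DataFrame, effects: EffectSpec) -> np.ndarray:
    """Linear covariate contribution on standardised scales."""
    e = effects.covariate_effects
    z_age = (cov["age"].to_numpy() - cov["age"].mean()) / cov["age"].std(ddof=1)
    z_bmi = (cov["bmi"].to_numpy() - cov["bmi"].mean()) / cov["bmi"].std(ddof=1)
    sex = cov["sex"].to_numpy() - 0.5
    return (e.get("age", 0.0) * z_age + e.get("sex", 0.0) * sex
            + e.get("bmi", 0.0) * z_bmi)


def _covariate_signal_var(effects: EffectSpec) -> float:
    e = effects.covariate_effects
    return e.get("age", 0.0) ** 2 + 0.25 * e.get("sex", 0.0) ** 2 + e.get("bmi", 0.0) ** 2


def _sample_ids(n: int, prefix: str = "S") -> pd.Index:
    return pd.Index([f"{prefix}{i:05d}" for i in range(n)], name="sample_id")


def simulate_clamp_cohort(
    panel: PanelSpec,
    effects: EffectSpec,
    n_families: int = 54,
    family_size_law=None,
    seed: int = 0,
    dynamics: dict[str, dict[int, float]] | None = None,
    familial_icc: float = 0.25,
    mz_extra_icc: float = 0.25,
    timepoint_noise_sd: float = 0.05,
) -> CohortBundle:
    """Simulate a family/twin clamp cohort with five metabolite timepoints.

    Families are drawn from ``family_size_law`` (a callable rng -> size;
    default sizes 2 or 3 with mean ~2.4, matching ~130 subjects from 54
    families). The first two members of each multi-member family are twins
    (MZ with probability 1/2), remaining members non-twin siblings. Each
    clamp phenotype is a linear function of the planted standardised
    log-ratio, covariates, a shared family effect (plus an extra shared
    effect for MZ pairs, doubling their intra-pair correlation) and noise
    with unit total residual variance.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    if family_size_law is None:
        def family_size_law(r):  # mean 2.4 -> ~130 subjects at 54 families
            return 2 + (r.random() < 0.4)
    sizes = [int(family_size_law(rng)) for _ in range(n_families)]
    if any(s <= 0 for s in sizes):
        raise ValueError("family_size_law produced a family of size 0")
    n = int(np.sum(sizes))

    family_id, zygosity = [], []
    mz_family = []
    for f, s in enumerate(sizes):
        fam = f"F{f:03d}"
        is_mz = s >= 2 and rng.random() < 0.5
        mz_family.append(is_mz)
        for k in range(s):
            family_id.append(fam)
            if s >= 2 and k < 2:
                zygosity.append("MZ" if is_mz else "DZ")
            else:
                zygosity.append("sib" if s >= 2 else "none")
    ids = _sample_ids(n)
    family_id = pd.Series(family_id, index=ids, name="family_id")
    zygosity = pd.Series(zygosity, index=ids, name="zygosity")

    panel = _dilute_panel(panel, effects)
    log_base = _draw_log_metabolites(panel, n, rng)
    covariates = _draw_covariates(n, rng)
    covariates.index = ids

    zr = _true_zratio(panel, effects, log_base)
    cov_sig = _covariate_signal(covariates, effects)

    # Family / zygosity random effects with unit total residual variance.
    if not (0 <= familial_icc < 1 and 0 <= familial_icc + mz_extra_icc < 1):
        raise ValueError("invalid intraclass correlation configuration")
    fam_codes = family_id.factorize()[0]
    is_mz_member = np.array(
        [zygosity.iloc[i] == "MZ" for i in range(n)]
    )
    resid_var = np.where(is_mz_member,
                         1.0 - familial_icc - mz_extra_icc,
                         1.0 - familial_icc)

    pheno = {}
    for name in CLAMP_PHENOTYPES:
        b_fam = rng.normal(0.0, np.sqrt(familial_icc), n_families)[fam_codes]
        mz_pair = rng.normal(0.0, np.sqrt(mz_extra_icc), n_families)[fam_codes]
        b_fam = b_fam + np.where(is_mz_member, mz_pair, 0.0)
        eps = rng.normal(0.0, np.sqrt(resid_var))
        beta = effects.clamp_effects.get(name, 0.0)
        pheno[name] = beta * zr + cov_sig + b_fam + eps
    phenotypes = pd.DataFrame(pheno, index=ids)

    # Five-timepoint dynamics: class-level multiplicative factors + noise.
    dyn = DEFAULT_CLAMP_DYNAMICS if dynamics is None else dynamics
    class_arr = np.asarray(panel.classes)
    longitudinal: dict[int, pd.DataFrame] = {}
    base = np.exp(log_base)
    for t in CLAMP_TIMEPOINTS:
        if t == 0:
            vals = base
        else:
            factors = np.array([dyn[c].get(t, 1.0) for c in class_arr])
            arg_mask = np.isin(np.asarray(panel.names), ARGININE_RESPONSIVE_LYSOPC)
            if t == 190:
                factors = np.where(arg_mask, ARGININE_LYSOPC_FACTOR, factors)
            noise = np.exp(rng.normal(0.0, timepoint_noise_sd, size=base.shape))
            vals = base * factors[None, :] * noise
        longitudinal[t] = pd.DataFrame(vals, index=ids, columns=panel.names)

    # Effects are planted per SD of the unit-variance residual scale; the
    # analysis standardises (quantile-normalises) the phenotype, so the
    # recoverable coefficient on that scale is beta / sd(phenotype).
    var_cov = _covariate_signal_var(effects)
    clamp_effects_std = {
        p: b / np.sqrt(b * b + var_cov + 1.0)
        for p, b in effects.clamp_effects.items()
    }
    truth = {
        "kind": "clamp",
        "pair": list(effects.pair),
        "component_dilution_corr": effects.component_dilution_corr,
        "clamp_effects": effects.clamp_effects,
        "clamp_effects_std": clamp_effects_std,
        "familial_icc": familial_icc,
        "mz_extra_icc": mz_extra_icc,
        "n_families": n_families,
        "seed": seed,
    }
    return CohortBundle(
        metabolites=longitudinal[0],
        covariates=covariates,
        family_id=family_id,
        zygosity=zygosity,
        phenotypes=phenotypes,
        longitudinal=longitudinal,
        truth=truth,
    )


# Relative insulin response shape over the OGTT (t = 0, 30, 60, 120 min).
_OGTT_INSULIN_SHAPE = np.array([1.0, 5.0, 4.0, 2.0])


def simulate_ogtt_cohort(
    panel: PanelSpec, effects: EffectSpec, n: int = 340, seed: int = 0
) -> CohortBundle:
    """Simulate an OGTT cohort with glucose/insulin curves tied to the ratio.

    The total insulin output (log AUC over 0-120 min) is constructed with
    unit variance and regression coefficient ``effects.ogtt_effect`` on the
    standardised planted log-ratio, so the downstream linear model recovers
    the planted standardised effect. Glucose in mmol/l (floored at 3),
    insulin in pmol/l.
    """
    if n < 10:
        raise ValueError("OGTT cohort needs n >= 10 for index estimation")
    rng = np.random.default_rng(seed)
    panel = _dilute_panel(panel, effects)
    log_base = _draw_log_metabolites(panel, n, rng)
    ids = _sample_ids(n)
    covariates = _draw_covariates(n, rng, age_loc=55.0, bmi_loc=26.0,
                                  igt_rate=0.15, lipid_rate=0.15)
    covariates.index = ids

    zr = _true_zratio(panel, effects, log_base)
    cov_sig = _covariate_signal(covariates, effects)
    resid = 1.0 - effects.ogtt_effect**2 - _covariate_signal_var(effects)
    if resid <= 0:
        raise ValueError("ogtt_effect and covariate effects imply variance > 1")
    x = effects.ogtt_effect * zr + cov_sig + rng.normal(0.0, np.sqrt(resid), n)

    # Insulin: distribute a log-normal AUC over the canonical response shape.
    shape_auc = np.trapezoid(_OGTT_INSULIN_SHAPE, OGTT_TIMEPOINTS)
    log_auc = np.log(30000.0) + 0.45 * x  # pmol/l x min scale
    insulin = pd.DataFrame(
        np.exp(log_auc)[:, None] / shape_auc * _OGTT_INSULIN_SHAPE[None, :]
        * np.exp(rng.normal(0.0, 0.03, (n, 4))),
        index=ids, columns=[f"insulin_{t}" for t in OGTT_TIMEPOINTS],
    )
    g0 = rng.normal(5.0, 0.4, n)
    glucose = pd.DataFrame(
        np.clip(
            np.column_stack([
                g0,
                g0 + rng.normal(2.5, 0.8, n) + 0.15 * x,
                g0 + rng.normal(1.8, 0.9, n) + 0.15 * x,
                g0 + rng.normal(0.6, 0.7, n) + 0.10 * x,
            ]),
            3.0, None,
        ),
        index=ids, columns=[f"glucose_{t}" for t in OGTT_TIMEPOINTS],
    )
    truth = {
        "kind": "ogtt",
        "pair": list(effects.pair),
        "ogtt_effect": effects.ogtt_effect,
        "component_dilution_corr": effects.component_dilution_corr,
        "seed": seed,
    }
    return CohortBundle(
        metabolites=pd.DataFrame(np.exp(log_base), index=ids, columns=panel.names),
        covariates=covariates,
        family_id=pd.Series(ids, index=ids, name="family_id"),
        zygosity=pd.Series("none", index=ids, name="zygosity"),
        ogtt_glucose=glucose,
        ogtt_insulin=insulin,
        truth=truth,
    )


def simulate_case_control_cohort(
    panel: PanelSpec,
    effects: EffectSpec,
    n_cases: int = 306,
    n_controls: int = 4619,
    seed: int = 0,
) -> CohortBundle:
    """Prevalent-disease cohort with exact case/control quotas.

    Outcomes are drawn from a logistic model in the planted standardised
    log-ratio and covariates; sampling continues until both quotas are met
    (outcome-dependent sampling), so achieved counts equal the request
    exactly.
    """
    rng = np.random.default_rng(seed)
    panel = _dilute_panel(panel, effects)
    kept_logs, kept_cov, kept_y = [], [], []
    need_cases, need_controls = n_cases, n_controls
    while need_cases > 0 or need_controls > 0:
        batch = max(1000, 2 * (need_cases + need_controls))
        log_m = _draw_log_metabolites(panel, batch, rng)
        cov = _draw_covariates(batch, rng, age_loc=58.0, bmi_loc=27.0,
                               igt_rate=0.2, lipid_rate=0.2)
        zr = _true_zratio(panel, effects, log_m)
        lp = (effects.logistic_intercept + effects.logistic_beta * zr
              + _covariate_signal(cov, effects))
        y = (rng.random(batch) < 1.0 / (1.0 + np.exp(-lp))).astype(int)
        for label, need in ((1, need_cases), (0, need_controls)):
            take = np.flatnonzero(y == label)[:need]
            kept_logs.append(log_m[take])
            kept_cov.append(cov.iloc[take])
            kept_y.append(y[take])
        need_cases -= min(need_cases, int((y == 1).sum()))
        need_controls -= min(need_controls, int((y == 0).sum()))
    log_all = np.vstack(kept_logs)
    cov_all = pd.concat(kept_cov, ignore_index=True)
    y_all = np.concatenate(kept_y)
    order = rng.permutation(len(y_all))
    log_all, y_all = log_all[order], y_all[order]
    cov_all = cov_all.iloc[order].reset_index(drop=True)
    ids = _sample_ids(len(y_all))
    cov_all.index = ids

    zr_all = _true_zratio(panel, effects, log_all)
    if len(np.unique(y_all)) == 2:
        if zr_all[y_all == 1].min() > zr_all[y_all == 0].max() or \
           zr_all[y_all == 1].max() < zr_all[y_all == 0].min():
            warnings.warn("planted logistic slope produced perfect separation",
                          stacklevel=2)

    truth = {
        "kind": "case_control",
        "pair": list(effects.pair),
        "logistic_beta": effects.logistic_beta,
        "logistic_intercept": effects.logistic_intercept,
        "component_dilution_corr": effects.component_dilution_corr,
        "seed": seed,
    }
    return CohortBundle(
        metabolites=pd.DataFrame(np.exp(log_all), index=ids, columns=panel.names),
        covariates=cov_all,
        family_id=pd.Series(ids, index=ids, name="family_id"),
        zygosity=pd.Series("none", index=ids, name="zygosity"),
        outcome=pd.DataFrame({"status": y_all}, index=ids),
        truth=truth,
    )


def simulate_incident_cohort(
    panel: PanelSpec,
    effects: EffectSpec,
    n: int = 4277,
    followup_years: float = 7.0,
    seed: int = 0,
) -> CohortBundle:
    """Incident-disease cohort: exponential proportional-hazards event times.

    Event times follow an exponential model with hazard
    ``baseline_hazard * exp(log_hr * z_ratio + covariate effects)``;
    censoring combines administrative truncation at ``followup_years`` with
    random exponential censoring calibrated to ``effects.censoring_rate``.
    """
    rng = np.random.default_rng(seed)
    panel = _dilute_panel(panel, effects)
    log_m = _draw_log_metabolites(panel, n, rng)
    ids = _sample_ids(n)
    cov = _draw_covariates(n, rng, age_loc=55.0, bmi_loc=27.0,
                           igt_rate=0.2, lipid_rate=0.2)
    cov.index = ids

    zr = _true_zratio(panel, effects, log_m)
    lp = effects.log_hr * zr + _covariate_signal(cov, effects)
    rate = effects.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    # staggered entry: administrative censoring averages followup_years
    t_admin = rng.uniform(0.7, 1.3, n) * followup_years
    if effects.censoring_rate > 0:
        cens_rate = -np.log(1.0 - effects.censoring_rate) / followup_years
        t_cens = np.minimum(rng.exponential(1.0 / cens_rate, n), t_admin)
    else:
        t_cens = t_admin
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)
    if event.sum() == 0:
        raise ValueError("simulation produced no events; lower censoring_rate "
                         "or raise baseline_hazard")

    truth = {
        "kind": "incident",
        "pair": list(effects.pair),
        "log_hr": effects.log_hr,
        "baseline_hazard": effects.baseline_hazard,
        "censoring_rate": effects.censoring_rate,
        "followup_years": followup_years,
        "component_dilution_corr": effects.component_dilution_corr,
        "seed": seed,
    }
    return CohortBundle(
        metabolites=pd.DataFrame(np.exp(log_m), index=ids, columns=panel.names),
        covariates=cov,
        family_id=pd.Series(ids, index=ids, name="family_id"),
        zygosity=pd.Series("none", index=ids, name="zygosity"),
        outcome=pd.DataFrame({"time": time, "event": event}, index=ids),
        truth=truth,
    )
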