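"""Validation-phase models: OGTT indices, linear/logistic/Cox regressions.

Ordinary model fitting is delegated to statsmodels (OLS, logistic ML)
and lifelines (Cox partial likelihood, Efron tie handling); this module
owns the OGTT surrogate-index formulas, the result packaging, and the
Cox score test used as an oracle against the log-rank statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

from .results import AssociationResult

# Glucose term in the corrected insulin response (mmol/l, = 70 mg/dl).
CIR_GLUCOSE_OFFSET = 3.89
# HOMA-IR insulin unit conversion, pmol/l per µU/ml.
INSULIN_PMOL_PER_MICROU = 6.945


def compute_ogtt_indices(
    glucose: pd.DataFrame,
    insulin: pd.DataFrame,
    timepoints: tuple[int, ...] = (0, 30, 60, 120),
) -> pd.DataFrame:
    """Six OGTT surrogate indices of insulin secretion and resistance.

    ``glucose`` (mmol/l) and ``insulin`` (pmol/l) hold one column per
    timepoint, ordered as ``timepoints``. AUCs are trapezoidal over
    0-120 min. The insulinogenic index is (I30 - I0) / (G30 - G0), the
    corrected insulin response 100 * I30 / (G30 * (G30 - 3.89)), and
    HOMA-IR is G0 * (I0 in µU/ml) / 22.5. Undefined denominators yield
    NaN (flagged missing), not errors.
    """
    if glucose.shape[1] != len(timepoints) or insulin.shape[1] != len(timepoints):
        raise ValueError("glucose and insulin must have one column per timepoint")
    g = glucose.to_numpy(dtype=float)
    ins = insulin.to_numpy(dtype=float)
    if (g <= 0).any():
        raise ValueError("glucose values must be positive")
    t = np.asarray(timepoints, dtype=float)
    auc_g = np.trapezoid(g, t, axis=1)
    auc_i = np.trapezoid(ins, t, axis=1)
    g0, g30 = g[:, 0], g[:, 1]
    i0, i30 = ins[:, 0], ins[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        igi = np.where(g30 != g0, (i30 - i0) / (g30 - g0), np.nan)
        cir = np.where(
            g30 > CIR_GLUCOSE_OFFSET,
            100.0 * i30 / (g30 * (g30 - CIR_GLUCOSE_OFFSET)),
            np.nan,
        )
    homa_ir = g0 * (i0 / INSULIN_PMOL_PER_MICROU) / 22.5
    return pd.DataFrame(
        {
            "auc_glucose": auc_g,
            "auc_insulin": auc_i,
            "auc_insulin_over_auc_glucose": auc_i / auc_g,
            "insulinogenic_index": igi,
            "corrected_insulin_response": cir,
            "homa_ir": homa_ir,
        },
        index=glucose.index,
    )


def _prep_design(X: pd.DataFrame) -> pd.DataFrame:
    Xc = sm.add_constant(X.astype(float), prepend=True, has_constant="skip")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return Xc


def fit_linear(
    y, X: pd.DataFrame, feature: str | None = None, phenotype: str = "outcome"
) -> AssociationResult:
    """OLS with classical SEs and two-sided t-based p for one feature."""
    feature = feature or str(X.columns[0])
    Xc = _prep_design(X)
    res = sm.OLS(np.asarray(y, dtype=float), Xc).fit()
    beta = float(res.params[feature])
    se = float(res.bse[feature])
    if se == 0 or not np.isfinite(se):
        raise ValueError(f"degenerate fit: SE for {feature} is {se}")
    # t-based p on the log scale for consistency with the Wald pipeline
    log_p = float(np.log(2.0) + stats.t.logsf(abs(beta / se), df=res.df_resid))
    return AssociationResult(
        feature=feature,
        phenotype=phenotype,
        beta=beta,
        se=se,
        n=int(res.nobs),
        model="linear",
        covariates=[c for c in X.columns if c != feature],
        log_p=log_p,
    )


def fit_logistic(
    y, X: pd.DataFrame, feature: str | None = None, phenotype: str = "status"
) -> AssociationResult:
    """Maximum-likelihood logistic regression; Wald SE/p, OR = exp(beta)."""
    ya = np.asarray(y, dtype=float)
    if set(np.unique(ya)) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes (0 and 1)")
    feature = feature or str(X.columns[0])
    Xc = _prep_design(X)
    try:
        res = sm.Logit(ya, Xc).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and kin
        raise ValueError(f"logistic fit failed (separation?): {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ValueError("logistic fit did not converge (possible separation)")
    beta = float(res.params[feature])
    se = float(res.bse[feature])
    if not np.isfinite(se) or se > 1e3:
        raise ValueError(f"quasi-separation: SE for {feature} is {se}")
    return AssociationResult(
        feature=feature,
        phenotype=phenotype,
        beta=beta,
        se=se,
        n=int(res.nobs),
        model="logistic",
        covariates=[c for c in X.columns if c != feature],
    )


@dataclass
class SurvivalFit:
    """Cox proportional-hazards fit for one feature of interest."""

    feature: str
    beta: float
    se: float
    n: int
    n_events: int
    ties: str = "efron"
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("SE must be positive")

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def log_p(self) -> float:
        return float(np.log(2.0) + stats.norm.logsf(abs(self.z)))

    @property
    def p(self) -> float:
        return float(np.exp(self.log_p))

    def to_association(self, phenotype: str = "incident") -> AssociationResult:
        return AssociationResult(
            feature=self.feature, phenotype=phenotype, beta=self.beta,
            se=self.se, n=self.n, model="cox", covariates=list(self.covariates),
        )


def fit_cox(
    time, event, X: pd.DataFrame, feature: str | None = None
) -> SurvivalFit:
    """Cox partial-likelihood fit (Efron ties) via lifelines."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    if (t <= 0).any():
        raise ValueError("event/censoring times must be positive")
    if e.sum() < 1:
        raise ValueError("at least one event is required")
    feature = feature or str(X.columns[0])
    df = X.astype(float).copy()
    df["_time"], df["_event"] = t, e
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as exc:
        raise ValueError(f"Cox fit failed (monotone likelihood?): {exc}") from exc
    se = float(cph.standard_errors_[feature])
    if not np.isfinite(se) or se > 1e3:
        raise ValueError(f"monotone likelihood: SE for {feature} is {se}")
    return SurvivalFit(
        feature=feature,
        beta=float(cph.params_[feature]),
        se=se,
        n=len(df),
        n_events=int(e.sum()),
        covariates=tuple(c for c in X.columns if c != feature),
    )


def cox_score_test(time, event, x) -> tuple[float, float]:
    """Cox partial-likelihood score test of beta = 0 for one covariate.

    Returns (chi-square statistic, p). With a single binary covariate and
    no tied event times this is algebraically the log-rank test, which is
    the oracle used in the test suite.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    xa = np.asarray(x, dtype=float)
    order = np.argsort(t)
    t, e, xa = t[order], e[order], xa[order]
    u = 0.0
    v = 0.0
    n = len(t)
    for i in range(n):
        if e[i] != 1:
            continue
        at_risk = xa[t >= t[i]]
        m = at_risk.mean()
        u += xa[i] - m
        v += at_risk.var()  # population variance of x over the risk set
    if v <= 0:
        raise ValueError("degenerate risk sets; score test undefined")
    chi2 = u * u / v
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
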