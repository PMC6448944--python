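"""Multiple-testing machinery and the p_gain screening statistic.

A ratio's p_gain is the smaller of its two component metabolites'
p-values divided by the ratio's p-value; values above a critical
threshold indicate that the ratio carries information beyond either
component. Internal arithmetic is done on natural-log p-values so the
statistic survives p-values far below float underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .results import AssociationResult

DEFAULT_P_FLOOR = 2.2e-16


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def p_gain_critical(alpha: float, n_metabolites: int) -> float:
    """Critical p_gain above which a ratio beats its components.

    Equals n_metabolites / (2 * alpha) — 10 * n_metabolites at the
    conventional alpha = 0.05 (1350 for a 135-metabolite panel).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n_metabolites < 1:
        raise ValueError("n_metabolites must be >= 1")
    return n_metabolites / (2.0 * alpha)


def compute_p_gain(
    p_ratio: float,
    p_m1: float,
    p_m2: float,
    p_floor: float = DEFAULT_P_FLOOR,
) -> float:
    """min(p_m1, p_m2) / p_ratio, with the single p-values floored.

    The component p-values are floored at ``p_floor`` before division
    (reported single p-values saturate at numerical precision); the
    ratio's p-value is used as-is. p_ratio = 0 is rejected — underflow
    must be handled upstream with log-p arithmetic
    (:func:`compute_p_gain_log`).
    """
    if p_ratio == 0:
        raise ValueError("p_ratio underflowed to 0; use compute_p_gain_log")
    for name, p in (("p_ratio", p_ratio), ("p_m1", p_m1), ("p_m2", p_m2)):
        if not (0 < p <= 1):
            raise ValueError(f"{name} must be in (0, 1], got {p}")
    return max(min(p_m1, p_m2), p_floor) / p_ratio


def compute_p_gain_log(
    log_p_ratio: float,
    log_p_m1: float,
    log_p_m2: float,
    p_floor: float = DEFAULT_P_FLOOR,
) -> float:
    """Natural log of the p_gain from natural-log p-values.

    Working in log space keeps the statistic finite and comparable even
    when the ratio p-value is far below float underflow (p < 1e-300) or
    the resulting p_gain would overflow.
    """
    num = max(min(log_p_m1, log_p_m2), np.log(p_floor))
    return float(num - log_p_ratio)


@dataclass
class ScreenDecision:
    """Per-(ratio, phenotype) screening verdict."""

    ratio: str
    phenotype: str
    beta: float
    se: float
    p_ratio: float
    p_m1: float
    p_m2: float
    p_gain: float
    log_p_gain: float
    bonferroni_pass: bool
    p_gain_pass: bool
    alpha: float
    n_tests: int
    n_metabolites: int

    @property
    def selected(self) -> bool:
        """The reported hit set requires both criteria."""
        return self.bonferroni_pass and self.p_gain_pass


def screen_ratios(
    singles: list[AssociationResult],
    ratios: list[AssociationResult],
    alpha: float = 0.05,
    p_floor: float = DEFAULT_P_FLOOR,
) -> list[ScreenDecision]:
    """Apply the Bonferroni and p_gain criteria to every ratio result.

    The Bonferroni denominator is (number of distinct ratios) x (number
    of distinct phenotypes) among the supplied ratio results; the p_gain
    critical value uses the number of distinct metabolites entering the
    ratios. Each ratio result must carry its component pair and both
    component single-metabolite results (same phenotype and model) must
    be present. Output is sorted by ascending ratio p-value (stable).
    """
    if not ratios:
        return []
    single_ix = {(r.feature, r.phenotype, r.model): r for r in singles}
    n_ratio_features = len({r.feature for r in ratios})
    n_phenotypes = len({r.phenotype for r in ratios})
    n_tests = n_ratio_features * n_phenotypes
    mets = set()
    for r in ratios:
        if r.components is None:
            raise ValueError(f"ratio {r.feature} lacks component metadata")
        mets.update(r.components)
    bonf = bonferroni_threshold(alpha, n_tests)
    crit = p_gain_critical(alpha, len(mets))

    decisions = []
    for r in ratios:
        m1, m2 = r.components
        try:
            s1 = single_ix[(m1, r.phenotype, r.model)]
            s2 = single_ix[(m2, r.phenotype, r.model)]
        except KeyError as exc:
            raise ValueError(
                f"missing single-metabolite result {exc.args[0]} for ratio {r.feature}"
            ) from None
        log_pg = compute_p_gain_log(r.log_p, s1.log_p, s2.log_p, p_floor)
        decisions.append(
            ScreenDecision(
                ratio=r.feature,
                phenotype=r.phenotype,
                beta=r.beta,
                se=r.se,
                p_ratio=r.p,
                p_m1=s1.p,
                p_m2=s2.p,
                p_gain=float(np.exp(log_pg)),
                log_p_gain=log_pg,
                bonferroni_pass=bool(r.p <= bonf),
                p_gain_pass=bool(log_pg > np.log(crit)),
                alpha=alpha,
                n_tests=n_tests,
                n_metabolites=len(mets),
            )
        )
    decisions.sort(key=lambda d: d.p_ratio)
    return decisions


def decisions_to_frame(decisions: list[ScreenDecision]) -> pd.DataFrame:
    """Screen report table (Table-2-style layout)."""
    return pd.DataFrame(
        {
            "ratio": [d.ratio for d in decisions],
            "phenotype": [d.phenotype for d in decisions],
            "beta": [d.beta for d in decisions],
            "se": [d.se for d in decisions],
            "p": [d.p_ratio for d in decisions],
            "p_m1": [d.p_m1 for d in decisions],
            "p_m2": [d.p_m2 for d in decisions],
            "p_gain": [d.p_gain for d in decisions],
            "bonferroni_pass": [d.bonferroni_pass for d in decisions],
            "p_gain_pass": [d.p_gain_pass for d in decisions],
            "selected": [d.selected for d in decisions],
        }
    )
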