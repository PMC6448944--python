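"""Shared result containers for association and survival fits.

P-values are carried both as floats and as natural-log values so that
downstream p_gain arithmetic survives underflow (p < 1e-300).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def wald_log_p(beta: float, se: float) -> float:
    """Natural log of the two-sided Wald p-value for beta/se ~ N(0, 1)."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = abs(beta / se)
    return float(np.log(2.0) + stats.norm.logsf(z))


@dataclass
class AssociationResult:
    """One (feature, phenotype, model) regression fit.

    ``beta`` is per SD of the (standardised) feature, in phenotype units.
    ``components`` records the two metabolites behind a ratio feature, if any.
    """

    feature: str
    phenotype: str
    beta: float
    se: float
    n: int
    model: str = "adjusted"
    n_clusters: int | None = None
    covariates: list[str] = field(default_factory=list)
    components: tuple[str, str] | None = None
    log_p: float | None = None  # natural log; overrides the Wald default

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.feature}: SE must be positive, got {self.se}")
        if self.log_p is None:
            self.log_p = wald_log_p(self.beta, self.se)

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def p(self) -> float:
        return float(np.exp(self.log_p))

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabulate association results (one row per fit, Table-1/2-style layout)."""
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "phenotype": [r.phenotype for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "z": [r.z for r in results],
            "p": [r.p for r in results],
            "log_p": [r.log_p for r in results],
            "n": [r.n for r in results],
            "n_clusters": [r.n_clusters for r in results],
            "model": [r.model for r in results],
        }
    )
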