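"""Inverse-variance fixed-effects meta-analysis of per-study estimates."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .results import AssociationResult
from .screen import DEFAULT_P_FLOOR, compute_p_gain_log

log = logging.getLogger(__name__)


@dataclass
class MetaResult:
    """Pooled fixed-effects estimate with heterogeneity diagnostics."""

    beta: float
    se: float
    k: int  # number of studies pooled
    weights: np.ndarray  # 1 / SE_i^2
    q: float  # Cochran heterogeneity statistic (diagnostic only)
    i2: float

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def log_p(self) -> float:
        return float(np.log(2.0) + stats.norm.logsf(abs(self.z)))

    @property
    def p(self) -> float:
        return float(np.exp(self.log_p))


def fixed_effects_meta(study_betas, study_ses) -> MetaResult:
    """Pool study estimates with weights 1/SE^2.

    beta_pooled = sum(w_i * beta_i) / sum(w_i), SE = sum(w_i)^(-1/2);
    Cochran's Q and I^2 are reported as diagnostics but never gate
    anything.
    """
    b = np.asarray(study_betas, dtype=float)
    s = np.asarray(study_ses, dtype=float)
    if b.size == 0:
        raise ValueError("at least one study is required")
    if b.shape != s.shape:
        raise ValueError("betas and SEs must align")
    if (s <= 0).any():
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (b - beta) ** 2))
    df = b.size - 1
    i2 = float(max(0.0, (q - df) / q)) if q > 0 and df > 0 else 0.0
    return MetaResult(beta=beta, se=se, k=b.size, weights=w, q=q, i2=i2)


def _pool(results: list[AssociationResult]) -> MetaResult:
    return fixed_effects_meta([r.beta for r in results], [r.se for r in results])


def meta_table(
    per_study: dict[str, dict[str, AssociationResult]],
    per_study_singles: dict[str, dict[str, AssociationResult]] | None = None,
    p_floor: float = DEFAULT_P_FLOOR,
) -> pd.DataFrame:
    """Pool every ratio across the studies where it is available.

    ``per_study`` maps study name -> {ratio name -> AssociationResult};
    missing (study, ratio) combinations are tolerated and shown as NaN
    ("na"). When ``per_study_singles`` is given (study -> {metabolite ->
    result}), a p_gain column is computed from the pooled single-metabolite
    p-values against the pooled ratio p-value; single-study rows are
    flagged. Ratios absent from every study are omitted with a log entry.
    """
    studies = list(per_study)
    all_ratios: list[str] = []
    for s in studies:
        for ratio in per_study[s]:
            if ratio not in all_ratios:
                all_ratios.append(ratio)

    rows = []
    for ratio in all_ratios:
        avail = {s: per_study[s][ratio] for s in studies if ratio in per_study[s]}
        if not avail:
            log.warning("ratio %s absent from every study; omitted", ratio)
            continue
        pooled = _pool(list(avail.values()))
        row: dict[str, object] = {"ratio": ratio}
        for s in studies:
            r = avail.get(s)
            row[f"{s}_beta"] = r.beta if r else np.nan
            row[f"{s}_se"] = r.se if r else np.nan
            row[f"{s}_p"] = r.p if r else np.nan
        row.update(
            meta_beta=pooled.beta, meta_se=pooled.se, meta_p=pooled.p,
            k_studies=pooled.k, q=pooled.q, i2=pooled.i2,
            single_study=pooled.k == 1,
        )
        if per_study_singles is not None:
            components = next(iter(avail.values())).components
            if components is None:
                raise ValueError(f"ratio {ratio} lacks component metadata")
            pooled_singles = []
            for m in components:
                ms = [per_study_singles[s][m] for s in avail
                      if m in per_study_singles.get(s, {})]
                if ms:
                    pooled_singles.append(_pool(ms))
            if len(pooled_singles) == 2:
                row["p_gain"] = float(np.exp(compute_p_gain_log(
                    pooled.log_p, pooled_singles[0].log_p,
                    pooled_singles[1].log_p, p_floor,
                )))
            else:
                row["p_gain"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
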