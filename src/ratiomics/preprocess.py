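"""Quality filtering, transformations and exhaustive pairwise log-ratios.

Metabolite matrices are plain pandas DataFrames: samples in rows (index =
sample IDs), metabolites in columns, positive concentrations in µmol/l,
missing values as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class QCAudit:
    """Per-metabolite record of the QC decision."""

    metabolite: str
    missing_frac: float
    detectable_frac: float
    kept: bool
    reason: str = ""


def qc_filter(
    raw: pd.DataFrame,
    max_missing_frac: float = 0.3,
    min_detectable_frac: float = 0.5,
    detection_floor: float = 0.0,
) -> tuple[pd.DataFrame, list[QCAudit]]:
    """Drop metabolites failing missingness / detectability thresholds.

    A value counts as detectable when present and strictly above
    ``detection_floor``. Returns the filtered matrix and a full audit log
    (one entry per input metabolite, kept or not).
    """
    for name, v in (("max_missing_frac", max_missing_frac),
                    ("min_detectable_frac", min_detectable_frac)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    audit: list[QCAudit] = []
    keep: list[str] = []
    n = len(raw)
    for col in raw.columns:
        vals = raw[col]
        miss = float(vals.isna().mean())
        detect = float(((vals > detection_floor) & vals.notna()).sum() / n)
        if miss > max_missing_frac:
            audit.append(QCAudit(col, miss, detect, False,
                                 f"missingness {miss:.2f} > {max_missing_frac}"))
        elif detect < min_detectable_frac:
            audit.append(QCAudit(col, miss, detect, False,
                                 f"detectable fraction {detect:.2f} < {min_detectable_frac}"))
        else:
            audit.append(QCAudit(col, miss, detect, True))
            keep.append(col)
    if not keep:
        raise ValueError(
            f"all metabolites removed by QC (max_missing_frac={max_missing_frac}, "
            f"min_detectable_frac={min_detectable_frac})"
        )
    return raw[keep], audit


def log_zscale(matrix: pd.DataFrame) -> pd.DataFrame:
    """log-transform then z-scale each metabolite column (ddof = 1).

    Post-condition: every column has mean 0 and SD 1 to 1e-10.
    """
    if (matrix.values <= 0).any():
        raise ValueError("log_zscale requires strictly positive values")
    logged = np.log(matrix)
    sd = logged.std(ddof=1)
    zero_var = sd[sd == 0].index.tolist()
    if zero_var:
        raise ValueError(f"zero-variance metabolite(s): {zero_var}")
    return (logged - logged.mean()) / sd


def zscale(values: pd.Series | np.ndarray) -> np.ndarray:
    """Plain z-scaling (ddof = 1) of an already-transformed feature."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-scale a constant vector")
    return (v - v.mean()) / sd


@dataclass
class RatioFeatureSet:
    """All unordered-pair log-ratio features of a metabolite matrix.

    ``pairs[k] = (m1, m2)`` with m1 preceding m2 in the source column
    order; ``values`` columns are named "<m1>_<m2>" and hold
    log(m1) - log(m2).
    """

    values: pd.DataFrame
    pairs: list[tuple[str, str]]
    source_columns: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return len(self.pairs)

    def components(self, feature: str) -> tuple[str, str]:
        return self.pairs[self.values.columns.get_loc(feature)]


def pairwise_log_ratios(matrix: pd.DataFrame) -> RatioFeatureSet:
    """Compute log(m1/m2) for every unordered metabolite pair.

    The canonical pair order is (i, j) with i < j in the column order of
    ``matrix``; exactly C(M, 2) features are produced.
    """
    m = matrix.shape[1]
    if m < 2:
        raise ValueError("need at least 2 metabolites for pairwise ratios")
    if (matrix.values <= 0).any():
        raise ValueError("pairwise ratios require strictly positive values")
    logged = np.log(matrix.to_numpy(dtype=float))
    ii, jj = np.triu_indices(m, k=1)
    vals = logged[:, ii] - logged[:, jj]
    cols = matrix.columns
    pairs = [(cols[i], cols[j]) for i, j in zip(ii, jj)]
    names = [f"{a}_{b}" for a, b in pairs]
    return RatioFeatureSet(
        values=pd.DataFrame(vals, index=matrix.index, columns=names),
        pairs=pairs,
        source_columns=list(cols),
    )


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform, Phi^-1((rank - 0.5) / n).

    Ties share the average rank; rank-preserving for distinct values.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise ValueError("inverse_normal_transform needs a 1-d vector, n >= 3")
    if np.unique(v).size == 1:
        raise ValueError("all values tied; transform undefined")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(v))
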