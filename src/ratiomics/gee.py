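"""Gaussian generalized estimating equations for family-clustered data.

Identity-link GEE with an exchangeable working correlation, moment
estimators of the scale and the intra-cluster correlation, and the
robust (sandwich) covariance. With all clusters of size one the
estimator collapses exactly to ordinary least squares with HC0
standard errors, which is the oracle used in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .preprocess import RatioFeatureSet, zscale
from .results import AssociationResult


@dataclass
class GEEFit:
    """Converged GEE solution with robust variance."""

    params: np.ndarray
    cov_robust: np.ndarray  # sandwich estimator
    rho: float  # exchangeable working correlation
    scale: float
    n_iter: int
    converged: bool
    exog_names: list[str]
    n_obs: int
    n_clusters: int
    exact_fit: bool = False  # zero residuals; SEs degenerate to 0

    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_robust), 0.0, None))


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[piv[k]] for k in range(len(diag)) if diag[k] < tol]


def fit_gee_gaussian(
    y,
    X,
    cluster_ids,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> GEEFit:
    """Fit an identity-link Gaussian GEE with exchangeable correlation.

    Iterates between a moment update of (scale, rho) from Pearson
    residuals and a generalized-least-squares update of the coefficients,
    until the maximum absolute coefficient change falls below ``tol``.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float)
    ids = np.asarray(cluster_ids)
    if not (len(ya) == len(Xa) == len(ids)):
        raise ValueError("y, X and cluster_ids must align")
    n, p = Xa.shape
    if np.linalg.matrix_rank(Xa) < p:
        bad = _collinear_columns(Xa, names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    codes, uniq = pd.factorize(ids)
    cluster_rows = [np.flatnonzero(codes == g) for g in range(len(uniq))]
    sizes = np.array([len(r) for r in cluster_rows])
    max_size = sizes.max()
    n_pairs = int((sizes * (sizes - 1) // 2).sum())

    beta, *_ = np.linalg.lstsq(Xa, ya, rcond=None)
    rho = 0.0
    converged = False
    it = 0
    exact = False
    for it in range(1, max_iter + 1):
        resid = ya - Xa @ beta
        ssr = float(resid @ resid)
        if ssr < 1e-28 * max(1.0, float(ya @ ya)):
            exact = True
            rho = 0.0
            converged = True
            break
        scale = ssr / (n - p)
        if n_pairs > p and max_size > 1:
            cross = sum(
                float(np.sum(np.outer(resid[r], resid[r]))) - float(resid[r] @ resid[r])
                for r in cluster_rows if len(r) > 1
            ) / 2.0
            rho = cross / scale / (n_pairs - p)
            lo = -1.0 / (max_size - 1) + 1e-6
            rho = float(np.clip(rho, lo, 1.0 - 1e-6))
        else:
            rho = 0.0
        # GLS step with closed-form compound-symmetry inverse
        xtwx = np.zeros((p, p))
        xtwy = np.zeros(p)
        for r in cluster_rows:
            Xi, yi, ni = Xa[r], ya[r], len(r)
            shrink = rho / (1.0 + (ni - 1) * rho)
            WX = (Xi - shrink * Xi.sum(0)) / (1.0 - rho)
            xtwx += Xi.T @ WX
            xtwy += WX.T @ yi
        new_beta = np.linalg.solve(xtwx, xtwy)
        delta = float(np.max(np.abs(new_beta - beta)))
        beta = new_beta
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"GEE did not converge in {max_iter} iterations (last rho={rho:.4f})"
        )

    resid = ya - Xa @ beta
    scale = float(resid @ resid) / (n - p) if not exact else 0.0
    bread = np.zeros((p, p))
    meat = np.zeros((p, p))
    for r in cluster_rows:
        Xi, ri, ni = Xa[r], resid[r], len(r)
        shrink = rho / (1.0 + (ni - 1) * rho)
        WX = (Xi - shrink * Xi.sum(0)) / (1.0 - rho)
        bread += Xi.T @ WX
        u = WX.T @ ri
        meat += np.outer(u, u)
    bread_inv = np.linalg.inv(bread)
    cov = bread_inv @ meat @ bread_inv
    cov = (cov + cov.T) / 2.0
    return GEEFit(
        params=beta,
        cov_robust=cov,
        rho=float(rho),
        scale=scale,
        n_iter=it,
        converged=converged,
        exog_names=names,
        n_obs=n,
        n_clusters=len(uniq),
        exact_fit=exact,
    )


INSULIN_SENSITIVITY = "insulin_sensitivity_index"


def _design(
    feature: np.ndarray,
    covariates: pd.DataFrame | None,
    adjustment: str,
    phenotype_name: str,
) -> pd.DataFrame:
    cols = {"intercept": np.ones(len(feature)), "feature": feature}
    if adjustment == "adjusted" and covariates is not None:
        cov = covariates.drop(columns=[phenotype_name], errors="ignore")
        # insulin sensitivity enters as a confounder for every phenotype
        # except itself ("if relevant" rule)
        if phenotype_name == INSULIN_SENSITIVITY and INSULIN_SENSITIVITY in cov:
            cov = cov.drop(columns=[INSULIN_SENSITIVITY])
        for c in cov.columns:
            cols[str(c)] = cov[c].to_numpy(dtype=float)
    elif adjustment not in ("adjusted", "crude"):
        raise ValueError(f"unknown adjustment tag: {adjustment}")
    return pd.DataFrame(cols)


def associate_fasting_features(
    features: RatioFeatureSet | pd.DataFrame,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None,
    clusters: pd.Series,
    adjustment: str = "adjusted",
) -> list[AssociationResult]:
    """GEE regression of a phenotype on each (standardised) feature.

    The phenotype is expected to be inverse-normal transformed already.
    Samples with any missing value among phenotype, feature or covariates
    are dropped per feature (complete-case analysis). Results are ordered
    by feature name.
    """
    if isinstance(features, RatioFeatureSet):
        fmat = features.values
        comp = dict(zip(fmat.columns, features.pairs))
    else:
        fmat = features
        comp = {}
    pheno_name = str(phenotype.name) if phenotype.name else "phenotype"
    y = phenotype.to_numpy(dtype=float)
    if np.nanstd(y) == 0:
        raise ValueError(f"phenotype {pheno_name} has zero variance")

    results = []
    for col in sorted(fmat.columns):
        f = fmat[col].to_numpy(dtype=float)
        mask = np.isfinite(f) & np.isfinite(y)
        if covariates is not None and adjustment == "adjusted":
            mask &= np.isfinite(
                covariates.drop(columns=[pheno_name], errors="ignore")
                .to_numpy(dtype=float)
            ).all(axis=1)
        X = _design(
            zscale(f[mask]),
            covariates.loc[mask] if covariates is not None else None,
            adjustment,
            pheno_name,
        )
        fit = fit_gee_gaussian(y[mask], X, clusters.to_numpy()[mask])
        k = X.columns.get_loc("feature")
        results.append(
            AssociationResult(
                feature=col,
                phenotype=pheno_name,
                beta=float(fit.params[k]),
                se=float(fit.bse()[k]),
                n=fit.n_obs,
                n_clusters=fit.n_clusters,
                model=adjustment,
                covariates=[c for c in X.columns if c not in ("intercept", "feature")],
                components=comp.get(col),
            )
        )
    return results


def test_timepoint_change(
    bundle,
    t_from: int,
    t_to: int,
    covariate_names: tuple[str, ...] = ("age", "sex", "bmi"),
) -> list[AssociationResult]:
    """Per-metabolite GEE contrast of log-levels between two clamp timepoints.

    Stacks the two timepoints long-format and regresses log-concentration
    on a timepoint indicator (1 = ``t_to``) plus age, sex and BMI, with
    clustering by family; the indicator's coefficient is the change on the
    log scale (negative = decline).
    """
    if t_from == t_to:
        raise ValueError("t_from and t_to must differ")
    if bundle.longitudinal is None or not {t_from, t_to} <= set(bundle.longitudinal):
        raise ValueError(f"timepoints {t_from} and {t_to} not both available")
    lo, hi = bundle.longitudinal[t_from], bundle.longitudinal[t_to]
    if len(lo) < 3:
        raise ValueError("need at least 3 samples per timepoint")
    cov = bundle.covariates[list(covariate_names)]
    cov2 = pd.concat([cov, cov], ignore_index=True)
    clusters = np.concatenate([bundle.family_id.to_numpy()] * 2)
    indicator = np.concatenate([np.zeros(len(lo)), np.ones(len(hi))])
    results = []
    contrast = f"t{t_to}_vs_t{t_from}"
    for m in lo.columns:
        lo_m, hi_m = lo[m].to_numpy(), hi[m].to_numpy()
        if np.array_equal(lo_m, hi_m):
            # identical profiles at both timepoints: a degenerate null
            # contrast (the working model would have rho -> 1)
            results.append(
                AssociationResult(m, contrast, beta=0.0, se=1.0,
                                  n=2 * len(lo_m), model="timepoint",
                                  log_p=0.0)
            )
            continue
        y = np.log(np.concatenate([lo_m, hi_m]))
        X = pd.DataFrame({"intercept": 1.0, "timepoint": indicator})
        for c in cov2.columns:
            X[c] = cov2[c].to_numpy(dtype=float)
        fit = fit_gee_gaussian(y, X, clusters)
        k = X.columns.get_loc("timepoint")
        results.append(
            AssociationResult(
                feature=m,
                phenotype=contrast,
                beta=float(fit.params[k]),
                se=float(fit.bse()[k]),
                n=fit.n_obs,
                n_clusters=fit.n_clusters,
                model="timepoint",
                covariates=list(covariate_names),
            )
        )
    return results
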