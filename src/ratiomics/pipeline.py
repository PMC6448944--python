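"""End-to-end orchestration: discovery screen and validation battery.

`run_discovery` simulates (or loads) a family-clustered clamp cohort,
derives fasting single-metabolite and exhaustive pairwise log-ratio
features, fits GEE association models against the six insulin-secretion
phenotypes and applies the Bonferroni + p_gain screen.

`run_validation` takes the candidate ratios forward: linear models
against OGTT surrogate indices in two cohorts, logistic models against
prevalent disease in three cohorts, Cox models against incident disease
in two cohorts — each meta-analysed — and a prediction-increment
comparison on the incident data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gee, meta, predict, preprocess, screen, validation
from .cohorts import (
    CLAMP_PHENOTYPES,
    EffectSpec,
    simulate_case_control_cohort,
    simulate_clamp_cohort,
    simulate_incident_cohort,
    simulate_ogtt_cohort,
)
from .panel import make_panel
from .results import AssociationResult, results_to_frame

log = logging.getLogger(__name__)

OGTT_INDICES = (
    "auc_glucose",
    "auc_insulin",
    "auc_insulin_over_auc_glucose",
    "insulinogenic_index",
    "corrected_insulin_response",
    "homa_ir",
)


@dataclass
class RunConfig:
    """Resolved configuration of a full pipeline run.

    Round-trips through YAML; every run's output directory carries the
    resolved config (including the seed) for reproducibility.
    """

    seed: int = 1
    n_metabolites: int = 135
    alpha: float = 0.05
    adjustment: str = "adjusted"
    n_families: int = 54
    ogtt_n: int = 340
    n_cases: int = 306
    n_controls: int = 4619
    incident_n: int = 4277
    followup_years: float = 7.0
    horizon: float = 7.0
    cv_folds: int | None = 10
    qc_max_missing_frac: float = 0.3
    qc_min_detectable_frac: float = 0.5
    validation_panel: list[str] | None = None  # None = all metabolites available
    effects: EffectSpec = field(default_factory=EffectSpec)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["effects"]["pair"] = list(d["effects"]["pair"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        eff = d.pop("effects", {})
        if "pair" in eff:
            eff["pair"] = tuple(eff["pair"])
        return cls(effects=EffectSpec(**eff), **d)


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_discovery(config: RunConfig, outdir: str | Path):
    """Discovery arm: clamp cohort -> preprocess -> GEE -> ratio screen.

    Returns the list of ScreenDecision (all ratios x phenotypes, sorted
    by p) and persists singles/ratios/screen tables plus the QC audit
    and the resolved config under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    panel = make_panel(config.n_metabolites)
    bundle = simulate_clamp_cohort(
        panel, config.effects, n_families=config.n_families, seed=config.seed
    )
    log.info("discovery cohort: %d samples, %d families",
             bundle.n_samples, bundle.family_id.nunique())

    kept, audit = preprocess.qc_filter(
        bundle.metabolites,
        max_missing_frac=config.qc_max_missing_frac,
        min_detectable_frac=config.qc_min_detectable_frac,
    )
    _write(pd.DataFrame([dataclasses.asdict(a) for a in audit]),
           outdir / "qc_audit.tsv")
    singles_std = preprocess.log_zscale(kept)
    ratios = preprocess.pairwise_log_ratios(kept)

    covars = bundle.covariates[["age", "sex", "bmi", "glucose_tolerance"]].copy()
    covars["insulin_sensitivity_index"] = (
        bundle.phenotypes["insulin_sensitivity_index"]
    )

    all_singles: list[AssociationResult] = []
    all_ratios: list[AssociationResult] = []
    for pheno_name in CLAMP_PHENOTYPES:
        y = pd.Series(
            preprocess.inverse_normal_transform(bundle.phenotypes[pheno_name]),
            index=bundle.phenotypes.index,
            name=pheno_name,
        )
        all_singles += gee.associate_fasting_features(
            singles_std, y, covars, bundle.family_id, adjustment=config.adjustment
        )
        all_ratios += gee.associate_fasting_features(
            ratios, y, covars, bundle.family_id, adjustment=config.adjustment
        )
    decisions = screen.screen_ratios(all_singles, all_ratios, alpha=config.alpha)

    _write(results_to_frame(all_singles), outdir / "singles_associations.tsv")
    _write(results_to_frame(all_ratios), outdir / "ratio_associations.tsv")
    _write(screen.decisions_to_frame(decisions), outdir / "screen.tsv")
    return decisions


def _split(total: int, fractions: list[float]) -> list[int]:
    out = [int(round(total * f)) for f in fractions[:-1]]
    out.append(total - sum(out))
    return out


def _ratio_feature(matrix: pd.DataFrame, m1: str, m2: str) -> np.ndarray:
    return preprocess.zscale(np.log(matrix[m1] / matrix[m2]))


def _single_feature(matrix: pd.DataFrame, m: str) -> np.ndarray:
    return preprocess.zscale(np.log(matrix[m]))


def parse_ratio(name: str) -> tuple[str, str]:
    parts = name.split("_")
    if len(parts) != 2:
        raise ValueError(f"cannot parse ratio name {name!r} (expected 'm1_m2')")
    return parts[0], parts[1]


def run_validation(config: RunConfig, candidate_ratios: list[str],
                   outdir: str | Path) -> dict:
    """Validation arm over the candidate ratios from discovery.

    Returns a summary dict and writes per-arm TSV/JSON reports. Ratios
    whose components are missing from the validation panel are reported
    as 'na' rows with a warning (not errors).
    """
    if not candidate_ratios:
        raise ValueError("candidate ratio set is empty")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    panel = make_panel(config.n_metabolites)
    effects = config.effects

    available = set(config.validation_panel
                    if config.validation_panel is not None else panel.names)
    usable, na_ratios = [], []
    for name in candidate_ratios:
        m1, m2 = parse_ratio(name)
        if m1 in available and m2 in available:
            usable.append((name, m1, m2))
        else:
            na_ratios.append(name)
            warnings.warn(f"ratio {name} unavailable in validation panel",
                          stacklevel=2)
    if not usable:
        raise ValueError("no candidate ratio is available in the validation panel")

    summary: dict = {"n_candidates": len(candidate_ratios),
                     "n_usable": len(usable), "na_ratios": na_ratios}

    # --- OGTT arm: two cohorts, six indices, fixed-effects meta ------------
    ogtt_rows = []
    n1 = config.ogtt_n // 2
    ogtt_threshold = config.alpha / 6  # six OGTT outcomes per ratio
    studies = {
        "ogtt_a": simulate_ogtt_cohort(panel, effects, n=n1, seed=config.seed + 11),
        "ogtt_b": simulate_ogtt_cohort(panel, effects, n=config.ogtt_n - n1,
                                       seed=config.seed + 12),
    }
    for name, m1, m2 in usable:
        for index_name in OGTT_INDICES:
            fits = []
            for sname, cohort in studies.items():
                indices = validation.compute_ogtt_indices(
                    cohort.ogtt_glucose, cohort.ogtt_insulin
                )
                X = pd.DataFrame(
                    {
                        name: _ratio_feature(cohort.metabolites, m1, m2),
                        "age": cohort.covariates["age"].to_numpy(),
                        "sex": cohort.covariates["sex"].to_numpy(),
                        "bmi": cohort.covariates["bmi"].to_numpy(),
                        "lipid_lowering":
                            cohort.covariates["lipid_lowering"].to_numpy(),
                    },
                    index=cohort.metabolites.index,
                )
                vals = indices[index_name]
                ok = vals.notna()
                fits.append(
                    validation.fit_linear(
                        preprocess.zscale(vals[ok]), X.loc[ok],
                        feature=name, phenotype=index_name,
                    )
                )
            pooled = meta.fixed_effects_meta([f.beta for f in fits],
                                             [f.se for f in fits])
            ogtt_rows.append({
                "ratio": name, "index": index_name,
                "meta_beta": pooled.beta, "meta_se": pooled.se,
                "meta_p": pooled.p,
                "significant": pooled.p < ogtt_threshold,
            })
    ogtt_table = pd.DataFrame(ogtt_rows)
    _write(ogtt_table, outdir / "ogtt_meta.tsv")
    summary["ogtt_threshold"] = ogtt_threshold

    # --- Prevalent arm: three case-control studies, logistic + meta --------
    case_split = _split(config.n_cases, [0.15, 0.20, 0.65])
    ctrl_split = _split(config.n_controls, [0.15, 0.20, 0.65])
    prev_ratio_res: dict[str, dict[str, AssociationResult]] = {}
    prev_single_res: dict[str, dict[str, AssociationResult]] = {}
    for j, sname in enumerate(("prev_a", "prev_b", "prev_c")):
        cohort = simulate_case_control_cohort(
            panel, effects, n_cases=case_split[j], n_controls=ctrl_split[j],
            seed=config.seed + 21 + j,
        )
        y = cohort.outcome["status"].to_numpy()
        covs = cohort.covariates[["age", "sex", "bmi", "lipid_lowering"]]
        prev_ratio_res[sname] = {}
        prev_single_res[sname] = {}
        needed_singles = set()
        for name, m1, m2 in usable:
            needed_singles.update((m1, m2))
            X = covs.copy()
            X.insert(0, name, _ratio_feature(cohort.metabolites, m1, m2))
            r = validation.fit_logistic(y, X, feature=name)
            r.components = (m1, m2)
            prev_ratio_res[sname][name] = r
        for m in sorted(needed_singles):
            X = covs.copy()
            X.insert(0, m, _single_feature(cohort.metabolites, m))
            prev_single_res[sname][m] = validation.fit_logistic(y, X, feature=m)
    prev_table = meta.meta_table(prev_ratio_res, prev_single_res)
    for name in na_ratios:
        prev_table = pd.concat(
            [prev_table, pd.DataFrame([{"ratio": name}])], ignore_index=True
        )
    _write(prev_table, outdir / "prevalent_meta.tsv")

    # --- Incident arm: two prospective studies, Cox + meta + prediction ----
    inc_n1 = config.incident_n // 2
    inc_cohorts = {
        "inc_a": simulate_incident_cohort(panel, effects, n=inc_n1,
                                          followup_years=config.followup_years,
                                          seed=config.seed + 31),
        "inc_b": simulate_incident_cohort(panel, effects,
                                          n=config.incident_n - inc_n1,
                                          followup_years=config.followup_years,
                                          seed=config.seed + 32),
    }
    inc_ratio_res: dict[str, dict[str, AssociationResult]] = {}
    inc_single_res: dict[str, dict[str, AssociationResult]] = {}
    for sname, cohort in inc_cohorts.items():
        t = cohort.outcome["time"].to_numpy()
        e = cohort.outcome["event"].to_numpy()
        covs = cohort.covariates[["age", "sex", "bmi", "lipid_lowering"]]
        inc_ratio_res[sname] = {}
        inc_single_res[sname] = {}
        needed_singles = set()
        for name, m1, m2 in usable:
            needed_singles.update((m1, m2))
            X = covs.copy()
            X.insert(0, name, _ratio_feature(cohort.metabolites, m1, m2))
            fit = validation.fit_cox(t, e, X, feature=name)
            r = fit.to_association()
            r.components = (m1, m2)
            inc_ratio_res[sname][name] = r
        for m in sorted(needed_singles):
            X = covs.copy()
            X.insert(0, m, _single_feature(cohort.metabolites, m))
            inc_single_res[sname][m] = validation.fit_cox(
                t, e, X, feature=m
            ).to_association()
    inc_table = meta.meta_table(inc_ratio_res, inc_single_res)
    _write(inc_table, outdir / "incident_meta.tsv")

    # Prediction increment of the top candidate in the first incident cohort.
    top = usable[0]
    cohort = inc_cohorts["inc_a"]
    base = cohort.covariates[["age", "sex", "bmi", "lipid_lowering"]].astype(float)
    added = pd.DataFrame(
        {top[0]: _ratio_feature(cohort.metabolites, top[1], top[2])},
        index=base.index,
    )
    comparison = predict.compare_models(
        base, added,
        cohort.outcome["time"], cohort.outcome["event"],
        horizon=config.horizon, k=config.cv_folds, seed=config.seed,
    )
    with open(outdir / "prediction_comparison.json", "w") as fh:
        json.dump(comparison.to_dict(), fh, indent=1)
    summary["prediction"] = comparison.to_dict()
    summary["prevalent_table"] = prev_table
    summary["incident_table"] = inc_table
    summary["ogtt_table"] = ogtt_table
    return summary
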