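"""Synthetic cohort generators: determinism, structure, planted truths."""

import numpy as np
import pandas as pd
import pytest

import ratiomics as rm
from ratiomics.cohorts import CLAMP_TIMEPOINTS
from ratiomics.panel import ARGININE_RESPONSIVE_LYSOPC, make_panel


class TestPanel:
    def test_default_mix_counts_and_uniqueness(self):
        panel = make_panel(135)
        assert panel.n_metabolites == 135
        assert len(set(panel.names)) == 135
        assert len(set(panel.classes)) == 8

    def test_same_seed_identical(self):
        a, b = make_panel(50, seed=3), make_panel(50, seed=3)
        assert a.names == b.names and a.classes == b.classes

    def test_non_positive_definite_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            make_panel(20, within_class_corr=0.2, between_class_corr=0.9)

    def test_high_within_class_correlation_realised(self):
        """rho = 0.99 in a 50-member class shows up in sampled data."""
        panel = make_panel(
            52,
            class_mix={"phosphatidylcholine-aa": 50 / 52, "amino acid": 2 / 52},
            within_class_corr=0.99,
        )
        rng = np.random.default_rng(0)
        draws = rng.multivariate_normal(
            panel.mean_vector(), panel.log_covariance(), size=2000,
            method="cholesky",
        )
        members = [panel.names.index(m)
                   for m in panel.members("phosphatidylcholine-aa")[:10]]
        sub = np.corrcoef(draws[:, members], rowvar=False)
        off_diag = sub[np.triu_indices(10, k=1)]
        assert abs(off_diag.mean() - 0.99) < 0.05


class TestClampCohort:
    def test_deterministic_serialization(self, small_panel, effects, tmp_path):
        b1 = rm.simulate_clamp_cohort(small_panel, effects, 20, seed=9)
        b2 = rm.simulate_clamp_cohort(small_panel, effects, 20, seed=9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        b1.write(d1)
        b2.write(d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_five_timepoints_and_positivity(self, clamp_bundle):
        assert set(clamp_bundle.longitudinal) == set(CLAMP_TIMEPOINTS)
        for mat in clamp_bundle.longitudinal.values():
            assert (mat.values > 0).all()

    def test_one_family_per_sample(self, clamp_bundle):
        assert clamp_bundle.family_id.notna().all()
        assert clamp_bundle.family_id.index.equals(clamp_bundle.metabolites.index)

    def test_amino_acid_decline_factor_recovered(self, effects):
        """Geometric-mean t120/t0 ratio matches the configured 0.8 factor."""
        panel = make_panel(
            12, class_mix={"amino acid": 0.5, "phosphatidylcholine-ae": 0.5}
        )
        bundle = rm.simulate_clamp_cohort(
            panel, effects, n_families=250, seed=11
        )  # ~600 samples
        aa = panel.members("amino acid")
        ratio = (
            np.log(bundle.longitudinal[120][aa])
            - np.log(bundle.longitudinal[0][aa])
        ).values.mean()
        assert abs(np.exp(ratio) - 0.8) < 0.02

    def test_arginine_only_lysopc_response(self, effects):
        panel = make_panel(
            16,
            class_mix={
                "lysophosphatidylcholine": 0.5,
                "amino acid": 0.25,
                "phosphatidylcholine-ae": 0.25,
            },
        )
        bundle = rm.simulate_clamp_cohort(panel, effects, n_families=250, seed=12)
        for m in ARGININE_RESPONSIVE_LYSOPC:
            r180 = (np.log(bundle.longitudinal[180][m])
                    - np.log(bundle.longitudinal[0][m])).mean()
            r190 = (np.log(bundle.longitudinal[190][m])
                    - np.log(bundle.longitudinal[180][m])).mean()
            assert abs(r180) < 0.02  # flat before the arginine bolus
            assert r190 > 0.1  # clear rise after it

    def test_family_icc_recovered(self, small_panel, null_effects):
        """Intra-family phenotype correlation matches the configured ICC."""
        bundle = rm.simulate_clamp_cohort(
            small_panel, null_effects, n_families=800, seed=13,
            familial_icc=0.3, mz_extra_icc=0.0,
        )
        y = bundle.phenotypes["first_phase_gsis"]
        pairs = []
        for _, idx in y.groupby(bundle.family_id).groups.items():
            vals = y.loc[idx].to_numpy()
            for i in range(len(vals)):
                for j in range(i + 1, len(vals)):
                    pairs.append((vals[i], vals[j]))
        arr = np.array(pairs)
        icc = np.corrcoef(np.concatenate([arr[:, 0], arr[:, 1]]),
                          np.concatenate([arr[:, 1], arr[:, 0]]))[0, 1]
        assert abs(icc - 0.3) < 0.05

    def test_zero_size_family_rejected(self, small_panel, effects):
        with pytest.raises(ValueError, match="size 0"):
            rm.simulate_clamp_cohort(
                small_panel, effects, 5, family_size_law=lambda rng: 0
            )


class TestOgttCohort:
    def test_glucose_floor_and_units(self, small_panel, effects):
        bundle = rm.simulate_ogtt_cohort(small_panel, effects, n=340, seed=2)
        assert (bundle.ogtt_glucose.values >= 3.0).all()
        assert (bundle.ogtt_insulin.values > 0).all()

    def test_small_n_rejected(self, small_panel, effects):
        with pytest.raises(ValueError, match="n >= 10"):
            rm.simulate_ogtt_cohort(small_panel, effects, n=5)

    def test_null_effect_gives_null_association(self, small_panel, null_effects):
        """With no planted effect, AUC_insulin ~ ratio z-scores are null."""
        import ratiomics.validation as val
        from ratiomics.preprocess import zscale

        hits = 0
        reps = 60
        for rep in range(reps):
            b = rm.simulate_ogtt_cohort(small_panel, null_effects, n=200,
                                        seed=100 + rep)
            idx = val.compute_ogtt_indices(b.ogtt_glucose, b.ogtt_insulin)
            zr = zscale(np.log(b.metabolites["Val"]
                               / b.metabolites["PC ae C32:2"]))
            fit = val.fit_linear(
                zscale(np.log(idx["auc_insulin"])),
                pd.DataFrame({"r": zr}, index=idx.index),
                feature="r",
            )
            hits += abs(fit.z) > 1.96
        # nominal 5% of 60 ~ 3; allow generous binomial slack
        assert hits <= 10


class TestCaseControlCohort:
    def test_exact_quota(self, small_panel, effects):
        b = rm.simulate_case_control_cohort(small_panel, effects,
                                            n_cases=75, n_controls=300, seed=4)
        counts = b.outcome["status"].value_counts()
        assert counts[1] == 75 and counts[0] == 300

    def test_null_slope_gives_or_near_one(self, small_panel, null_effects):
        from ratiomics.preprocess import zscale
        from ratiomics.validation import fit_logistic

        ors = []
        for rep in range(20):
            b = rm.simulate_case_control_cohort(
                small_panel, null_effects, n_cases=150, n_controls=600,
                seed=200 + rep,
            )
            zr = zscale(np.log(b.metabolites["Val"]
                               / b.metabolites["PC ae C32:2"]))
            fit = fit_logistic(b.outcome["status"],
                               pd.DataFrame({"r": zr}, index=b.outcome.index))
            ors.append(fit.odds_ratio)
        assert abs(np.mean(ors) - 1.0) < 0.1


class TestIncidentCohort:
    def test_structure_and_truth(self, small_panel, effects):
        b = rm.simulate_incident_cohort(small_panel, effects, n=800, seed=6)
        assert (b.outcome["time"] > 0).all()
        assert set(b.outcome["event"].unique()) <= {0, 1}
        assert b.truth["log_hr"] == effects.log_hr

    def test_event_fraction_near_design(self, small_panel, effects):
        b = rm.simulate_incident_cohort(small_panel, effects, n=4000, seed=7)
        assert 0.12 < b.outcome["event"].mean() < 0.32

    def test_full_censoring_rejected(self, small_panel):
        with pytest.raises(ValueError, match="censoring_rate"):
            rm.EffectSpec(censoring_rate=1.0)

    def test_null_log_hr_cox_centred_at_zero(self, small_panel, null_effects):
        from ratiomics.preprocess import zscale
        from ratiomics.validation import fit_cox

        betas = []
        for rep in range(20):
            b = rm.simulate_incident_cohort(small_panel, null_effects,
                                            n=1500, seed=300 + rep)
            zr = zscale(np.log(b.metabolites["Val"]
                               / b.metabolites["PC ae C32:2"]))
            fit = fit_cox(b.outcome["time"], b.outcome["event"],
                          pd.DataFrame({"r": zr}, index=b.outcome.index))
            betas.append(fit.beta)
        assert abs(np.mean(betas)) < 0.05


def test_ratio_beats_singles_mechanism(small_panel, effects):
    """With component dilution >= 0.6 the ratio's z beats either single's.

    This is the construction behind p_gain > 1: the phenotype loads on
    log(A/B), and the positive A-B correlation dilutes each component's
    marginal signal.
    """
    from ratiomics.gee import associate_fasting_features
    from ratiomics.preprocess import (
        inverse_normal_transform,
        log_zscale,
        pairwise_log_ratios,
    )

    z2_ratio, z2_single = [], []
    for rep in range(30):
        b = rm.simulate_clamp_cohort(small_panel, effects, 54, seed=400 + rep)
        mats = b.metabolites[["Val", "PC ae C32:2"]]
        y = pd.Series(
            inverse_normal_transform(b.phenotypes["second_phase_gsis"]),
            index=mats.index, name="second_phase_gsis",
        )
        ratios = pairwise_log_ratios(mats)
        singles = log_zscale(mats)
        r_res = associate_fasting_features(ratios, y, None, b.family_id,
                                           adjustment="crude")
        s_res = associate_fasting_features(singles, y, None, b.family_id,
                                           adjustment="crude")
        z2_ratio.append(r_res[0].z ** 2)
        z2_single.append(max(r.z**2 for r in s_res))
    assert np.mean(z2_ratio) > np.mean(z2_single)
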