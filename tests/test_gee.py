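"""GEE solver: oracle equivalences, invariances, timepoint contrasts."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import ratiomics as rm
from ratiomics import gee
from ratiomics.preprocess import inverse_normal_transform


def _random_instance(seed, n=25, p=3, clustered=False):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)])
    X.insert(0, "const", 1.0)
    y = X.to_numpy() @ rng.normal(size=p + 1) + rng.normal(size=n)
    clusters = rng.integers(0, n // 3, n) if clustered else np.arange(n)
    return y, X, clusters


class TestFitGeeGaussian:
    def test_singleton_clusters_equal_ols_with_hc0(self):
        """On independent data GEE is exactly OLS with HC0 sandwich SEs."""
        for seed in range(100):
            y, X, clusters = _random_instance(seed)
            fit = gee.fit_gee_gaussian(y, X, clusters)
            Xa = X.to_numpy()
            beta_ols = np.linalg.solve(Xa.T @ Xa, Xa.T @ y)
            assert np.allclose(fit.params, beta_ols, atol=1e-10)
            r = y - Xa @ beta_ols
            bread = np.linalg.inv(Xa.T @ Xa)
            hc0 = bread @ (Xa.T * r**2) @ Xa @ bread
            assert np.allclose(fit.cov_robust, hc0, atol=1e-10)
            assert fit.rho == 0.0

    def test_matches_statsmodels_on_clustered_data(self):
        rng = np.random.default_rng(7)
        nfam, size = 80, 3
        fam = np.repeat(np.arange(nfam), size)
        b = rng.normal(0, 0.7, nfam)[fam]
        x = rng.normal(size=nfam * size)
        y = 1 + 0.5 * x + b + rng.normal(size=nfam * size)
        X = pd.DataFrame({"const": 1.0, "x": x})
        mine = gee.fit_gee_gaussian(y, X, fam)
        ref = sm.GEE(
            y, X, groups=fam,
            cov_struct=sm.cov_struct.Exchangeable(),
            family=sm.families.Gaussian(),
        ).fit()
        assert np.allclose(mine.params, ref.params.to_numpy(), atol=1e-8)
        assert np.allclose(mine.bse(), ref.bse.to_numpy(), atol=1e-8)
        assert mine.rho == pytest.approx(float(ref.cov_struct.dep_params),
                                         abs=1e-8)

    def test_exchangeable_rho_recovered(self):
        """200 families of 2 with true rho 0.5: estimate within +-0.1."""
        rng = np.random.default_rng(11)
        nfam = 200
        fam = np.repeat(np.arange(nfam), 2)
        b = rng.normal(0, np.sqrt(0.5), nfam)[fam]
        y = b + rng.normal(0, np.sqrt(0.5), 2 * nfam)
        X = pd.DataFrame({"const": np.ones(2 * nfam)})
        fit = gee.fit_gee_gaussian(y, X, fam)
        assert abs(fit.rho - 0.5) < 0.1

    def test_exact_linear_fit_flagged(self):
        X = pd.DataFrame({"const": 1.0, "x": np.arange(10.0)})
        y = 2.0 + 3.0 * X["x"]
        fit = gee.fit_gee_gaussian(y, X, np.arange(10))
        assert fit.exact_fit
        assert np.allclose(fit.params, [2.0, 3.0], atol=1e-10)
        assert np.allclose(fit.bse(), 0.0, atol=1e-10)

    def test_rank_deficient_design_names_columns(self):
        X = pd.DataFrame({"const": 1.0, "a": np.arange(10.0),
                          "b": 2 * np.arange(10.0)})
        with pytest.raises(ValueError, match="collinear"):
            gee.fit_gee_gaussian(np.random.default_rng(0).normal(size=10),
                                 X, np.arange(10))

    def test_permutation_invariance(self):
        y, X, clusters = _random_instance(3, n=30, clustered=True)
        fit1 = gee.fit_gee_gaussian(y, X, clusters)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        fit2 = gee.fit_gee_gaussian(y[perm], X.iloc[perm], clusters[perm])
        assert np.allclose(fit1.params, fit2.params, atol=1e-10)
        assert np.allclose(fit1.bse(), fit2.bse(), atol=1e-10)

    def test_duplicated_clusters_do_not_shrink_se(self):
        """Doubling every sample into a correlated pair can't shrink SEs."""
        y, X, _ = _random_instance(5, n=40)
        single = gee.fit_gee_gaussian(y, X, np.arange(40))
        y2 = np.repeat(y, 2)
        X2 = X.loc[X.index.repeat(2)].reset_index(drop=True)
        doubled = gee.fit_gee_gaussian(y2, X2, np.repeat(np.arange(40), 2))
        assert np.allclose(doubled.params, single.params, atol=1e-8)
        assert (doubled.bse() >= single.bse() - 1e-10).all()


class TestAssociateFastingFeatures:
    def test_sign_equivariance(self, clamp_bundle):
        y = pd.Series(
            inverse_normal_transform(clamp_bundle.phenotypes["second_phase_gsis"]),
            index=clamp_bundle.metabolites.index, name="second_phase_gsis",
        )
        feats = pd.DataFrame(
            {"f": np.log(clamp_bundle.metabolites["Val"])},
            index=clamp_bundle.metabolites.index,
        )
        res = gee.associate_fasting_features(feats, y, None,
                                             clamp_bundle.family_id,
                                             adjustment="crude")[0]
        res_neg = gee.associate_fasting_features(-feats, y, None,
                                                 clamp_bundle.family_id,
                                                 adjustment="crude")[0]
        assert res_neg.beta == pytest.approx(-res.beta, abs=1e-10)
        assert res_neg.se == pytest.approx(res.se, abs=1e-10)
        assert res_neg.p == pytest.approx(res.p, rel=1e-10)

    def test_insulin_sensitivity_excluded_for_itself(self, clamp_bundle):
        covs = clamp_bundle.covariates[["age", "sex", "bmi"]].copy()
        covs["insulin_sensitivity_index"] = (
            clamp_bundle.phenotypes["insulin_sensitivity_index"]
        )
        y = pd.Series(
            inverse_normal_transform(
                clamp_bundle.phenotypes["insulin_sensitivity_index"]
            ),
            index=clamp_bundle.metabolites.index,
            name="insulin_sensitivity_index",
        )
        feats = pd.DataFrame(
            {"f": np.log(clamp_bundle.metabolites["Val"])},
            index=clamp_bundle.metabolites.index,
        )
        res = gee.associate_fasting_features(feats, y, covs,
                                             clamp_bundle.family_id)[0]
        assert "insulin_sensitivity_index" not in res.covariates
        y2 = y.rename("second_phase_gsis")
        res2 = gee.associate_fasting_features(feats, y2, covs,
                                              clamp_bundle.family_id)[0]
        assert "insulin_sensitivity_index" in res2.covariates

    def test_complete_case_dropping_reported(self, clamp_bundle):
        covs = clamp_bundle.covariates[["age", "sex", "bmi"]].copy()
        covs.iloc[:5, 0] = np.nan
        y = pd.Series(
            inverse_normal_transform(clamp_bundle.phenotypes["glp1_sis"]),
            index=clamp_bundle.metabolites.index, name="glp1_sis",
        )
        feats = pd.DataFrame(
            {"f": np.log(clamp_bundle.metabolites["Val"])},
            index=clamp_bundle.metabolites.index,
        )
        res = gee.associate_fasting_features(feats, y, covs,
                                             clamp_bundle.family_id)[0]
        assert res.n == clamp_bundle.n_samples - 5

    def test_constant_phenotype_error(self, clamp_bundle):
        y = pd.Series(np.ones(clamp_bundle.n_samples),
                      index=clamp_bundle.metabolites.index, name="flat")
        feats = pd.DataFrame(
            {"f": np.log(clamp_bundle.metabolites["Val"])},
            index=clamp_bundle.metabolites.index,
        )
        with pytest.raises(ValueError, match="zero variance"):
            gee.associate_fasting_features(feats, y, None,
                                           clamp_bundle.family_id,
                                           adjustment="crude")

    def test_null_feature_p_uniform(self, small_panel, null_effects):
        """Null-feature p-values are uniform (KS check over replicates)."""
        from scipy import stats

        pvals = []
        for rep in range(120):
            b = rm.simulate_clamp_cohort(small_panel, null_effects, 54,
                                         seed=800 + rep)
            y = pd.Series(
                inverse_normal_transform(b.phenotypes["second_phase_gsis"]),
                index=b.metabolites.index, name="second_phase_gsis",
            )
            feats = pd.DataFrame(
                {"f": np.log(b.metabolites["Val"] / b.metabolites["PC ae C32:2"])},
                index=b.metabolites.index,
            )
            pvals.append(
                gee.associate_fasting_features(feats, y, None, b.family_id,
                                               adjustment="crude")[0].p
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestTimepointChange:
    def test_declining_class_negative_beta(self, effects):
        panel = rm.make_panel(
            12, class_mix={"amino acid": 0.5, "phosphatidylcholine-ae": 0.5}
        )
        bundle = rm.simulate_clamp_cohort(panel, effects, 54, seed=21)
        res = gee.test_timepoint_change(bundle, 0, 120)
        aa = set(panel.members("amino acid"))
        aa_res = [r for r in res if r.feature in aa]
        neg = sum(r.beta < 0 for r in aa_res)
        assert neg >= 0.95 * len(aa_res)
        # planted decline factor 0.8 -> log change ~ -0.223
        assert np.mean([r.beta for r in aa_res]) == pytest.approx(
            np.log(0.8), abs=0.05
        )

    def test_arginine_contrast_significant(self, effects):
        panel = rm.make_panel(
            16,
            class_mix={
                "lysophosphatidylcholine": 0.5,
                "amino acid": 0.25,
                "phosphatidylcholine-ae": 0.25,
            },
        )
        bundle = rm.simulate_clamp_cohort(panel, effects, 54, seed=22)
        res = {r.feature: r for r in gee.test_timepoint_change(bundle, 180, 190)}
        from ratiomics.panel import ARGININE_RESPONSIVE_LYSOPC

        for m in ARGININE_RESPONSIVE_LYSOPC:
            assert res[m].beta > 0
            assert res[m].p < 3.5e-4

    def test_identical_timepoints_zero_beta(self, clamp_bundle):
        bundle = clamp_bundle
        frozen = dict(bundle.longitudinal)
        frozen[999] = frozen[0]
        import dataclasses

        b2 = dataclasses.replace(bundle, longitudinal=frozen)
        res = gee.test_timepoint_change(b2, 0, 999)
        assert all(r.beta == 0.0 for r in res)

    def test_same_timepoint_rejected(self, clamp_bundle):
        with pytest.raises(ValueError, match="must differ"):
            gee.test_timepoint_change(clamp_bundle, 120, 120)
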