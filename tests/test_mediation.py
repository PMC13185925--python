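"""Phenotypic mediation models: recovery, identities, invariances."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from twinmediate import MediationModel, generate_cohort, percent_mediated

from conftest import single_mediator_config


@pytest.fixture(scope="module")
def simple_fit(mediation_cohort):
    model = MediationModel(mediation_cohort.standardized(), "exposure",
                           "outcome", "med_01", kind="simple")
    return model.fit(seed=0)


class TestSimpleMediation:
    def test_recovers_generating_paths(self, simple_fit):
        """Generating a=0.3, b=0.2, c'=0.15 on standardized traits."""
        eff = simple_fit.effects()
        t = eff.table.loc["med_01"]
        assert abs(t["a"] - 0.3) < 3 * t["se_a"]
        assert abs(t["b"] - 0.2) < 3 * t["se_b"]
        assert abs(eff.c_prime - 0.15) < 3 * eff.se_c_prime

    def test_indirect_is_product_and_total_is_sum(self, simple_fit):
        eff = simple_fit.effects()
        t = eff.table.loc["med_01"]
        assert t["ab"] == pytest.approx(t["a"] * t["b"], abs=1e-10)
        assert eff.c_total == pytest.approx(eff.c_prime + eff.sum_ab,
                                            abs=1e-12)

    def test_joint_fit_matches_two_stage_regressions(self, simple_fit,
                                                     mediation_cohort):
        """The SEM a and b equal the standardized OLS coefficients of the
        two separate regressions (complete-data oracle)."""
        df = mediation_cohort.standardized().data
        a_ols = sm.OLS(df["med_01"], sm.add_constant(df["exposure"])).fit()
        b_ols = sm.OLS(df["outcome"], sm.add_constant(
            df[["med_01", "exposure"]])).fit()
        t = simple_fit.effects().table.loc["med_01"]
        assert t["a"] == pytest.approx(a_ols.params["exposure"], abs=5e-3)
        assert t["b"] == pytest.approx(b_ols.params["med_01"], abs=5e-3)

    def test_percent_mediated_formula(self):
        assert percent_mediated(0.14, 0.10) == pytest.approx(58.333, abs=1e-2)
        assert percent_mediated(0.1, 0.0) == pytest.approx(100.0)
        assert np.isnan(percent_mediated(0.0, 0.0))


class TestParallelMediation:
    @pytest.fixture(scope="class")
    def parallel_cohort(self):
        cfg = single_mediator_config(
            n_pairs_mz=2500, n_pairs_dz=2500,
            ace_mediators=((0.3, 0.0, 0.7), (0.3, 0.0, 0.7)),
            pleiotropic_mediators=(0.0, 0.0),
            factor_loadings=((1.0, 0.0), (0.0, 1.0)),
            a_paths=(0.3, 0.2), b_paths=(0.1, 0.1), c_prime=0.1)
        return generate_cohort(cfg, seed=17).standardized()

    def test_total_indirect_recovered(self, parallel_cohort):
        """Two active mediators with ab = 0.03 and 0.02: sum 0.05."""
        res = MediationModel(parallel_cohort, "exposure", "outcome",
                             ["med_01", "med_02"], kind="parallel").fit(seed=0)
        eff = res.effects()
        assert abs(eff.sum_ab - 0.05) < 3 * eff.se_sum_ab

    def test_inert_mediator_leaves_total_indirect(self, parallel_cohort):
        df = parallel_cohort.data.copy()
        rng = np.random.default_rng(1)
        df["med_99"] = rng.standard_normal(len(df))
        two = MediationModel(parallel_cohort, "exposure", "outcome",
                             ["med_01", "med_02"], kind="parallel").fit(seed=0)
        three = MediationModel(df, "exposure", "outcome",
                               ["med_01", "med_02", "med_99"],
                               kind="parallel").fit(seed=0)
        e2, e3 = two.effects(), three.effects()
        assert abs(e3.sum_ab - e2.sum_ab) < 2 * max(e2.se_sum_ab,
                                                    e3.se_sum_ab)


class TestLatentFactorMediation:
    @pytest.fixture(scope="class")
    def latent_cohort(self):
        loadings = ((0.7, 0.0), (0.65, 0.0), (0.6, 0.0),
                    (0.0, 0.65), (0.0, 0.6), (0.0, 0.6))
        cfg = single_mediator_config(
            n_pairs_mz=1500, n_pairs_dz=1500,
            ace_mediators=tuple((0.3, 0.0, 0.7) for _ in range(6)),
            pleiotropic_mediators=tuple(0.0 for _ in range(6)),
            factor_loadings=loadings,
            a_paths=(0.29, 0.29), b_paths=(0.17, 0.14), c_prime=0.05,
            factor_correlation=0.3)
        return generate_cohort(cfg, seed=23).standardized()

    FACTORS = {"f1": ["med_01", "med_02", "med_03"],
               "f2": ["med_04", "med_05", "med_06"]}

    def test_recovery_of_factor_level_paths(self, latent_cohort):
        res = MediationModel(latent_cohort, "exposure", "outcome",
                             kind="latent", factors=self.FACTORS).fit(seed=0)
        eff = res.effects()
        truth = 0.29 * 0.17 + 0.29 * 0.14
        assert abs(eff.sum_ab - truth) < 3 * eff.se_sum_ab
        assert abs(eff.c_prime - 0.05) < 3 * eff.se_c_prime

    def test_indicator_permutation_leaves_deviance(self, latent_cohort):
        """Relabelling indicators within a factor does not change fit."""
        res1 = MediationModel(latent_cohort, "exposure", "outcome",
                              kind="latent", factors=self.FACTORS).fit(seed=0)
        permuted = {"f1": ["med_02", "med_01", "med_03"],
                    "f2": ["med_05", "med_06", "med_04"]}
        res2 = MediationModel(latent_cohort, "exposure", "outcome",
                              kind="latent", factors=permuted).fit(seed=0)
        # marker choice changes raw scaling but not fit or std effects
        assert res1.fitres.minus2ll == pytest.approx(
            res2.fitres.minus2ll, abs=0.5)
        assert res1.effects().sum_ab == pytest.approx(
            res2.effects().sum_ab, abs=0.01)

    def test_single_indicator_factor_rejected(self, latent_cohort):
        with pytest.raises(ValueError, match="indicator"):
            MediationModel(latent_cohort, "exposure", "outcome",
                           kind="latent",
                           factors={"f1": ["med_01"],
                                    "f2": ["med_04", "med_05"]})


def test_name_collision_rejected(mediation_cohort):
    with pytest.raises(ValueError, match="distinct"):
        MediationModel(mediation_cohort.data, "exposure", "exposure",
                       "med_01", kind="simple")
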