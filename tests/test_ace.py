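"""Twin biometric models: Falconer oracle, recovery, concordance."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinmediate import (BivariateACE, TwinCohort, UnivariateACE,
                         concordance_summary, falconer_oracle,
                         generate_cohort, lrt)

from conftest import single_mediator_config


@pytest.mark.parametrize("r_mz, r_dz, expect", [
    (0.6, 0.45, (0.30, 0.30, 0.40)),
    (0.5, 0.25, (0.50, 0.00, 0.50)),
    (2 / 3, 0.5, (1 / 3, 1 / 3, 1 / 3)),
])
def test_falconer_formulas(r_mz, r_dz, expect):
    h2, c2, e2, ok = falconer_oracle(r_mz, r_dz)
    assert (h2, c2, e2) == pytest.approx(expect)
    assert ok


def test_falconer_out_of_range_flagged():
    *_, ok = falconer_oracle(0.9, 0.1)  # h2 = 1.6
    assert not ok


class TestUnivariate:
    def test_recovery_and_falconer_agreement(self, ace_cohort):
        """FIML estimates track both the generating equal-thirds triple
        and the closed-form Falconer decomposition of the same data."""
        res = UnivariateACE(ace_cohort, "exposure").fit(seed=0)
        assert res.converged
        est = res.estimates()
        assert est.a2 + est.c2 + est.e2 == pytest.approx(1.0, abs=1e-6)
        groups = ace_cohort.zygosity_groups()
        r = {z: float(np.corrcoef(g["exposure_1"], g["exposure_2"])[0, 1])
             for z, g in groups.items()}
        h2, c2, e2, _ = falconer_oracle(r["MZ"], r["DZ"])
        for fitted, oracle in ((est.a2, h2), (est.c2, c2), (est.e2, e2)):
            assert fitted == pytest.approx(oracle, abs=0.02)
        for fitted, truth, ci in ((est.a2, 1 / 3, est.ci_a2),
                                  (est.c2, 1 / 3, est.ci_c2),
                                  (est.e2, 1 / 3, est.ci_e2)):
            half = (ci[1] - ci[0]) / 2
            assert abs(fitted - truth) < 3 * max(half / 1.96, 1e-3)

    def test_equal_twin_correlations_give_zero_heritability(self):
        """When MZ and DZ resemble each other equally there is no
        additive-genetic signal."""
        cfg = single_mediator_config(
            n_pairs_mz=2000, n_pairs_dz=2000, ace_exposure=(0.0, 0.5, 0.5))
        cohort = generate_cohort(cfg, seed=9)
        est = UnivariateACE(cohort, "exposure").fit(seed=0).estimates()
        half = (est.ci_a2[1] - est.ci_a2[0]) / 2
        assert est.a2 < 3 * max(half / 1.96, 0.02)

    def test_submodel_deviance_ordering(self, ace_cohort):
        full = UnivariateACE(ace_cohort, "exposure").fit(seed=0)
        ae = UnivariateACE(ace_cohort, "exposure", "AE").fit(seed=0)
        assert ae.fitres.minus2ll >= full.fitres.minus2ll - 1e-6
        chi2, df, p = lrt(full.fitres, ae.fitres)
        assert df == 1

    def test_single_zygosity_rejected(self, ace_cohort):
        mz_only = TwinCohort(
            ace_cohort.data.query("zygosity == 'MZ'").copy())
        with pytest.raises(ValueError, match="DZ"):
            UnivariateACE(mz_only, "exposure")


class TestBivariate:
    def test_identical_traits_give_unit_correlations(self, ace_cohort):
        df = ace_cohort.data.copy()
        df["copy"] = df["exposure"]
        est = BivariateACE(TwinCohort(df), "exposure", "copy").fit(
            seed=0).estimates()
        for r in (est.r_g, est.r_c, est.r_e):
            assert r == pytest.approx(1.0, abs=0.02)

    def test_independent_traits_give_zero_correlations(self):
        cfg = single_mediator_config(
            n_pairs_mz=1500, n_pairs_dz=1500,
            a_paths=(0.0, 0.0), b_paths=(0.0, 0.0), c_prime=0.0)
        cohort = generate_cohort(cfg, seed=13)
        # outcome has no structural or confounder link to exposure here
        est = BivariateACE(cohort, "exposure", "outcome").fit(
            seed=0).estimates()
        for r in (est.r_g, est.r_c, est.r_e):
            assert abs(r) < 0.12


class TestConcordance:
    def test_identical_cotwins_never_discordant(self, ace_cohort):
        df = ace_cohort.data.copy()
        wide = df.pivot(index="family_id", columns="twin", values="exposure")
        df.loc[df["twin"] == 2, "exposure"] = df.loc[
            df["twin"] == 2, "family_id"].map(wide[1]).to_numpy()
        assert concordance_summary(TwinCohort(df, strict=False),
                                   "exposure", 1.0) == 0.0

    def test_zero_threshold_counts_any_difference(self, ace_cohort):
        assert concordance_summary(ace_cohort, "exposure", 0.0) == 1.0

    def test_matches_normal_difference_tail(self, ace_cohort):
        """Within-pair difference is normal with variance 2(1 - r); the
        discordance rate equals its tail beyond one phenotypic SD."""
        rate = concordance_summary(ace_cohort, "exposure", 1.0)
        groups = ace_cohort.zygosity_groups()
        expect = 0.0
        total = sum(len(g) for g in groups.values())
        for z, g in groups.items():
            r = float(np.corrcoef(g["exposure_1"], g["exposure_2"])[0, 1])
            tail = 2 * stats.norm.sf(1.0 / math.sqrt(2 * (1 - r)))
            expect += tail * len(g) / total
        assert rate == pytest.approx(expect, abs=3 * math.sqrt(
            expect * (1 - expect) / total))
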