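"""Generator: analytic twin covariances, instrument, missingness."""

import math

import numpy as np
import pytest
from scipy import stats

from twinmediate import SimulationConfig, generate_cohort, inject_missingness
from twinmediate.simulate import implied_pair_covariance

from conftest import single_mediator_config


def _within_pair_cov(cohort, trait, zyg):
    w = cohort.zygosity_groups()[zyg]
    a, b = w[f"{trait}_1"], w[f"{trait}_2"]
    return float(np.cov(a, b)[0, 1])


class TestConfigValidation:
    @pytest.mark.parametrize("field, bad", [
        ("ace_exposure", (0.5, 0.5, 0.5)),
        ("ace_outcome", (0.5, 0.6)),
        ("missing_rate", 1.0),
        ("thresholds", (0.0, 0.0, 1.0, 2.0)),
        ("factor_correlation", 1.5),
        ("n_pairs_mz", 0),
    ])
    def test_invalid_field_named_in_error(self, field, bad):
        with pytest.raises(ValueError, match=field.split("_")[0]):
            single_mediator_config(**{field: bad})


class TestTwinStructure:
    def test_mz_pairs_share_pgs(self, mediation_cohort):
        mz = mediation_cohort.data.query("zygosity == 'MZ'")
        spread = mz.groupby("family_id")["pgs"].agg(lambda s: s.max() - s.min())
        assert (spread < 1e-12).all()

    def test_equal_thirds_exposure_matches_closed_form(self, ace_cohort):
        """MZ within-pair correlation -> a2 + c2 = 2/3; DZ -> 1/2."""
        n = 2000
        for zyg, expect in (("MZ", 2 / 3), ("DZ", 0.5)):
            w = ace_cohort.zygosity_groups()[zyg]
            r = np.corrcoef(w["exposure_1"], w["exposure_2"])[0, 1]
            mc_se = (1 - expect ** 2) / math.sqrt(n - 3)
            assert abs(r - expect) < 3 * mc_se

    def test_pure_e_trait_uncorrelated_within_pairs(self):
        cfg = single_mediator_config(
            n_pairs_mz=3000, n_pairs_dz=3000, ace_exposure=(0.0, 0.0, 1.0))
        cohort = generate_cohort(cfg, seed=1)
        for zyg in ("MZ", "DZ"):
            assert abs(_within_pair_cov(cohort, "exposure", zyg)) < 0.06

    def test_analytic_covariance_matches_generating_ace(self):
        """Implied cross-twin covariances equal a2+c2 (MZ), a2/2+c2 (DZ)."""
        triple = (0.4, 0.25, 0.35)
        cfg = single_mediator_config(ace_exposure=triple)
        for zyg, expect in (("MZ", triple[0] + triple[1]),
                            ("DZ", 0.5 * triple[0] + triple[1])):
            names, sig = implied_pair_covariance(cfg, zyg)
            i, j = names.index("exposure_1"), names.index("exposure_2")
            assert sig[i, j] == pytest.approx(expect, abs=1e-12)
            assert np.allclose(np.diag(sig), 1.0, atol=1e-9)
            assert np.allclose(sig, sig.T)

    def test_instrumental_path_recovered_empirically(self):
        cfg = single_mediator_config(
            n_pairs_mz=5000, n_pairs_dz=5000, instrumental_path=0.09)
        cohort = generate_cohort(cfg, seed=3)
        r = np.corrcoef(cohort.data["pgs"], cohort.data["exposure"])[0, 1]
        assert abs(r - 0.09) < 3 / math.sqrt(len(cohort.data))

    def test_reproducible_for_fixed_seed(self):
        cfg = single_mediator_config(n_pairs_mz=50, n_pairs_dz=50)
        a = generate_cohort(cfg, seed=11).data
        b = generate_cohort(cfg, seed=11).data
        assert a.equals(b)


class TestMeasurementLayer:
    def test_items_give_in_range_composites(self):
        cfg = SimulationConfig.realistic(n_pairs_mz=200, n_pairs_dz=200)
        cohort = generate_cohort(cfg, seed=5)
        comp = cohort.data["exposure"].dropna()
        assert comp.between(0, 4).all()

    def test_missing_rate_zero_is_identity(self, mediation_cohort):
        out = inject_missingness(mediation_cohort, 0.0, seed=1)
        assert out.data.equals(mediation_cohort.data)

    def test_item_missingness_proportion(self):
        cfg = SimulationConfig.realistic(
            n_pairs_mz=500, n_pairs_dz=500, missing_rate=0.0)
        cohort = generate_cohort(cfg, seed=2)
        out = inject_missingness(cohort, 0.2, seed=3)
        item_cols = [c for c in out.items.columns if "_item" in c]
        vals = out.items[item_cols].to_numpy(float)
        prop = float(np.isnan(vals).mean())
        n = vals.size
        assert abs(prop - 0.2) < 3 * math.sqrt(0.2 * 0.8 / n)

    def test_composite_missingness_matches_binomial_tail(self):
        """3-item scales at item rate 0.9: composite missing when >1 of 3
        items are missing, so P = P(Bin(3, .9) >= 2)."""
        cfg = SimulationConfig.realistic(
            n_pairs_mz=1500, n_pairs_dz=1500, missing_rate=0.0)
        cfg.item_counts = {k: 3 for k in cfg.item_counts}
        cohort = generate_cohort(cfg, seed=4)
        out = inject_missingness(cohort, 0.9, seed=5)
        prop = float(out.data["exposure"].isna().mean())
        expect = float(stats.binom.sf(1, 3, 0.9))
        n = len(out.data)
        assert abs(prop - expect) < 3 * math.sqrt(expect * (1 - expect) / n)

    def test_rate_one_rejected(self, mediation_cohort):
        with pytest.raises(ValueError):
            inject_missingness(mediation_cohort, 1.0)
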