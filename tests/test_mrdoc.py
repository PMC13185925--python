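"""MR-DoC models: identification, recovery, constraints, stratified tests."""

import numpy as np
import pandas as pd
import pytest

from twinmediate import MRDoCModel, SimulationConfig, generate_cohort
from twinmediate.mrdoc import (build_mrdoc_spec, pair_median_split,
                               stratified_equality_test)

from conftest import single_mediator_config


@pytest.fixture(scope="module")
def baseline_cohort():
    """Instrument 0.09, pleiotropy 0.06, causal 0.14, A/C confounding."""
    cfg = SimulationConfig(
        n_pairs_mz=3000, n_pairs_dz=3000,
        ace_mediators=((0.3, 0.0, 0.7),), pleiotropic_mediators=(0.0,),
        factor_loadings=((0.6, 0.0),), a_paths=(0.0, 0.0),
        b_paths=(0.0, 0.0), c_prime=0.14, r_e=0.0)
    return generate_cohort(cfg, seed=101).standardized()


class TestBaseline:
    def test_recovers_instrumental_causal_pleiotropic(self, baseline_cohort):
        res = MRDoCModel(baseline_cohort).fit(seed=0)
        assert res.converged
        eff = res.effects()
        for (value, se, _ci), truth in ((eff.instrumental, 0.09),
                                        (eff.causal, 0.14)):
            assert abs(value - truth) < 3 * se
        p = eff.pleiotropic.loc["outcome"]
        assert abs(p["std"] - 0.06) < 3 * p["se"]

    def test_confounding_alone_gives_null_causal(self):
        """Strong A-confounding with no causal path: the causal estimate
        stays near zero where a naive regression would not."""
        cfg = single_mediator_config(
            n_pairs_mz=3000, n_pairs_dz=3000, c_prime=0.0, r_a=0.5,
            instrumental_path=0.09, pleiotropic_outcome=0.0)
        cohort = generate_cohort(cfg, seed=7).standardized()
        res = MRDoCModel(cohort).fit(seed=0)
        eff = res.effects()
        value, se, _ = eff.causal
        assert abs(value) < 3 * se
        naive = float(np.corrcoef(cohort.data["exposure"],
                                  cohort.data["outcome"])[0, 1])
        assert naive > 0.1  # confounded phenotypic association is large

    def test_removing_instrument_inflates_causal_uncertainty(self):
        """When identification leans on the instrument (exposure-outcome
        E covariance freed, pleiotropy fixed), weakening the
        instrumental path inflates the Monte-Carlo sampling variance of
        the causal estimate; with no instrument at all the
        weak-instrument flag trips on every replicate."""
        draws = {0.3: [], 0.09: []}
        zero_flags = []
        for rep in range(8):
            for f in (0.3, 0.09, 0.0):
                cfg = single_mediator_config(
                    n_pairs_mz=1500, n_pairs_dz=1500, c_prime=0.1,
                    r_a=0.4, instrumental_path=f, pleiotropic_outcome=0.0,
                    a_paths=(0.0, 0.0), b_paths=(0.0, 0.0),
                    factor_loadings=((0.6, 0.0),))
                cohort = generate_cohort(cfg, seed=900 + rep).standardized()
                eff = MRDoCModel(cohort, free_re=True,
                                 free_pleiotropy=False).fit(seed=rep).effects()
                if f == 0.0:
                    zero_flags.append(eff.weak_instrument)
                else:
                    draws[f].append(eff.causal[0])
        sd_strong = np.std(draws[0.3], ddof=1)
        sd_weak = np.std(draws[0.09], ddof=1)
        assert sd_weak > 1.5 * sd_strong, (sd_strong, sd_weak)
        assert all(zero_flags)

    def test_double_identification_rejected(self):
        with pytest.raises(ValueError, match="not identified"):
            build_mrdoc_spec(free_re=True, free_pleiotropy=True)


class TestMediationVariant:
    @pytest.fixture(scope="class")
    def med_cohort(self):
        cfg = SimulationConfig(
            n_pairs_mz=3000, n_pairs_dz=3000,
            ace_mediators=((0.3, 0.0, 0.7),), pleiotropic_mediators=(0.0,),
            factor_loadings=((1.0, 0.0),), a_paths=(0.46, 0.0),
            b_paths=(0.13, 0.0), c_prime=0.09, factor_correlation=0.0,
            r_e=0.0)
        return generate_cohort(cfg, seed=55).standardized()

    def test_simple_mediation_recovery(self, med_cohort):
        res = MRDoCModel(med_cohort, mediators=["med_01"]).fit(seed=0)
        assert res.converged
        eff = res.effects()
        t = eff.mediation.table.loc["med_01"]
        assert abs(t["a"] - 0.46) < 3 * t["se_a"]
        assert abs(t["b"] - 0.13) < 3 * t["se_b"]
        assert t["ab"] == pytest.approx(t["a"] * t["b"], abs=1e-10)
        assert "c_med_01=0" in res.model.constraint_tags

    def test_zero_paths_generation_gives_zero_effects(self):
        cfg = single_mediator_config(
            n_pairs_mz=2000, n_pairs_dz=2000, a_paths=(0.0, 0.0),
            b_paths=(0.0, 0.0), c_prime=0.0, factor_loadings=((0.6, 0.0),),
            instrumental_path=0.09)
        cohort = generate_cohort(cfg, seed=77).standardized()
        eff = MRDoCModel(cohort, mediators=["med_01"]).fit(seed=0).effects()
        t = eff.mediation.table.loc["med_01"]
        assert abs(t["ab"]) < 0.01
        assert abs(eff.mediation.c_prime) < 3 * eff.mediation.se_c_prime

    def test_freeing_mediator_c_consistent_when_generating_c_zero(
            self, med_cohort):
        """With generating shared environment zero for the mediator, the
        constrained and unconstrained variants agree."""
        dropped = MRDoCModel(med_cohort, mediators=["med_01"],
                             drop_c_mediators=[True]).fit(seed=0)
        freed = MRDoCModel(med_cohort, mediators=["med_01"],
                           drop_c_mediators=[False]).fit(seed=0)
        for res in (dropped, freed):
            assert res.converged
        td = dropped.effects().mediation.table.loc["med_01"]
        tf = freed.effects().mediation.table.loc["med_01"]
        for col in ("a", "b"):
            assert abs(td[col] - tf[col]) < 3 * max(td[f"se_{col}"],
                                                    tf[f"se_{col}"])


class TestStratified:
    @staticmethod
    def _strata(cohort, frac_high=0.5, seed=0):
        fams = cohort.pairs_wide()["family_id"]
        rng = np.random.default_rng(seed)
        return pd.Series(np.where(rng.random(len(fams)) < frac_high,
                                  "high", "low"), index=fams)

    def test_equal_paths_give_nonsignificant_lrt(self):
        cfg = single_mediator_config(
            n_pairs_mz=1200, n_pairs_dz=1200, a_paths=(0.3, 0.0),
            b_paths=(0.15, 0.0), c_prime=0.05, factor_loadings=((1.0, 0.0),),
            instrumental_path=0.09)
        cohort = generate_cohort(cfg, seed=61).standardized()
        strata = self._strata(cohort)
        free, constr, (chi2, df, p) = stratified_equality_test(
            cohort, strata, mediators=["med_01"], fit_options={"seed": 0})
        assert df == 3
        assert chi2 >= 0
        assert p > 0.003  # no generated moderation

    def test_different_a_paths_detected(self):
        """a = 0.34 vs 0.23 across strata is picked up by the LRT."""
        frames = []
        for stratum, a in (("high", 0.34), ("low", 0.23)):
            cfg = single_mediator_config(
                n_pairs_mz=1500, n_pairs_dz=1500, a_paths=(a, 0.0),
                b_paths=(0.15, 0.0), c_prime=0.05,
                factor_loadings=((1.0, 0.0),), instrumental_path=0.09)
            ch = generate_cohort(cfg, seed=3 if stratum == "high" else 4)
            df = ch.data.copy()
            df["family_id"] = stratum[0] + df["family_id"]
            frames.append((stratum, df))
        from twinmediate import TwinCohort
        allc = TwinCohort(pd.concat([f for _s, f in frames],
                                    ignore_index=True)).standardized()
        strata = pd.Series({fid: ("high" if fid.startswith("h") else "low")
                            for fid in allc.data["family_id"].unique()})
        _f, _c, (chi2, df_, p) = stratified_equality_test(
            allc, strata, mediators=["med_01"], fit_options={"seed": 0})
        assert p < 0.003

    def test_empty_cell_named(self, baseline_cohort):
        strata = self._strata(baseline_cohort)
        strata[:] = "high"
        with pytest.raises(ValueError, match="empty cell"):
            stratified_equality_test(baseline_cohort, strata,
                                     mediators=["med_01"])

    def test_pair_median_split_keeps_families(self, baseline_cohort):
        labels = pair_median_split(baseline_cohort, "exposure")
        assert set(labels.unique()) <= {"high", "low"}
        assert len(labels) == baseline_cohort.n_pairs
        assert abs((labels == "high").sum() - (labels == "low").sum()) <= 1
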