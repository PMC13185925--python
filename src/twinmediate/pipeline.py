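"""End-to-end orchestration: simulate -> screen -> factors -> mediation
-> MR-DoC -> report, with machine-readable outputs and a run manifest.

Every stage writes CSV tables into the output directory; the manifest
(JSON) records the seed, configuration, adjusted significance threshold
and constraint tags so any table can be regenerated exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ace import concordance_summary
from .cohort import TwinCohort, read_cohort, write_cohort
from .config import SimulationConfig
from .factors import efa_two_factor, factor_groups
from .mediation import MediationModel
from .mrdoc import MRDoCModel, pair_median_split, stratified_equality_test
from .screen import (bonferroni_threshold, cluster_robust_regression,
                     median_split, moderation_test, pgs_validation,
                     screen_mediators)
from .simulate import generate_cohort

log = logging.getLogger("twinmediate")

STAGES = ("simulate", "screen", "factors", "mediate", "mrdoc", "report")


@dataclass
class PipelineConfig:
    """Configuration of the analysis pipeline.

    ``cohort_path`` loads an existing cohort CSV; otherwise a cohort is
    simulated from ``simulation`` (or defaults).  ``stages`` must be a
    prefix of the dependency order simulate -> screen -> factors ->
    mediate -> mrdoc -> report.
    """

    out_dir: str = "twinmediate_out"
    seed: int = 0
    alpha: float = 0.05
    n_mediators: int = 18
    stages: tuple[str, ...] = STAGES
    cohort_path: str | None = None
    simulation: SimulationConfig | None = None
    run_stratified: bool = True
    max_simple_models: int = 3
    verbosity: str = "INFO"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        order = [s for s in STAGES if s in self.stages]
        if tuple(order) != tuple(self.stages) or order != list(
                STAGES[: len(order)]):
            raise ValueError(
                f"stages must be a prefix of {STAGES}, got {self.stages}")

    @classmethod
    def demo(cls, **overrides) -> "PipelineConfig":
        """Small, fast end-to-end configuration."""
        n_med = overrides.pop("n_mediators", 6)
        sim = overrides.pop("simulation", None)
        if sim is None:
            from .config import DEFAULT_LOADINGS
            sim = SimulationConfig(
                n_pairs_mz=400, n_pairs_dz=400,
                ace_mediators=tuple((0.30, 0.00, 0.70)
                                    for _ in range(n_med)),
                pleiotropic_mediators=tuple(0.03 for _ in range(n_med)),
                factor_loadings=DEFAULT_LOADINGS[:n_med],
            )
        return cls(simulation=sim, n_mediators=n_med, **overrides)


def descriptive_summary(counts: pd.DataFrame | dict,
                        denominator: int | None = None) -> pd.DataFrame:
    """Percentage table from counts: ``100 * count / denominator`` to 2 dp.

    ``counts`` is a mapping name -> count (with a shared ``denominator``)
    or name -> (count, denominator).  Zero denominators are an error.
    """
    rows = []
    items = counts.items() if isinstance(counts, dict) else counts.iterrows()
    for name, v in items:
        if isinstance(v, (tuple, list, pd.Series)):
            n, d = int(v[0]), int(v[1])
        else:
            if denominator is None:
                raise ValueError("denominator required for scalar counts")
            n, d = int(v), int(denominator)
        if d <= 0:
            raise ValueError(f"{name}: zero or negative denominator")
        if n < 0:
            raise ValueError(f"{name}: negative count")
        rows.append({"category": name, "n": n, "denominator": d,
                     "percent": round(100.0 * n / d, 2)})
    return pd.DataFrame(rows).set_index("category")


def cohort_descriptives(cohort: TwinCohort) -> pd.DataFrame:
    counts = cohort.data["zygosity"].value_counts().to_dict()
    return descriptive_summary(counts, denominator=len(cohort.data))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary.

    Deterministic for a fixed configuration and seed.  On stage failure
    a failure marker is written beside the partial outputs and the
    exception re-raised with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    level = getattr(logging, config.verbosity.upper(), 20)
    logging.basicConfig(level=level)
    log.setLevel(level)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    from . import __version__ as pkg_version

    manifest: dict = {
        "package_version": pkg_version,
        "seed": config.seed,
        "alpha": config.alpha,
        "n_mediators": config.n_mediators,
        "stages_run": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    raw_thr, rounded_thr = bonferroni_threshold(config.alpha,
                                               config.n_mediators)
    manifest["adjusted_threshold"] = raw_thr
    manifest["adjusted_threshold_rounded"] = rounded_thr
    headline: dict = {}
    state: dict = {}

    def stage(name):
        return name in config.stages

    current = "setup"
    try:
        # ---------------- simulate / load ----------------------------
        current = "simulate"
        if config.cohort_path is not None:
            cohort = read_cohort(config.cohort_path)
        else:
            sim = config.simulation or SimulationConfig()
            cohort = generate_cohort(sim, seed=config.seed)
            manifest["simulation"] = json.loads(json.dumps(
                asdict(sim), default=list))
        if stage("simulate"):
            write_cohort(cohort, out / "cohort.csv")
            cohort_descriptives(cohort).to_csv(out / "descriptives.csv")
            manifest["stages_run"].append("simulate")
            manifest["n_pairs"] = cohort.n_pairs
        meds = cohort.mediator_columns
        state["cohort"] = cohort

        # ---------------- screening ----------------------------------
        if stage("screen"):
            current = "screen"
            log.info("stage: screen")
            assoc = cluster_robust_regression(cohort, "outcome", "exposure")
            headline["beta_exposure_outcome"] = assoc.beta
            pgsres = pgs_validation(cohort, "exposure")
            headline["beta_pgs_exposure"] = pgsres.beta
            labels, counts = median_split(cohort.data["exposure"])
            frame = cohort.data.copy()
            frame["exposure_level"] = (labels == "high").astype(float)
            mod = moderation_test(frame, "outcome", "exposure",
                                  "exposure_level")
            screen_tab = screen_mediators(cohort, "exposure", "outcome",
                                          meds, raw_thr)
            screen_tab.to_csv(out / "association_screen.csv")
            pd.DataFrame([assoc.as_dict(), pgsres.as_dict(),
                          mod.as_dict()]).to_csv(
                out / "key_associations.csv", index=False)
            headline["discordance_rate"] = concordance_summary(
                cohort, "exposure", 1.0)
            state["included"] = [m for m in meds
                                 if screen_tab.loc[m, "included"]]
            manifest["median_split_counts"] = counts
            manifest["stages_run"].append("screen")
        else:
            state["included"] = meds

        # ---------------- factor analysis -----------------------------
        if stage("factors"):
            current = "factors"
            log.info("stage: factors")
            sol = efa_two_factor(cohort)
            sol.loadings.to_csv(out / "factor_loadings.csv")
            headline["factor_correlation"] = sol.factor_correlation
            state["factors"] = factor_groups(sol)
            manifest["stages_run"].append("factors")

        # ---------------- phenotypic mediation ------------------------
        if stage("mediate"):
            current = "mediate"
            log.info("stage: mediate")
            std = cohort.standardized()
            tabs = []
            for m in state["included"][: config.max_simple_models]:
                res = MediationModel(std, "exposure", "outcome", m,
                                     kind="simple").fit(seed=config.seed)
                eff = res.effects(threshold=raw_thr)
                tabs.append(eff.table.assign(model=f"simple:{m}",
                                             c_prime=eff.c_prime))
            if state["included"]:
                par = MediationModel(std, "exposure", "outcome",
                                     state["included"],
                                     kind="parallel").fit(seed=config.seed)
                eff = par.effects(threshold=raw_thr)
                tabs.append(eff.table.assign(model="parallel",
                                             c_prime=eff.c_prime))
                headline["phenotypic_parallel_percent_mediated"] = \
                    eff.percent_mediated
            factors = state.get("factors")
            if factors and all(len(v) >= 2 for v in factors.values()):
                lat = MediationModel(std, "exposure", "outcome",
                                     kind="latent",
                                     factors=factors).fit(seed=config.seed)
                eff = lat.effects(threshold=raw_thr)
                tabs.append(eff.table.assign(model="latent",
                                             c_prime=eff.c_prime))
                headline["phenotypic_latent_percent_mediated"] = \
                    eff.percent_mediated
                headline["phenotypic_latent_sum_ab"] = eff.sum_ab
            pd.concat(tabs).to_csv(out / "mediation_phenotypic.csv")
            manifest["stages_run"].append("mediate")

        # ---------------- MR-DoC --------------------------------------
        if stage("mrdoc"):
            current = "mrdoc"
            log.info("stage: mrdoc")
            std = cohort.standardized()
            base = MRDoCModel(std).fit(seed=config.seed)
            be = base.effects(threshold=raw_thr)
            headline["mrdoc_instrumental"] = be.instrumental[0]
            headline["mrdoc_causal"] = be.causal[0]
            headline["mrdoc_pleiotropic_outcome"] = float(
                be.pleiotropic["std"].get("outcome", np.nan))
            tables = [base.to_table(raw_thr)]
            factors = state.get("factors")
            if factors and all(len(v) >= 2 for v in factors.values()):
                lat = MRDoCModel(std, latent_factors=factors).fit(
                    seed=config.seed)
                if lat.converged:
                    le = lat.effects(threshold=raw_thr)
                    headline["mrdoc_latent_percent_mediated"] = \
                        le.mediation.percent_mediated
                    headline["mrdoc_latent_sum_ab"] = le.mediation.sum_ab
                    tables.append(lat.to_table(raw_thr))
                    manifest["mrdoc_constraints"] = list(le.constraint_tags)
                else:
                    manifest["mrdoc_latent_converged"] = False
                    log.warning("latent MR-DoC model did not converge; "
                                "table omitted")
            pd.concat(tables).to_csv(out / "mediation_mrdoc.csv",
                                     index=False)
            if config.run_stratified and state["included"]:
                strata = pair_median_split(std, "exposure")
                top = state["included"][0]
                _free, _constr, (chi2, df, p) = stratified_equality_test(
                    std, strata, mediators=[top],
                    fit_options={"seed": config.seed})
                pd.DataFrame([{"mediator": top, "chi2": chi2, "df": df,
                               "p": p}]).to_csv(
                    out / "stratified_tests.csv", index=False)
                headline["stratified_p"] = p
            manifest["stages_run"].append("mrdoc")

        # ---------------- report --------------------------------------
        if stage("report"):
            current = "report"
            log.info("stage: report")
            (out / "headline_effects.json").write_text(
                json.dumps(headline, indent=2, default=float))
            manifest["stages_run"].append("report")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {current}\nerror: {exc}\n")
        log.error("stage %s failed: %s", current, exc)
        log.removeHandler(fh)
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest["headline"] = headline
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    log.info("pipeline complete: %s", ", ".join(manifest["stages_run"]))
    log.removeHandler(fh)
    fh.close()
    return manifest
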