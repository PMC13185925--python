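"""MR-DoC models: Mendelian randomization combined with direction-of-
causation twin modelling, with and without mediators.

The polygenic score enters once per twin as an exogenous instrument
(cross-twin covariance fixed at 1.0 in MZ and 0.5 in DZ pairs, random
mating), with an instrumental path to the exposure and free pleiotropic
paths to outcome and mediators.  Additive-genetic (and retained
shared-environment) confounding among exposure, mediators and outcome
is carried by a triangular Cholesky structure over per-trait latent
factors whose cross-twin correlations are fixed at 1.0/0.5 (A) and 1.0
(C); nonshared-environment cross-trait covariances are fixed at zero,
which is the identification constraint that renders the pleiotropic
path estimable.  Mediation decompositions reuse the standardized
a / b / c' machinery of :mod:`twinmediate.mediation`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import TwinCohort
from .mediation import MediationEffects, compute_mediation_effects
from .model import PathModel, PathModelResults, lrt
from .ram import PathModelSpec
from .screen import median_split


@dataclass
class GroupDef:
    """One fitting group: zygosity-specific latent correlations plus an
    optional stratum suffix applied to stratified path labels."""

    name: str
    rho_a: float
    rho_pgs: float
    suffix: str = ""


DEFAULT_GROUPS = (GroupDef("MZ", 1.0, 1.0), GroupDef("DZ", 0.5, 0.5))


def _mask_mz_pgs(frame: pd.DataFrame, pgs: str) -> pd.DataFrame:
    """Enter the PGS once per monozygotic pair.

    MZ co-twins carry identical scores, which would make the implied
    pair covariance exactly singular; dropping the second twin's copy
    loses no information and keeps every pattern positive definite.
    """
    frame = frame.copy()
    frame[f"{pgs}_2"] = np.nan
    return frame


@dataclass
class MRDoCEffects:
    instrumental: tuple[float, float, tuple[float, float]]  # value, se, ci
    causal: tuple[float, float, tuple[float, float]] | None
    pleiotropic: pd.DataFrame  # per target: std, se, lower, upper, p
    mediation: MediationEffects | None
    constraint_tags: tuple[str, ...]

    @property
    def weak_instrument(self) -> bool:
        """True when the instrumental path is not clearly nonzero (its
        estimate within two standard errors of zero); causal and
        mediation estimates are then poorly identified by the PGS."""
        value, se, _ci = self.instrumental
        return abs(value) < 2 * se

    def summary(self) -> str:
        v, se, ci = self.instrumental
        lines = [
            "MR-DoC effects (standardized)", "=" * 54,
            f"instrumental (PGS->exposure): {v: .3f} "
            f"[{ci[0]: .3f}, {ci[1]: .3f}]"
            + ("  ** weak instrument **" if self.weak_instrument else ""),
        ]
        if self.causal is not None:
            cv, _cse, cci = self.causal
            lines.append(
                f"causal (exposure->outcome):  {cv: .3f} "
                f"[{cci[0]: .3f}, {cci[1]: .3f}]")
        lines.append("pleiotropic paths:")
        lines.append(self.pleiotropic.to_string(
            float_format=lambda x: f"{x: .3f}"))
        if self.mediation is not None:
            lines += ["", self.mediation.summary()]
        lines.append(f"constraints: {', '.join(self.constraint_tags)}")
        return "\n".join(lines)


def build_mrdoc_spec(*, pgs: str = "pgs", exposure: str = "exposure",
                     outcome: str = "outcome", mediators=(),
                     latent_factors: dict | None = None,
                     drop_c_mediators=None, free_re: bool = False,
                     free_pleiotropy: bool = True,
                     groups=DEFAULT_GROUPS, stratify_params=("a", "b", "cp"),
                     moments: pd.DataFrame | None = None) -> PathModelSpec:
    """Two-group (or stratified multi-group) MR-DoC twin specification.

    With no mediators this is the baseline model: instrumental path
    PGS -> exposure, causal path exposure -> outcome, pleiotropic path
    PGS -> outcome, and A/C Cholesky confounding between exposure and
    outcome.  ``mediators`` adds observed mediator slots (a, b and
    pleiotropic paths per mediator); ``latent_factors`` instead inserts
    latent factor mediators measured by indicator composites, each
    indicator keeping its own additive-genetic and nonshared residual.

    ``drop_c_mediators`` flags (per mediator slot) whether the shared-
    environment component of that slot is constrained to zero (default
    True for every slot, mirroring instability-driven constraints).
    ``free_re`` frees the exposure-outcome nonshared covariance instead
    of the pleiotropic path; freeing both is not identified.
    """
    if free_re and free_pleiotropy:
        raise ValueError(
            "freeing both the pleiotropic path and the exposure-outcome "
            "E covariance is not identified; fix one")
    mediators = list(mediators)
    if latent_factors and mediators:
        raise ValueError("give either observed mediators or latent factors")
    slots = list(latent_factors) if latent_factors else mediators
    if drop_c_mediators is None:
        drop_c = {s: True for s in slots}
    else:
        if len(drop_c_mediators) != len(slots):
            raise ValueError("drop_c_mediators length must match mediator slots")
        drop_c = dict(zip(slots, drop_c_mediators))

    indicators = ([i for ii in latent_factors.values() for i in ii]
                  if latent_factors else [])
    if latent_factors:
        for f, inds in latent_factors.items():
            if len(inds) < 2:
                raise ValueError(f"factor {f!r} needs at least two indicators")

    order = [exposure, *slots, outcome]      # Cholesky order
    c_traits = [exposure, *[s for s in slots if not drop_c[s]], outcome]

    per_twin_obs = [pgs, exposure, *(indicators if latent_factors else slots),
                    outcome]
    observed = [f"{v}_{i}" for i in (1, 2) for v in per_twin_obs]
    latent = []
    for i in (1, 2):
        latent += [f"GA_{t}_{i}" for t in order]
        latent += [f"GC_{t}_{i}" for t in c_traits]
        if latent_factors:
            latent += [f"{f}_{i}" for f in latent_factors]
            latent += [f"GA_{ind}_{i}" for ind in indicators]
    gdefs = list(groups)
    spec = PathModelSpec(observed, latent, groups=[g.name for g in gdefs])

    def vstart(v):
        return float(moments.loc[v, "var"]) if moments is not None else 1.0

    def mstart(v):
        return float(moments.loc[v, "mean"]) if moments is not None else 0.0

    def slot_var(i, s):
        """Name of the variable carrying mediator slot s for twin i."""
        return f"{s}_{i}"

    # --- per-twin structural paths and variances ----------------------
    for i in (1, 2):
        x_i, y_i, pgs_i = f"{exposure}_{i}", f"{outcome}_{i}", f"{pgs}_{i}"
        spec.add_path(pgs_i, x_i, label="f", start=0.1)
        spec.add_path(pgs_i, y_i, **(
            dict(label="p__outcome", start=0.05) if free_pleiotropy
            else dict(value=0.0)))
        for s in slots:
            spec.add_path(pgs_i, slot_var(i, s), label=f"p__{s}", start=0.02)
        # A Cholesky loadings (labels shared across twins and groups)
        for k, t in enumerate(order):
            for t_src in order[: k + 1]:
                start = 0.5 if t_src == t else 0.1
                spec.add_path(f"GA_{t_src}_{i}", slot_var(i, t) if t in slots
                              else f"{t}_{i}",
                              label=f"ach__{t}__{t_src}", start=start)
        for k, t in enumerate(c_traits):
            for t_src in c_traits[: k + 1]:
                start = 0.4 if t_src == t else 0.1
                spec.add_path(f"GC_{t_src}_{i}", slot_var(i, t) if t in slots
                              else f"{t}_{i}",
                              label=f"cch__{t}__{t_src}", start=start)
        # E residual variances (cross-trait E covariances fixed at zero)
        spec.add_var(x_i, label="ve__exposure", start=0.4 * vstart(exposure),
                     lower=1e-8)
        spec.add_var(y_i, label="ve__outcome", start=0.4 * vstart(outcome),
                     lower=1e-8)
        if free_re:
            spec.add_cov(x_i, y_i, label="re_xy", start=0.05)
        spec.add_mean(x_i, label="mu__exposure", start=mstart(exposure))
        spec.add_mean(y_i, label="mu__outcome", start=mstart(outcome))
        spec.add_mean(pgs_i, label="mu__pgs", start=mstart(pgs))
        if latent_factors:
            for f, inds in latent_factors.items():
                spec.add_var(f"{f}_{i}", label=f"ve__{f}", start=0.3,
                             lower=1e-8)
                for k, ind in enumerate(inds):
                    if k == 0:
                        spec.add_path(f"{f}_{i}", f"{ind}_{i}", value=1.0)
                    else:
                        spec.add_path(f"{f}_{i}", f"{ind}_{i}",
                                      label=f"lam__{ind}", start=0.8)
                    spec.add_path(f"GA_{ind}_{i}", f"{ind}_{i}",
                                  label=f"au__{ind}", start=0.3)
                    spec.add_var(f"{ind}_{i}", label=f"ve__{ind}",
                                 start=0.4 * vstart(ind), lower=1e-8)
                    spec.add_mean(f"{ind}_{i}", label=f"mu__{ind}",
                                  start=mstart(ind))
        else:
            for s in slots:
                spec.add_var(f"{s}_{i}", label=f"ve__{s}",
                             start=0.4 * vstart(s), lower=1e-8)
                spec.add_mean(f"{s}_{i}", label=f"mu__{s}", start=mstart(s))

    # --- mediation paths, possibly stratum-specific --------------------
    done: set[tuple] = set()
    for g in gdefs:
        sfx = g.suffix

        def lab(base, stratified):
            return base + (sfx if stratified else "")

        key = (sfx,)
        if key in done:
            continue
        done.add(key)
        grp = [gg.name for gg in gdefs if gg.suffix == sfx]
        for gname in grp:
            for i in (1, 2):
                x_i, y_i = f"{exposure}_{i}", f"{outcome}_{i}"
                for s in slots:
                    spec.add_path(x_i, slot_var(i, s),
                                  label=lab(f"a__{s}", "a" in stratify_params),
                                  start=0.2, group=gname)
                    spec.add_path(slot_var(i, s), y_i,
                                  label=lab(f"b__{s}", "b" in stratify_params),
                                  start=0.1, group=gname)
                spec.add_path(x_i, y_i,
                              label=lab("cp", "cp" in stratify_params),
                              start=0.1, group=gname)

    # --- latent covariance structure per group -------------------------
    for g in gdefs:
        for t in order:
            for i in (1, 2):
                spec.add_var(f"GA_{t}_{i}", value=1.0, group=g.name)
            spec.add_cov(f"GA_{t}_1", f"GA_{t}_2", value=g.rho_a, group=g.name)
        for t in c_traits:
            for i in (1, 2):
                spec.add_var(f"GC_{t}_{i}", value=1.0, group=g.name)
            spec.add_cov(f"GC_{t}_1", f"GC_{t}_2", value=1.0, group=g.name)
        if latent_factors:
            for ind in indicators:
                for i in (1, 2):
                    spec.add_var(f"GA_{ind}_{i}", value=1.0, group=g.name)
                spec.add_cov(f"GA_{ind}_1", f"GA_{ind}_2", value=g.rho_a,
                             group=g.name)
        spec.add_var(f"{pgs}_1", label="v_pgs", start=vstart(pgs), lower=1e-8,
                     group=g.name)
        spec.add_var(f"{pgs}_2", label="v_pgs", start=vstart(pgs), lower=1e-8,
                     group=g.name)
        spec.add_cov(f"{pgs}_1", f"{pgs}_2", label="v_pgs", scale=g.rho_pgs,
                     group=g.name)
    return spec


class MRDoCModel:
    """MR-DoC model on a twin cohort (baseline or mediation variant).

    ``mediators`` gives observed mediator columns; ``latent_factors``
    maps factor names to indicator columns for the latent variant; with
    neither, the baseline exposure/outcome model is fitted.
    """

    def __init__(self, cohort: TwinCohort, *, pgs: str = "pgs",
                 exposure: str = "exposure", outcome: str = "outcome",
                 mediators=(), latent_factors: dict | None = None,
                 drop_c_mediators=None, free_re: bool = False,
                 free_pleiotropy: bool = True, dz_pgs_rho: float = 0.5):
        self.cohort = cohort
        self.names = dict(pgs=pgs, exposure=exposure, outcome=outcome)
        self.mediators = list(mediators)
        self.latent_factors = latent_factors
        self.slots = (list(latent_factors) if latent_factors
                      else self.mediators)
        groups = (GroupDef("MZ", 1.0, 1.0), GroupDef("DZ", 0.5, dz_pgs_rho))
        data = cohort.zygosity_groups()
        for g, frame in data.items():
            if len(frame) == 0:
                raise ValueError(f"zygosity group {g!r} is empty")
        data["MZ"] = _mask_mz_pgs(data["MZ"], pgs)
        indicators = ([i for ii in latent_factors.values() for i in ii]
                      if latent_factors else [])
        per_twin = [pgs, exposure, *(indicators or self.mediators), outcome]
        moments = pd.DataFrame({
            "var": cohort.data[per_twin].var(ddof=1),
            "mean": cohort.data[per_twin].mean(),
        })
        drop_c = drop_c_mediators
        self.constraint_tags = tuple(
            [f"re_xy={'free' if free_re else '0'}",
             f"pleiotropy={'free' if free_pleiotropy else '0'}"]
            + [f"c_{s}=0" for s in self.slots
               if drop_c is None or drop_c[self.slots.index(s)]])
        self.spec = build_mrdoc_spec(
            pgs=pgs, exposure=exposure, outcome=outcome,
            mediators=self.mediators, latent_factors=latent_factors,
            drop_c_mediators=drop_c, free_re=free_re,
            free_pleiotropy=free_pleiotropy, groups=groups, moments=moments)
        self.model = PathModel(self.spec, data)
        self.free_pleiotropy = free_pleiotropy

    def fit(self, **kw) -> "MRDoCResults":
        return MRDoCResults(self, self.model.fit(**kw))


class MRDoCResults:
    def __init__(self, model: MRDoCModel, fitres: PathModelResults):
        self.model = model
        self.fitres = fitres

    @property
    def converged(self) -> bool:
        return self.fitres.converged

    def effects(self, threshold: float = 0.003) -> MRDoCEffects:
        if not self.fitres.converged:
            raise RuntimeError("MR-DoC effects require a converged fit")
        fr = self.fitres

        def std(label):
            fn = fr.std_path_fn(label)
            return fr.delta_method(lambda s: fn(s.to_numpy()))

        instrumental = std("f")
        pleio_rows = []
        if self.model.free_pleiotropy:
            targets = ["outcome", *self.model.slots]
            for t in targets:
                v, se, ci = std(f"p__{t}")
                from scipy import stats as _st
                p = 2 * _st.norm.sf(abs(v) / se) if se > 0 else 1.0
                pleio_rows.append({"target": t, "std": v, "se": se,
                                   "lower": ci[0], "upper": ci[1], "p": p})
        pleio = pd.DataFrame(pleio_rows).set_index("target") if pleio_rows \
            else pd.DataFrame()
        mediation = None
        causal = None
        if self.model.slots:
            pairs = [(s, f"a__{s}", f"b__{s}") for s in self.model.slots]
            mediation = compute_mediation_effects(
                fr, pairs, "cp", threshold=threshold)
        else:
            causal = std("cp")
        return MRDoCEffects(
            instrumental=instrumental, causal=causal, pleiotropic=pleio,
            mediation=mediation, constraint_tags=self.model.constraint_tags)

    def summary(self, threshold: float = 0.003) -> str:
        return (self.effects(threshold).summary() + "\n\n"
                + self.fitres.summary())

    def to_table(self, threshold: float = 0.003) -> pd.DataFrame:
        """Flat results table: a, b, c', ab and pleiotropic paths with CIs."""
        eff = self.effects(threshold)
        rows = []
        if eff.mediation is not None:
            t = eff.mediation.table
            for m in t.index:
                rows.append({
                    "mediator": m,
                    "a": t.loc[m, "a"], "a_lower": t.loc[m, "a_lower"],
                    "a_upper": t.loc[m, "a_upper"],
                    "b": t.loc[m, "b"], "b_lower": t.loc[m, "b_lower"],
                    "b_upper": t.loc[m, "b_upper"],
                    "c_prime": eff.mediation.c_prime,
                    "c_prime_lower": eff.mediation.ci_c_prime[0],
                    "c_prime_upper": eff.mediation.ci_c_prime[1],
                    "ab": t.loc[m, "ab"], "ab_lower": t.loc[m, "ab_lower"],
                    "ab_upper": t.loc[m, "ab_upper"],
                    "pleiotropic": eff.pleiotropic.loc[m, "std"]
                    if m in eff.pleiotropic.index else np.nan,
                    "constraints": ";".join(eff.constraint_tags),
                    "minus2ll": self.fitres.minus2ll,
                    "aic": self.fitres.aic,
                })
        else:
            v, _se, ci = eff.causal
            fv, _fse, fci = eff.instrumental
            rows.append({
                "mediator": "(baseline)", "causal": v, "causal_lower": ci[0],
                "causal_upper": ci[1], "instrumental": fv,
                "instrumental_lower": fci[0], "instrumental_upper": fci[1],
                "pleiotropic": eff.pleiotropic["std"].get("outcome", np.nan),
                "constraints": ";".join(eff.constraint_tags),
                "minus2ll": self.fitres.minus2ll, "aic": self.fitres.aic,
            })
        return pd.DataFrame(rows)


# ----------------------------------------------------------------------

def pair_median_split(cohort: TwinCohort, trait: str = "exposure"):
    """Pair-level high/low stratification by pair-mean trait vs the median.

    Keeps families intact: the pair mean of the trait is compared with
    the median of pair means.  Returns a Series indexed by family_id.
    """
    wide = cohort.pairs_wide([trait])
    pair_mean = wide[[f"{trait}_1", f"{trait}_2"]].mean(axis=1)
    labels, _counts = median_split(pair_mean)
    labels.index = wide["family_id"]
    return labels


def stratified_equality_test(cohort: TwinCohort, strata: pd.Series, *,
                             mediators=(), latent_factors=None,
                             stratify_params=("a", "b", "cp"),
                             fit_options=None, **model_kw):
    """Compare stratified MR-DoC mediation models by likelihood ratio.

    ``strata`` maps family_id to 'high'/'low'.  A four-group model
    (zygosity x stratum) is fitted twice: once with the mediation paths
    in ``stratify_params`` free per stratum, once with them equated; the
    LRT of the constrained against the free model tests moderation of
    mediation by stratum.

    Returns ``(free_results, constrained_results, (chi2, df, p))``.
    """
    fit_options = fit_options or {}
    mediators = list(mediators)
    slots = list(latent_factors) if latent_factors else mediators
    if not slots:
        raise ValueError("stratified test requires mediator slots")
    names = dict(pgs="pgs", exposure="exposure", outcome="outcome")
    names.update({k: v for k, v in model_kw.items() if k in names})
    wide = cohort.pairs_wide()
    lab = wide["family_id"].map(strata)
    data = {}
    for zyg in ("MZ", "DZ"):
        zmask = (wide["zygosity"] == "MZ") if zyg == "MZ" else \
            (wide["zygosity"] != "MZ")
        for s in ("high", "low"):
            frame = wide[zmask & (lab == s)]
            if len(frame) == 0:
                raise ValueError(f"empty cell: zygosity {zyg}, stratum {s!r}")
            if zyg == "MZ":
                frame = _mask_mz_pgs(frame, names["pgs"])
            data[f"{zyg}_{s}"] = frame
    indicators = ([i for ii in latent_factors.values() for i in ii]
                  if latent_factors else [])
    per_twin = [names["pgs"], names["exposure"],
                *(indicators or mediators), names["outcome"]]
    moments = pd.DataFrame({
        "var": cohort.data[per_twin].var(ddof=1),
        "mean": cohort.data[per_twin].mean(),
    })

    def groups(suffixed: bool):
        out = []
        for zyg, rho in (("MZ", 1.0), ("DZ", 0.5)):
            for s in ("high", "low"):
                sfx = f"__{s}" if suffixed else ""
                out.append(GroupDef(f"{zyg}_{s}", rho,
                                    1.0 if zyg == "MZ" else 0.5, sfx))
        return out

    results = {}
    for tag, suffixed in (("constrained", False), ("free", True)):
        spec = build_mrdoc_spec(
            pgs=names["pgs"], exposure=names["exposure"],
            outcome=names["outcome"], mediators=mediators,
            latent_factors=latent_factors, groups=groups(suffixed),
            stratify_params=stratify_params if suffixed else (),
            moments=moments,
            **{k: v for k, v in model_kw.items() if k not in names})
        model = PathModel(spec, data)
        start = None
        if tag == "free":  # warm start: constrained solution replicated
            constrained = results["constrained"].params
            start = np.array([
                constrained[lab] if lab in constrained.index
                else constrained[lab.rsplit("__high", 1)[0]
                                 .rsplit("__low", 1)[0]]
                for lab in spec.free_labels])
        results[tag] = model.fit(compute_se=False, start_values=start,
                                 **fit_options)
    test = lrt(results["free"], results["constrained"])
    return results["free"], results["constrained"], test
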