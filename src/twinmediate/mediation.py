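"""Phenotypic mediation SEM: simple, parallel-observed and latent-factor.

Models are fitted on individual-level rows by FIML; the non-independence
of twins within families is handled with a family-clustered (CR1)
sandwich covariance.  Effects follow the classical decomposition:
a (exposure -> mediator), b (mediator -> outcome), direct effect c',
indirect effects ab, total indirect sum(ab), total effect
c = c' + sum(ab), and percent mediated 100 * sum(ab) / (sum(ab) + c').
All reported effects are standardized by model-implied SDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import TwinCohort
from .model import PathModel, PathModelResults
from .ram import PathModelSpec


@dataclass
class MediationEffects:
    """Standardized mediation decomposition with delta-method intervals."""

    table: pd.DataFrame              # per mediator: a, b, ab with se/CI/p
    c_prime: float
    se_c_prime: float
    ci_c_prime: tuple[float, float]
    p_c_prime: float
    sum_ab: float
    se_sum_ab: float
    ci_sum_ab: tuple[float, float]
    p_sum_ab: float
    c_total: float
    percent_mediated: float
    threshold: float

    @property
    def significant_indirect(self) -> pd.Series:
        return self.table["p_ab"] < self.threshold

    def summary(self) -> str:
        lines = ["Mediation decomposition (standardized)", "=" * 54]
        lines.append(self.table.to_string(
            float_format=lambda v: f"{v: .3f}"))
        pm = (f"{self.percent_mediated:.1f}%" if np.isfinite(self.percent_mediated)
              else "undefined")
        lines += [
            "-" * 54,
            f"c' (direct)  = {self.c_prime: .3f} "
            f"[{self.ci_c_prime[0]: .3f}, {self.ci_c_prime[1]: .3f}] "
            f"p = {self.p_c_prime:.4g}",
            f"sum(ab)      = {self.sum_ab: .3f} "
            f"[{self.ci_sum_ab[0]: .3f}, {self.ci_sum_ab[1]: .3f}] "
            f"p = {self.p_sum_ab:.4g}",
            f"c (total)    = {self.c_total: .3f}",
            f"percent mediated = {pm}  "
            f"(significance threshold {self.threshold:g})",
        ]
        return "\n".join(lines)


def percent_mediated(sum_ab: float, c_prime: float) -> float:
    """Share of the total effect carried by mediators.

    ``100 * sum_ab / (sum_ab + c_prime)``; undefined (nan) when the
    total effect is zero.
    """
    denom = sum_ab + c_prime
    if abs(denom) < 1e-12:
        return float("nan")
    return 100.0 * sum_ab / denom


def _wald(value, se, alpha=0.05):
    z = stats.norm.ppf(1 - alpha / 2)
    p = 2 * stats.norm.sf(abs(value) / se) if se > 0 else (0.0 if value else 1.0)
    return (value - z * se, value + z * se), p


def compute_mediation_effects(fitres: PathModelResults, pairs, cp_label: str,
                              threshold: float = 0.003, robust: bool = False,
                              group: str | None = None) -> MediationEffects:
    """Mediation decomposition from a fitted path model.

    ``pairs`` is a list of ``(name, a_label, b_label)`` triples naming
    the indirect pathways.  Products and sums are standardized first and
    carried through the delta method; ``robust`` selects the clustered
    covariance when available.
    """
    a_fns = {n: fitres.std_path_fn(a, group) for n, a, _b in pairs}
    b_fns = {n: fitres.std_path_fn(b, group) for n, _a, b in pairs}
    cp_fn = fitres.std_path_fn(cp_label, group)

    def dm(fn):
        value, se, ci = fitres.delta_method(
            lambda s: fn(s.to_numpy()), robust=robust)
        _ci, p = _wald(value, se)
        return value, se, ci, p

    rows = []
    for name, _a, _b in pairs:
        av, ase, aci, ap = dm(a_fns[name])
        bv, bse, bci, bp = dm(b_fns[name])
        abv, abse, abci, abp = dm(
            lambda t, n=name: a_fns[n](t) * b_fns[n](t))
        rows.append({
            "mediator": name, "a": av, "se_a": ase, "a_lower": aci[0],
            "a_upper": aci[1], "p_a": ap,
            "b": bv, "se_b": bse, "b_lower": bci[0], "b_upper": bci[1],
            "p_b": bp,
            "ab": abv, "se_ab": abse, "ab_lower": abci[0],
            "ab_upper": abci[1], "p_ab": abp,
        })
    table = pd.DataFrame(rows).set_index("mediator")

    cpv, cpse, cpci, cpp = dm(cp_fn)

    def total_indirect(t):
        return sum(a_fns[n](t) * b_fns[n](t) for n, _a, _b in pairs)

    sv, sse, sci, sp = dm(total_indirect)
    c_total = cpv + sv
    percent = percent_mediated(sv, cpv)
    return MediationEffects(
        table=table, c_prime=cpv, se_c_prime=cpse, ci_c_prime=cpci,
        p_c_prime=cpp, sum_ab=sv, se_sum_ab=sse, ci_sum_ab=sci, p_sum_ab=sp,
        c_total=c_total, percent_mediated=percent, threshold=threshold,
    )


# ----------------------------------------------------------------------
# spec builders (individual-level, single group)

def build_simple_mediation_spec(exposure: str, mediator: str, outcome: str,
                                moments: pd.DataFrame | None = None
                                ) -> PathModelSpec:
    """x -> m -> y with direct path; free residuals and means."""
    names = (exposure, mediator, outcome)
    if len(set(names)) != 3:
        raise ValueError("exposure, mediator and outcome names must be distinct")
    return build_parallel_mediation_spec(exposure, [mediator], outcome, moments)


def build_parallel_mediation_spec(exposure: str, mediators, outcome: str,
                                  moments: pd.DataFrame | None = None
                                  ) -> PathModelSpec:
    """Parallel observed mediators with correlated residuals."""
    mediators = list(mediators)
    names = [exposure, *mediators, outcome]
    if len(set(names)) != len(names):
        raise ValueError("variable names must be distinct")
    if not mediators:
        raise ValueError("at least one mediator required")
    spec = PathModelSpec(names, groups=("all",))

    def vstart(v):
        return float(moments.loc[v, "var"]) if moments is not None else 1.0

    def mstart(v):
        return float(moments.loc[v, "mean"]) if moments is not None else 0.0

    spec.add_var(exposure, label="v_x", start=vstart(exposure), lower=1e-8)
    spec.add_mean(exposure, label="mu_x", start=mstart(exposure))
    for m in mediators:
        spec.add_path(exposure, m, label=f"a__{m}", start=0.1)
        spec.add_path(m, outcome, label=f"b__{m}", start=0.1)
        spec.add_var(m, label=f"v__{m}", start=0.8 * vstart(m), lower=1e-8)
        spec.add_mean(m, label=f"mu__{m}", start=mstart(m))
    for i, mi in enumerate(mediators):
        for mj in mediators[i + 1:]:
            spec.add_cov(mi, mj, label=f"rcov__{mi}__{mj}", start=0.05)
    spec.add_path(exposure, outcome, label="cp", start=0.1)
    spec.add_var(outcome, label="v_y", start=0.8 * vstart(outcome), lower=1e-8)
    spec.add_mean(outcome, label="mu_y", start=mstart(outcome))
    return spec


def build_latent_factor_mediation_spec(exposure: str, factors: dict,
                                       outcome: str,
                                       moments: pd.DataFrame | None = None
                                       ) -> PathModelSpec:
    """Two (or more) latent factors as parallel mediators.

    ``factors`` maps factor name to its indicator list; each factor is
    scaled by its first indicator (marker loading fixed to 1).
    Standardized output is invariant to this scaling choice.
    """
    for f, inds in factors.items():
        if len(inds) < 2:
            raise ValueError(
                f"factor {f!r} has {len(inds)} indicator(s); at least two "
                "are needed for identification")
    indicators = [i for inds in factors.values() for i in inds]
    observed = [exposure, *indicators, outcome]
    if len(set(observed)) != len(observed):
        raise ValueError("variable names must be distinct")
    spec = PathModelSpec(observed, latent=list(factors), groups=("all",))

    def vstart(v):
        return float(moments.loc[v, "var"]) if moments is not None else 1.0

    def mstart(v):
        return float(moments.loc[v, "mean"]) if moments is not None else 0.0

    spec.add_var(exposure, label="v_x", start=vstart(exposure), lower=1e-8)
    spec.add_mean(exposure, label="mu_x", start=mstart(exposure))
    for f, inds in factors.items():
        for k, ind in enumerate(inds):
            if k == 0:
                spec.add_path(f, ind, value=1.0)  # marker scaling
            else:
                spec.add_path(f, ind, label=f"lam__{ind}", start=0.8)
            spec.add_var(ind, label=f"v__{ind}", start=0.5 * vstart(ind),
                         lower=1e-8)
            spec.add_mean(ind, label=f"mu__{ind}", start=mstart(ind))
        spec.add_path(exposure, f, label=f"a__{f}", start=0.1)
        spec.add_path(f, outcome, label=f"b__{f}", start=0.1)
        spec.add_var(f, label=f"vd__{f}", start=0.4 * vstart(inds[0]),
                     lower=1e-8)
    fnames = list(factors)
    for i, fi in enumerate(fnames):
        for fj in fnames[i + 1:]:
            spec.add_cov(fi, fj, label=f"rcov__{fi}__{fj}", start=0.1)
    spec.add_path(exposure, outcome, label="cp", start=0.1)
    spec.add_var(outcome, label="v_y", start=0.8 * vstart(outcome), lower=1e-8)
    spec.add_mean(outcome, label="mu_y", start=mstart(outcome))
    return spec


# ----------------------------------------------------------------------

class MediationModel:
    """Phenotypic mediation SEM on individual-level twin data.

    Parameters
    ----------
    data
        Cohort or DataFrame with one row per individual.
    exposure, outcome
        Column names.
    mediators
        List of mediator columns (``kind='simple'`` takes exactly one).
    kind
        ``'simple'``, ``'parallel'`` or ``'latent'``.
    factors
        For ``kind='latent'``: mapping factor name -> indicator columns.
    """

    def __init__(self, data: TwinCohort | pd.DataFrame, exposure: str,
                 outcome: str, mediators=None, kind: str = "simple",
                 factors: dict | None = None, cluster: str = "family_id"):
        df = data.data if isinstance(data, TwinCohort) else data
        self.kind = kind
        self.exposure, self.outcome = exposure, outcome
        self.cluster_col = cluster if cluster in df.columns else None
        if kind == "latent":
            if not factors:
                raise ValueError("kind='latent' requires a factors mapping")
            self.factors = factors
            cols = [exposure, *[i for ii in factors.values() for i in ii],
                    outcome]
            self.pairs_meta = [(f, f"a__{f}", f"b__{f}") for f in factors]
        else:
            mediators = [mediators] if isinstance(mediators, str) else list(
                mediators or [])
            if kind == "simple" and len(mediators) != 1:
                raise ValueError("kind='simple' takes exactly one mediator")
            if not mediators:
                raise ValueError("no mediators supplied")
            self.mediators = mediators
            cols = [exposure, *mediators, outcome]
            self.pairs_meta = [(m, f"a__{m}", f"b__{m}") for m in mediators]
        keep = cols + ([self.cluster_col] if self.cluster_col else [])
        self.frame = df[keep].reset_index(drop=True)
        moments = pd.DataFrame({
            "var": self.frame[cols].var(ddof=1),
            "mean": self.frame[cols].mean(),
        })
        if kind == "latent":
            self.spec = build_latent_factor_mediation_spec(
                exposure, factors, outcome, moments)
        elif kind == "parallel":
            self.spec = build_parallel_mediation_spec(
                exposure, self.mediators, outcome, moments)
        else:
            self.spec = build_simple_mediation_spec(
                exposure, self.mediators[0], outcome, moments)
        self.model = PathModel(self.spec, {"all": self.frame})

    def fit(self, robust: bool = True, **kw) -> "MediationResults":
        cluster = None
        if robust and self.cluster_col is not None:
            cluster = {"all": self.frame[self.cluster_col].to_numpy()}
        res = self.model.fit(cluster=cluster, **kw)
        return MediationResults(self, res, robust=cluster is not None)


class MediationResults:
    def __init__(self, model: MediationModel, fitres: PathModelResults,
                 robust: bool):
        self.model = model
        self.fitres = fitres
        self.robust = robust

    @property
    def converged(self) -> bool:
        return self.fitres.converged

    def effects(self, threshold: float = 0.003,
                robust: bool | None = None) -> MediationEffects:
        if not self.fitres.converged:
            raise RuntimeError("mediation effects require a converged fit")
        robust = self.robust if robust is None else robust
        return compute_mediation_effects(
            self.fitres, self.model.pairs_meta, "cp",
            threshold=threshold, robust=robust)

    def summary(self, threshold: float = 0.003) -> str:
        return self.effects(threshold).summary() + "\n\n" + self.fitres.summary()
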