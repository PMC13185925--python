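"""Univariate and bivariate ACE twin models.

Trait variance is decomposed into additive-genetic (A), shared-
environment (C) and nonshared-environment (E) components using the
classical twin design: latent A factors correlate 1.0 across
monozygotic and 0.5 across dizygotic co-twins, C correlates 1.0 in
both, E is uncorrelated.  Components enter as path coefficients
(a, c, e) whose squares are variances, so no negative-variance boundary
arises; proportions are reported with delta-method intervals.  The
bivariate model uses a correlated-factors parameterization that yields
the genetic, shared- and nonshared-environmental correlations
(r_g, r_c, r_e) directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import TwinCohort
from .model import PathModel, PathModelResults
from .ram import PathModelSpec

_SUBMODELS = {"ACE": ("a", "c", "e"), "AE": ("a", "e"), "CE": ("c", "e"), "E": ("e",)}


@dataclass
class ACEEstimates:
    """Variance proportions (and, for bivariate fits, component correlations)."""

    model_tag: str
    a2: float
    c2: float
    e2: float
    ci_a2: tuple[float, float]
    ci_c2: tuple[float, float]
    ci_e2: tuple[float, float]
    r_g: float | None = None
    r_c: float | None = None
    r_e: float | None = None
    ci_r_g: tuple[float, float] | None = None
    ci_r_c: tuple[float, float] | None = None
    ci_r_e: tuple[float, float] | None = None
    by_trait: dict = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        out = {"a2": self.a2, "c2": self.c2, "e2": self.e2}
        if self.r_g is not None:
            out.update({"r_g": self.r_g, "r_c": self.r_c, "r_e": self.r_e})
        return pd.Series(out)


def falconer_oracle(r_mz: float, r_dz: float):
    """Falconer's closed-form ACE decomposition from twin correlations.

    ``h2 = 2 (r_mz - r_dz)``, ``c2 = 2 r_dz - r_mz``, ``e2 = 1 - r_mz``.
    Returns ``(h2, c2, e2, in_range)`` where ``in_range`` flags whether
    all three proportions fall in [0, 1].
    """
    if not (-1 <= r_mz <= 1 and -1 <= r_dz <= 1):
        raise ValueError("twin correlations must lie in [-1, 1]")
    h2 = 2.0 * (r_mz - r_dz)
    c2 = 2.0 * r_dz - r_mz
    e2 = 1.0 - r_mz
    in_range = all(0 <= v <= 1 for v in (h2, c2, e2))
    return h2, c2, e2, in_range


def concordance_summary(cohort: TwinCohort, trait: str,
                        threshold_sd: float = 1.0) -> float:
    """Fraction of complete pairs differing by more than ``threshold_sd``
    sample standard deviations on ``trait`` (a discordance rate)."""
    wide = cohort.pairs_wide([trait])
    d = (wide[f"{trait}_1"] - wide[f"{trait}_2"]).dropna()
    if len(d) == 0:
        raise ValueError(f"no complete pairs for trait {trait!r}")
    sd = cohort.data[trait].std(ddof=1)
    return float((d.abs() > threshold_sd * sd).mean())


def _check_two_groups(groups: dict[str, pd.DataFrame]):
    for g, frame in groups.items():
        if len(frame) == 0:
            raise ValueError(
                f"zygosity group {g!r} is empty: ACE models need both MZ and "
                "DZ pairs for identification"
            )


def _proportion_fn(which: str, comps: tuple[str, ...]):
    def fn(s: pd.Series) -> float:
        total = sum(s[c] ** 2 for c in comps)
        return (s[which] ** 2 / total) if which in comps else 0.0
    return fn


class UnivariateACE:
    """One-trait ACE model on MZ/DZ pairs, fitted by two-group FIML.

    ``submodel`` selects the nested variant (ACE, AE, CE or E); nested
    fits can be compared with :func:`twinmediate.model.lrt`.
    """

    def __init__(self, cohort: TwinCohort, trait: str, submodel: str = "ACE"):
        if submodel not in _SUBMODELS:
            raise ValueError(f"unknown submodel {submodel!r}")
        if trait not in cohort.data.columns:
            raise ValueError(f"trait {trait!r} not in cohort")
        self.cohort = cohort
        self.trait = trait
        self.submodel = submodel
        self.groups = cohort.zygosity_groups([trait])
        _check_two_groups(self.groups)
        self.spec = self._build_spec()
        self.model = PathModel(self.spec, self.groups)

    def _build_spec(self) -> PathModelSpec:
        t = self.trait
        comps = _SUBMODELS[self.submodel]
        observed = [f"{t}_1", f"{t}_2"]
        latent = [f"{k.upper()}{i}" for i in (1, 2) for k in comps]
        spec = PathModelSpec(observed, latent, groups=("MZ", "DZ"))
        sd = float(self.cohort.data[t].std(ddof=1))
        start = sd / np.sqrt(len(comps))
        for i in (1, 2):
            for k in comps:
                spec.add_path(f"{k.upper()}{i}", f"{t}_{i}", label=k, start=start)
                spec.add_var(f"{k.upper()}{i}", value=1.0)
            spec.add_mean(f"{t}_{i}", label="mu",
                          start=float(self.cohort.data[t].mean()))
        if "a" in comps:
            spec.add_cov("A1", "A2", value=1.0, group="MZ")
            spec.add_cov("A1", "A2", value=0.5, group="DZ")
        if "c" in comps:
            spec.add_cov("C1", "C2", value=1.0)
        return spec

    def fit(self, **kw) -> "ACEResults":
        res = self.model.fit(**kw)
        return ACEResults(self, res)


class ACEResults:
    """Results wrapper translating path coefficients into ACE proportions."""

    def __init__(self, model: UnivariateACE, fit: PathModelResults):
        self.model = model
        self.fitres = fit
        self.comps = _SUBMODELS[model.submodel]

    @property
    def converged(self) -> bool:
        return self.fitres.converged

    def estimates(self, alpha: float = 0.05) -> ACEEstimates:
        vals, cis = {}, {}
        for k in ("a", "c", "e"):
            if k in self.comps:
                v, _se, ci = self.fitres.delta_method(
                    _proportion_fn(k, self.comps), alpha=alpha)
            else:
                v, ci = 0.0, (0.0, 0.0)
            vals[k], cis[k] = v, (max(ci[0], 0.0), min(ci[1], 1.0))
        return ACEEstimates(
            model_tag=self.model.submodel,
            a2=vals["a"], c2=vals["c"], e2=vals["e"],
            ci_a2=cis["a"], ci_c2=cis["c"], ci_e2=cis["e"],
        )

    def summary(self) -> str:
        est = self.estimates()
        head = (f"Univariate {self.model.submodel} model for "
                f"{self.model.trait!r}\n"
                f"a2 = {est.a2:.3f} {est.ci_a2}, c2 = {est.c2:.3f} "
                f"{est.ci_c2}, e2 = {est.e2:.3f} {est.ci_e2}\n")
        return head + self.fitres.summary()


class BivariateACE:
    """Correlated-factors bivariate ACE model for two traits.

    Yields per-trait variance decompositions plus the cross-trait
    genetic, shared-environmental and nonshared correlations.
    """

    def __init__(self, cohort: TwinCohort, trait1: str, trait2: str):
        for t in (trait1, trait2):
            if t not in cohort.data.columns:
                raise ValueError(f"trait {t!r} not in cohort")
        if trait1 == trait2:
            raise ValueError("traits must differ")
        self.cohort = cohort
        self.traits = (trait1, trait2)
        wide = cohort.zygosity_groups([trait1, trait2])
        _check_two_groups(wide)
        self.groups = wide
        self.spec = self._build_spec()
        self.model = PathModel(self.spec, self.groups)

    def _build_spec(self) -> PathModelSpec:
        t1, t2 = self.traits
        observed = [f"{t}_{i}" for i in (1, 2) for t in self.traits]
        latent = [f"{k}_{t}_{i}" for i in (1, 2) for t in self.traits
                  for k in ("A", "C", "E")]
        spec = PathModelSpec(observed, latent, groups=("MZ", "DZ"))
        data = self.cohort.data
        for t, tag in zip(self.traits, ("x", "y")):
            sd = float(data[t].std(ddof=1))
            for i in (1, 2):
                for k in ("a", "c", "e"):
                    spec.add_path(f"{k.upper()}_{t}_{i}", f"{t}_{i}",
                                  label=f"{k}_{tag}", start=sd / np.sqrt(3))
                    spec.add_var(f"{k.upper()}_{t}_{i}", value=1.0)
                spec.add_mean(f"{t}_{i}", label=f"mu_{tag}",
                              start=float(data[t].mean()))
            # same-trait cross-twin component covariances
            spec.add_cov(f"A_{t}_1", f"A_{t}_2", value=1.0, group="MZ")
            spec.add_cov(f"A_{t}_1", f"A_{t}_2", value=0.5, group="DZ")
            spec.add_cov(f"C_{t}_1", f"C_{t}_2", value=1.0)
        rbounds = dict(lower=-0.999, upper=0.999, start=0.3)
        for i in (1, 2):  # within-twin cross-trait correlations
            spec.add_cov(f"A_{t1}_{i}", f"A_{t2}_{i}", label="r_g", **rbounds)
            spec.add_cov(f"C_{t1}_{i}", f"C_{t2}_{i}", label="r_c", **rbounds)
            spec.add_cov(f"E_{t1}_{i}", f"E_{t2}_{i}", label="r_e", **rbounds)
        for i, j in ((1, 2), (2, 1)):  # cross-twin cross-trait
            spec.add_cov(f"A_{t1}_{i}", f"A_{t2}_{j}", label="r_g", scale=1.0,
                         group="MZ", **rbounds)
            spec.add_cov(f"A_{t1}_{i}", f"A_{t2}_{j}", label="r_g", scale=0.5,
                         group="DZ", **rbounds)
            spec.add_cov(f"C_{t1}_{i}", f"C_{t2}_{j}", label="r_c", **rbounds)
        return spec

    def fit(self, **kw) -> "BivariateACEResults":
        return BivariateACEResults(self, self.model.fit(**kw))


class BivariateACEResults:
    def __init__(self, model: BivariateACE, fit: PathModelResults):
        self.model = model
        self.fitres = fit

    @property
    def converged(self) -> bool:
        return self.fitres.converged

    def estimates(self, alpha: float = 0.05) -> ACEEstimates:
        by_trait = {}
        for trait, tag in zip(self.model.traits, ("x", "y")):
            comps = (f"a_{tag}", f"c_{tag}", f"e_{tag}")
            vals = {}
            for k in comps:
                v, _se, ci = self.fitres.delta_method(
                    _proportion_fn(k, comps), alpha=alpha)
                vals[k[0]] = (v, ci)
            by_trait[trait] = vals
        corrs = {}
        z = stats.norm.ppf(1 - alpha / 2)
        se = self.fitres.se()
        for r in ("r_g", "r_c", "r_e"):
            v = float(self.fitres.params[r])
            lo, hi = v - z * se[r], v + z * se[r]
            corrs[r] = (v, (max(lo, -1.0), min(hi, 1.0)))
        t1 = self.model.traits[0]
        return ACEEstimates(
            model_tag="ACE-bivariate",
            a2=by_trait[t1]["a"][0], c2=by_trait[t1]["c"][0],
            e2=by_trait[t1]["e"][0],
            ci_a2=by_trait[t1]["a"][1], ci_c2=by_trait[t1]["c"][1],
            ci_e2=by_trait[t1]["e"][1],
            r_g=corrs["r_g"][0], r_c=corrs["r_c"][0], r_e=corrs["r_e"][0],
            ci_r_g=corrs["r_g"][1], ci_r_c=corrs["r_c"][1],
            ci_r_e=corrs["r_e"][1],
            by_trait=by_trait,
        )

    def summary(self) -> str:
        est = self.estimates()
        lines = [f"Bivariate ACE model for {self.model.traits}"]
        for t, vals in est.by_trait.items():
            lines.append(
                f"  {t}: a2={vals['a'][0]:.3f} c2={vals['c'][0]:.3f} "
                f"e2={vals['e'][0]:.3f}")
        lines.append(
            f"  r_g={est.r_g:.3f} {est.ci_r_g}, r_c={est.r_c:.3f} "
            f"{est.ci_r_c}, r_e={est.r_e:.3f} {est.ci_r_e}")
        return "\n".join(lines) + "\n" + self.fitres.summary()
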