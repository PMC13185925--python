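"""Seeded synthetic twin-cohort generator.

Every generated quantity is represented exactly as a loading vector on a
basis of independent unit-variance latent factors, each tagged with a
kind that fixes its cross-twin correlation: additive-genetic factors
(``A``) correlate 1.0 within monozygotic and 0.5 within dizygotic pairs,
shared-environment factors (``C``) correlate 1.0 in both, nonshared
factors (``E``) are uncorrelated across co-twins, and the polygenic
score (``PGS``) correlates 1.0 (MZ) or 0.5 (DZ, random mating).

Traits are built recursively on this basis — exposure from the
instrumental path plus an ACE residual, two correlated latent factors
from the exposure, mediators from factor loadings and pleiotropy,
outcome from the mediation paths — with every residual scale solved so
each trait has unit variance exactly.  Confounding is carried by
exchangeable correlations (``r_a``, ``r_c``, ``r_e``) among the A/C/E
residual components of all traits.  The implied pair covariance matrix
is therefore available in closed form (:func:`implied_pair_covariance`)
and sampling is a single matrix product per zygosity group.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import TwinCohort
from .config import SimulationConfig

_KIND_RHO = {"PGS": None, "A": 0.5, "C": 1.0, "E": 0.0}  # DZ values; MZ = 1 except E


class _Basis:
    """Registry of independent unit-variance latent factors."""

    def __init__(self) -> None:
        self.names: list[str] = []
        self.kinds: list[str] = []

    def add(self, name: str, kind: str) -> int:
        self.names.append(name)
        self.kinds.append(kind)
        return len(self.names) - 1

    def cross_twin_rho(self, group: str, dz_pgs_rho: float) -> np.ndarray:
        """Per-factor correlation between the two co-twins' copies."""
        rho = np.empty(len(self.kinds))
        for i, kind in enumerate(self.kinds):
            if kind == "E":
                rho[i] = 0.0
            elif kind == "PGS":
                rho[i] = 1.0 if group == "MZ" else dz_pgs_rho
            elif kind == "C":
                rho[i] = 1.0
            else:  # A
                rho[i] = 1.0 if group == "MZ" else 0.5
        return rho


def _residual_vector(basis_len, idx_common, idx_specific, triple, r_acc) -> np.ndarray:
    """Unit-variance ACE residual with exchangeable confounder loading."""
    u = np.zeros(basis_len)
    for (i_com, i_spec), share, r in zip(
        zip(idx_common, idx_specific), np.sqrt(np.asarray(triple, float)), r_acc
    ):
        u[i_com] = share * math.sqrt(r)
        u[i_spec] = share * math.sqrt(1.0 - r)
    return u


def _solve_scale(struct: np.ndarray, unit: np.ndarray, label: str) -> float:
    """Residual scale s with var(struct + s*unit) = 1 (unit has variance 1)."""
    g = float(struct @ unit)
    lead = float(struct @ struct)
    disc = g * g + 1.0 - lead
    if -1e-9 <= disc < 0:  # boundary case, e.g. a unit loading
        disc = 0.0
    if disc < 0:
        raise ValueError(
            f"{label}: structural paths explain more than unit variance "
            f"(explained {lead:.3f}); reduce path coefficients or loadings"
        )
    return -g + math.sqrt(disc)


def _build_loadings(config: SimulationConfig):
    """Within-twin loading matrix for pgs, exposure, factors, mediators, outcome."""
    basis = _Basis()
    meds = list(config.mediator_names)
    res_traits = ["exposure", "f1", "f2", *meds, "outcome"]

    i_pgs = basis.add("pgs", "PGS")
    common = [basis.add(f"{k}_common", k) for k in ("A", "C", "E")]
    specific = {
        t: [basis.add(f"{k}_{t}", k) for k in ("A", "C", "E")] for t in res_traits
    }
    # Oversized basis is harmless; final length known only after adds, so
    # build residual vectors afterwards.
    L = len(basis.names)
    r_acc = (config.r_a, config.r_c, config.r_e)

    def resid(trait: str, triple, confounded: bool = True) -> np.ndarray:
        # Mediator-specific residuals are unconfounded: mediators share
        # variance with each other and with exposure/outcome only through
        # the factors, which carry the confounder correlations.
        r = r_acc if confounded else (0.0, 0.0, 0.0)
        return _residual_vector(L, common, specific[trait], triple, r)

    W: dict[str, np.ndarray] = {}
    W["pgs"] = np.zeros(L)
    W["pgs"][i_pgs] = 1.0

    f = config.instrumental_path
    if not -1 <= f <= 1:
        raise ValueError("instrumental_path: must lie in [-1, 1]")
    W["exposure"] = f * W["pgs"] + math.sqrt(1 - f * f) * resid(
        "exposure", config.ace_exposure
    )

    # Latent mediator factors: exposure path plus ACE disturbance; the
    # second factor's disturbance is blended with the first's so the
    # implied factor correlation matches the configured value exactly.
    a1, a2 = config.a_paths
    u1 = resid("f1", config.ace_factors[0])
    u2 = resid("f2", config.ace_factors[1])
    s1 = _solve_scale(a1 * W["exposure"], u1, "factor 1")
    W["f1"] = a1 * W["exposure"] + s1 * u1

    def _blend(alpha: float) -> np.ndarray:
        b = alpha * u1 + math.sqrt(1 - alpha * alpha) * u2
        return b / math.sqrt(float(b @ b))

    def factor_corr_gap(alpha: float) -> float:
        blended = _blend(alpha)
        s2 = _solve_scale(a2 * W["exposure"], blended, "factor 2")
        w2 = a2 * W["exposure"] + s2 * blended
        return float(W["f1"] @ w2) - config.factor_correlation

    try:
        alpha = brentq(factor_corr_gap, -0.999, 0.999, xtol=1e-12)
    except ValueError as exc:
        raise ValueError(
            "factor_correlation: not attainable given a_paths and confounder "
            "correlations"
        ) from exc
    blended = _blend(alpha)
    s2 = _solve_scale(a2 * W["exposure"], blended, "factor 2")
    W["f2"] = a2 * W["exposure"] + s2 * blended

    lam = np.asarray(config.factor_loadings, float)
    for j, name in enumerate(meds):
        struct = (
            lam[j, 0] * W["f1"]
            + lam[j, 1] * W["f2"]
            + config.pleiotropic_mediators[j] * W["pgs"]
        )
        u = resid(name, config.ace_mediators[j], confounded=False)
        W[name] = struct + _solve_scale(struct, u, name) * u

    b1, b2 = config.b_paths
    struct = (
        config.c_prime * W["exposure"]
        + b1 * W["f1"]
        + b2 * W["f2"]
        + config.pleiotropic_outcome * W["pgs"]
    )
    u = resid("outcome", config.ace_outcome)
    W["outcome"] = struct + _solve_scale(struct, u, "outcome") * u

    order = ["pgs", "exposure", "f1", "f2", *meds, "outcome"]
    return basis, order, np.vstack([W[t] for t in order])


def implied_pair_covariance(config: SimulationConfig, group: str):
    """Exact generating covariance of (twin1 traits, twin2 traits).

    Returns ``(names, sigma)`` where names are the observed trait slots
    (pgs, exposure, mediator factors, mediators, outcome) for twin 1
    followed by twin 2, and ``sigma`` is the implied covariance under
    the configured structural model (continuous, pre-measurement scale).
    """
    if group not in ("MZ", "DZ"):
        raise ValueError("group must be 'MZ' or 'DZ'")
    basis, order, W = _build_loadings(config)
    rho = basis.cross_twin_rho(group, config.dz_pgs_correlation)
    within = W @ W.T
    cross = W @ (rho[:, None] * W.T)
    sigma = np.block([[within, cross], [cross.T, within]])
    names = [f"{t}_1" for t in order] + [f"{t}_2" for t in order]
    return names, sigma


def _sample_group(config, group, n_pairs, rng):
    basis, order, W = _build_loadings(config)
    rho = basis.cross_twin_rho(group, config.dz_pgs_correlation)
    L = len(basis.names)
    z_shared = rng.standard_normal((n_pairs, L))
    vals = []
    for _ in (1, 2):
        z_unique = rng.standard_normal((n_pairs, L))
        latent = np.sqrt(rho) * z_shared + np.sqrt(1.0 - rho) * z_unique
        vals.append(latent @ W.T)
    return order, vals  # list of (n_pairs, n_traits) per twin


def _make_items(trait_vals: np.ndarray, n_items: int, loading: float,
                thresholds: np.ndarray, rng) -> np.ndarray:
    """Ordinal 5-point items from a latent trait (congeneric, equal loadings)."""
    n = trait_vals.shape[0]
    noise = rng.standard_normal((n, n_items))
    latent = loading * trait_vals[:, None] + math.sqrt(1 - loading**2) * noise
    return np.digitize(latent, thresholds).astype(float)


def _composite_from_items(items: np.ndarray, min_fraction: float = 0.5) -> np.ndarray:
    observed = ~np.isnan(items)
    counts = observed.sum(axis=1)
    sums = np.where(observed, items, 0.0).sum(axis=1)
    score = np.divide(sums, counts, out=np.full(len(items), np.nan),
                      where=counts > 0)
    score[counts < min_fraction * items.shape[1]] = np.nan
    return score


def generate_cohort(config: SimulationConfig, seed: int | None = None) -> TwinCohort:
    """Draw a twin cohort from the configured generating model.

    Reproducible for a fixed seed (``config.seed`` unless overridden).
    When ``config.item_counts`` is set, composites are means of 5-point
    ordinal items (>=50% observed rule) with MCAR item nonresponse at
    ``config.missing_rate``; otherwise composites equal the latent traits.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    meds = list(config.mediator_names)
    composites = ["exposure", *meds, "outcome"]

    frames = []
    item_frames = []
    fam_counter = 0
    for group, n_pairs in (("MZ", config.n_pairs_mz), ("DZ", config.n_pairs_dz)):
        order, twin_vals = _sample_group(config, group, n_pairs, rng)
        col = {t: i for i, t in enumerate(order)}
        if group == "MZ":
            zyg = np.repeat("MZ", n_pairs)
        else:  # alternate same-sex / opposite-sex labels at equal rates
            zyg = np.where(np.arange(n_pairs) % 2 == 0, "DZss", "DZos")
        fams = [f"F{fam_counter + i:06d}" for i in range(n_pairs)]
        fam_counter += n_pairs

        for twin_idx, vals in enumerate(twin_vals, start=1):
            row = {
                "family_id": fams,
                "zygosity": zyg,
                "twin": twin_idx,
                "pgs": vals[:, col["pgs"]],
            }
            items_row = {"family_id": fams, "twin": twin_idx}
            for trait in composites:
                latent = vals[:, col[trait]]
                if config.item_counts is None:
                    row[trait] = latent
                else:
                    k = config.item_counts.get(trait, 5)
                    items = _make_items(
                        latent, k, config.item_loading,
                        np.asarray(config.thresholds), rng,
                    )
                    if config.missing_rate > 0:
                        items[rng.random(items.shape) < config.missing_rate] = np.nan
                    for i in range(k):
                        items_row[f"{trait}_item{i + 1}"] = items[:, i]
                    row[trait] = _composite_from_items(items)
            frames.append(pd.DataFrame(row))
            if config.item_counts is not None:
                item_frames.append(pd.DataFrame(items_row))

    df = pd.concat(frames, ignore_index=True)
    rename = {m: f"med_{j + 1:02d}" for j, m in enumerate(meds)}
    df = df.rename(columns=rename)
    df = df.sort_values(["family_id", "twin"], kind="stable").reset_index(drop=True)
    cohort = TwinCohort(df)
    cohort.meta = {
        "seed": int(config.seed if seed is None else seed),
        "mediator_names": meds,
    }
    if item_frames:
        items_df = pd.concat(item_frames, ignore_index=True)
        cohort.items = items_df.sort_values(
            ["family_id", "twin"], kind="stable"
        ).reset_index(drop=True)
    else:
        cohort.items = None
    return cohort


def inject_missingness(cohort: TwinCohort, rate: float, seed: int = 0,
                       min_fraction: float = 0.5) -> TwinCohort:
    """Set item values missing completely at random and recompute composites.

    When the cohort carries item-level data each item is masked
    independently with probability ``rate``; otherwise masking is applied
    at the composite level (each composite missing with probability
    ``rate``), which is the composite-scale analogue of item MCAR.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    df = cohort.data.copy()
    items = getattr(cohort, "items", None)
    if rate == 0:
        out = TwinCohort(df, strict=False)
        out.items = None if items is None else items.copy()
        return out
    if items is not None:
        items = items.copy()
        item_cols = [c for c in items.columns if "_item" in c]
        vals = items[item_cols].to_numpy(float)
        vals[rng.random(vals.shape) < rate] = np.nan
        items[item_cols] = vals
        traits = sorted({c.rsplit("_item", 1)[0] for c in item_cols})
        trait_to_col = {"exposure": "exposure", "outcome": "outcome"}
        med_names = cohort.meta.get("mediator_names", []) if hasattr(cohort, "meta") else []
        for j, m in enumerate(med_names):
            trait_to_col[m] = f"med_{j + 1:02d}"
        for trait in traits:
            cols = [c for c in item_cols if c.startswith(f"{trait}_item")]
            score = _composite_from_items(items[cols].to_numpy(float), min_fraction)
            df[trait_to_col.get(trait, trait)] = score
    else:
        comp_cols = ["exposure", *[c for c in df.columns if c.startswith("med_")],
                     "outcome"]
        for c in comp_cols:
            mask = rng.random(len(df)) < rate
            df.loc[mask, c] = np.nan
    out = TwinCohort(df, strict=False)
    out.items = items
    if hasattr(cohort, "meta"):
        out.meta = dict(cohort.meta)
    return out
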