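"""Simulation configuration for synthetic twin cohorts.

The generator emulates a register-based twin cohort assessed in early
adulthood: a standardized polygenic score, an exposure composite
(childhood maltreatment), eighteen mediator composites (personality and
mental-health scales) organised by two correlated latent factors —
negative/disordered affect and externalizing tendencies — and an outcome
composite (intimate-partner-violence victimization).  All structural
coefficients are on the standardized (unit-variance) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

#: Mediator battery in canonical order.  The first factor (negative /
#: disordered affect) loads on internalizing-type scales, the second
#: (externalizing tendencies) on disinhibition-type scales; signs encode
#: the direction of the loading (e.g. well-being loads negatively).
MEDIATOR_NAMES: tuple[str, ...] = (
    "neuroticism",
    "extraversion",
    "openness",
    "agreeableness",
    "conscientiousness",
    "self_control",
    "consideration_future",
    "risk_taking",
    "anxiety",
    "peer_problems",
    "hyperactivity",
    "conduct_problems",
    "depressive_symptoms",
    "aggression",
    "antisocial_behavior",
    "adhd",
    "psychotic_experiences",
    "well_being",
)

#: Default 18x2 loading pattern (factor 1, factor 2).
DEFAULT_LOADINGS: tuple[tuple[float, float], ...] = (
    (0.65, 0.0),    # neuroticism
    (-0.45, 0.0),   # extraversion
    (0.0, 0.30),    # openness
    (0.0, -0.40),   # agreeableness
    (0.0, -0.50),   # conscientiousness
    (0.0, -0.60),   # self_control
    (0.0, -0.40),   # consideration_future
    (0.0, 0.55),    # risk_taking
    (0.70, 0.0),    # anxiety
    (0.50, 0.0),    # peer_problems
    (0.0, 0.55),    # hyperactivity
    (0.0, 0.60),    # conduct_problems
    (0.70, 0.0),    # depressive_symptoms
    (0.0, 0.55),    # aggression
    (0.0, 0.45),    # antisocial_behavior
    (0.0, 0.60),    # adhd
    (0.55, 0.0),    # psychotic_experiences
    (-0.60, 0.0),   # well_being
)

#: Equal-probability standard-normal cut points for 5-point items.
EQUAL_THRESHOLDS: tuple[float, ...] = (-0.8416, -0.2533, 0.2533, 0.8416)

#: Right-skew preset approximating maltreatment-like item distributions
#: (most respondents endorse the lowest category).
SKEW_THRESHOLDS: tuple[float, ...] = (0.2533, 0.8416, 1.2816, 1.7507)


def _check_triple(name: str, triple) -> tuple[float, float, float]:
    t = tuple(float(v) for v in triple)
    if len(t) != 3:
        raise ValueError(f"{name}: expected three variance proportions, got {triple!r}")
    if any(v < 0 or v > 1 for v in t):
        raise ValueError(f"{name}: variance proportions must lie in [0, 1], got {t}")
    if abs(sum(t) - 1.0) > 1e-12:
        raise ValueError(f"{name}: variance proportions must sum to 1, got sum {sum(t)!r}")
    return t


@dataclass
class SimulationConfig:
    """Generating parameters for a synthetic twin cohort.

    Defaults reproduce the study conditions the downstream models target:
    exposure variance split roughly in thirds between A, C and E; outcome
    heritability modest (A 17%, C 7%, E 76%); a weak polygenic instrument
    (0.09) with a small pleiotropic path to the outcome (0.06); factor-level
    mediation paths a = 0.29 and b = (0.17, 0.14) with direct effect
    c' = 0.05.  Composites are continuous by default; set ``item_counts``
    to discretize through 5-point ordinal items.
    """

    n_pairs_mz: int = 1988
    n_pairs_dz: int = 3683

    ace_exposure: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    ace_outcome: tuple[float, float, float] = (0.17, 0.07, 0.76)
    # Residual (mediator-specific) ACE after factors and PGS are removed;
    # shared environment defaults to zero, as for most mediator scales.
    ace_mediators: tuple[tuple[float, float, float], ...] = tuple(
        (0.30, 0.00, 0.70) for _ in MEDIATOR_NAMES
    )
    # ACE of the latent-factor disturbances (after the exposure path).
    ace_factors: tuple[tuple[float, float, float], ...] = (
        (0.35, 0.0, 0.65),
        (0.35, 0.0, 0.65),
    )

    instrumental_path: float = 0.09
    pleiotropic_outcome: float = 0.06
    pleiotropic_mediators: tuple[float, ...] = tuple(0.03 for _ in MEDIATOR_NAMES)

    # Factor-level mediation paths: exposure -> factor (a), factor ->
    # outcome (b) and the direct exposure -> outcome effect (c').
    a_paths: tuple[float, float] = (0.29, 0.29)
    b_paths: tuple[float, float] = (0.17, 0.14)
    c_prime: float = 0.05

    factor_loadings: tuple[tuple[float, float], ...] = DEFAULT_LOADINGS
    factor_correlation: float = 0.45

    # Exchangeable confounder correlations among the A / C / E residual
    # components of exposure, factor disturbances and outcome residual
    # (mediator-specific residuals stay unconfounded; mediators share
    # variance with the other traits only through the factors).
    r_a: float = 0.52
    r_c: float = 0.42
    r_e: float = 0.0

    dz_pgs_correlation: float = 0.5

    # Measurement layer: None generates continuous composites equal to the
    # latent trait; otherwise each composite is the mean of ordinal items.
    item_counts: dict[str, int] | None = None
    thresholds: tuple[float, ...] = EQUAL_THRESHOLDS
    item_loading: float = 0.85
    missing_rate: float = 0.0

    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_mediators(self) -> int:
        return len(self.ace_mediators)

    @property
    def mediator_names(self) -> tuple[str, ...]:
        return MEDIATOR_NAMES[: self.n_mediators]

    def validate(self) -> None:
        if self.n_pairs_mz < 1 or self.n_pairs_dz < 1:
            raise ValueError("n_pairs_mz/n_pairs_dz: at least one pair per zygosity group")
        self.ace_exposure = _check_triple("ace_exposure", self.ace_exposure)
        self.ace_outcome = _check_triple("ace_outcome", self.ace_outcome)
        self.ace_mediators = tuple(
            _check_triple(f"ace_mediators[{i}]", t) for i, t in enumerate(self.ace_mediators)
        )
        self.ace_factors = tuple(
            _check_triple(f"ace_factors[{i}]", t) for i, t in enumerate(self.ace_factors)
        )
        lam = np.asarray(self.factor_loadings, dtype=float)
        if lam.shape != (self.n_mediators, 2):
            raise ValueError(
                f"factor_loadings: expected shape ({self.n_mediators}, 2), got {lam.shape}"
            )
        self.factor_loadings = tuple(tuple(row) for row in lam)
        if len(self.pleiotropic_mediators) != self.n_mediators:
            raise ValueError("pleiotropic_mediators: one path per mediator required")
        if not -1 < self.factor_correlation < 1:
            raise ValueError("factor_correlation: must lie in (-1, 1)")
        for nm in ("r_a", "r_c", "r_e"):
            v = getattr(self, nm)
            if not 0 <= v <= 1:
                raise ValueError(f"{nm}: confounder correlation must lie in [0, 1]")
        if not 0 <= self.dz_pgs_correlation <= 1:
            raise ValueError("dz_pgs_correlation: must lie in [0, 1]")
        thr = tuple(float(t) for t in self.thresholds)
        if any(b <= a for a, b in zip(thr, thr[1:])):
            raise ValueError("thresholds: cut points must be strictly increasing")
        self.thresholds = thr
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate: must lie in [0, 1)")
        if not 0 < self.item_loading <= 1:
            raise ValueError("item_loading: must lie in (0, 1]")
        if self.item_counts is not None:
            for k, v in self.item_counts.items():
                if v < 1:
                    raise ValueError(f"item_counts[{k!r}]: need at least one item")

    # ------------------------------------------------------------------
    @classmethod
    def realistic(cls, **overrides) -> "SimulationConfig":
        """Preset with the ordinal measurement layer switched on.

        Exposure: 8 items on a right-skewed 5-point scale; outcome: 6
        items; mediators: 5 items each on equal-probability cut points.
        Item nonresponse is 5% completely at random.
        """
        counts = {"exposure": 8, "outcome": 6}
        counts.update({name: 5 for name in MEDIATOR_NAMES})
        defaults = dict(item_counts=counts, missing_rate=0.05)
        defaults.update(overrides)
        return cls(**defaults)

    def to_yaml(self, path: str | Path) -> None:
        import json

        data = json.loads(json.dumps(asdict(self)))  # tuples -> lists
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**data)
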