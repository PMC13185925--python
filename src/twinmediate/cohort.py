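"""Twin-cohort container and the cohort CSV schema.

One row per individual; exactly two rows per family.  Columns:
``family_id, zygosity, twin, pgs, exposure, med_01..med_NN, outcome``
with ``zygosity`` in {MZ, DZss, DZos} and ``twin`` in {1, 2}.  Empty
cells encode missing composite scores.  Monozygotic co-twins carry
identical polygenic scores.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ZYGOSITY_LABELS = ("MZ", "DZss", "DZos")


class CohortFormatError(ValueError):
    """Raised when a cohort table violates the pair schema."""


def composite_score(items: Sequence[float], min_fraction: float = 0.5) -> float:
    """Mean of the non-missing items, requiring a minimum observed fraction.

    Mirrors the scale-scoring rule used for questionnaire composites:
    the composite is the mean of the available items provided at least
    ``min_fraction`` of the items are non-missing, otherwise missing
    (``nan``).  Missing items are ``None`` or ``nan``.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    arr = np.array([np.nan if v is None else float(v) for v in items], dtype=float)
    if arr.size == 0:
        raise ValueError("items must be non-empty")
    observed = ~np.isnan(arr)
    if observed.sum() / arr.size < min_fraction:
        return float("nan")
    return float(arr[observed].mean())


class TwinCohort:
    """Per-individual twin records with pair-level structure.

    Thin wrapper around a :class:`pandas.DataFrame` that enforces the
    two-rows-per-family invariant and provides the wide (one row per
    pair) layout the twin models consume.
    """

    def __init__(self, data: pd.DataFrame, strict: bool = True):
        self.data = data.reset_index(drop=True)
        self.validate(strict=strict)

    # -- schema -------------------------------------------------------
    @property
    def mediator_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("med_")]

    @property
    def trait_columns(self) -> list[str]:
        return ["pgs", "exposure", *self.mediator_columns, "outcome"]

    @property
    def n_pairs(self) -> int:
        return len(self.data) // 2

    def validate(self, strict: bool = True) -> None:
        df = self.data
        required = {"family_id", "zygosity", "twin", "pgs", "exposure", "outcome"}
        missing = required - set(df.columns)
        if missing:
            raise CohortFormatError(f"missing required columns: {sorted(missing)}")
        bad_zyg = ~df["zygosity"].isin(ZYGOSITY_LABELS)
        if bad_zyg.any():
            row = int(np.flatnonzero(bad_zyg.to_numpy())[0])
            raise CohortFormatError(f"row {row}: unknown zygosity {df['zygosity'].iloc[row]!r}")
        counts = df.groupby("family_id").size()
        odd = counts[counts != 2]
        if len(odd):
            raise CohortFormatError(
                f"family {odd.index[0]!r}: expected exactly 2 rows, found {int(odd.iloc[0])}"
            )
        by_fam = df.groupby("family_id")
        nzyg = by_fam["zygosity"].nunique()
        if (nzyg > 1).any():
            fam = nzyg[nzyg > 1].index[0]
            raise CohortFormatError(f"family {fam!r}: inconsistent zygosity within pair")
        twin_sets = by_fam["twin"].agg(lambda s: tuple(sorted(s)))
        bad = twin_sets[twin_sets != (1, 2)]
        if len(bad):
            raise CohortFormatError(f"family {bad.index[0]!r}: twin indices must be {{1, 2}}")
        mz = df[df["zygosity"] == "MZ"]
        if len(mz):
            spread = mz.groupby("family_id")["pgs"].agg(lambda s: s.max() - s.min())
            if (spread > 1e-9).any():
                fam = spread[spread > 1e-9].index[0]
                msg = f"family {fam!r}: MZ co-twins have different polygenic scores"
                if strict:
                    raise CohortFormatError(msg)
                import warnings

                warnings.warn(msg, stacklevel=2)

    # -- layouts ------------------------------------------------------
    def pairs_wide(self, traits: Iterable[str] | None = None) -> pd.DataFrame:
        """One row per family: ``<trait>_1``/``<trait>_2`` columns plus zygosity."""
        traits = list(traits) if traits is not None else self.trait_columns
        df = self.data
        wide = df.pivot(index="family_id", columns="twin", values=traits)
        wide.columns = [f"{t}_{i}" for t, i in wide.columns]
        zyg = df.groupby("family_id")["zygosity"].first()
        wide["zygosity"] = zyg
        return wide.reset_index()

    def zygosity_groups(self, traits: Iterable[str] | None = None,
                        collapse_dz: bool = True) -> dict[str, pd.DataFrame]:
        """Wide pair frames keyed by zygosity group (MZ vs pooled DZ)."""
        wide = self.pairs_wide(traits)
        if collapse_dz:
            return {
                "MZ": wide[wide["zygosity"] == "MZ"],
                "DZ": wide[wide["zygosity"] != "MZ"],
            }
        return {z: wide[wide["zygosity"] == z] for z in ZYGOSITY_LABELS}

    def standardized(self) -> "TwinCohort":
        """Z-score every trait column across individuals (missing preserved)."""
        df = self.data.copy()
        for c in self.trait_columns:
            v = df[c].astype(float)
            df[c] = (v - v.mean()) / v.std(ddof=1)
        return TwinCohort(df, strict=False)

    def __len__(self) -> int:
        return len(self.data)


def write_cohort(cohort: TwinCohort, path: str | Path) -> None:
    """Write the cohort CSV (UTF-8, one header line, empty cell = missing)."""
    cohort.data.to_csv(path, index=False, na_rep="")


def read_cohort(path: str | Path, strict: bool = True) -> TwinCohort:
    """Read a cohort CSV, validating the pair schema.

    Raises :class:`CohortFormatError` naming the offending family or row
    on malformed input; with ``strict=False`` an MZ polygenic-score
    mismatch is downgraded to a warning.
    """
    try:
        df = pd.read_csv(path, dtype={"family_id": str})
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise CohortFormatError(f"{path}: cannot parse cohort CSV ({exc})") from exc
    if "twin" in df.columns:
        df["twin"] = df["twin"].astype(int)
    return TwinCohort(df, strict=strict)
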