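"""Synthetic census-like age-by-sex population tables.

Stands in for census extracts so the whole pipeline is testable offline: a
requested per-sex total is allocated multinomially across age bands, and
population bases ("males 21-40", "females 20-44") are extracted by exact
band-aligned interval sums.  Age intervals are half-open ``[lo, hi)``
everywhere, so "21 to 40 inclusive" is ``[21, 41)``.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Band",
    "PopulationTable",
    "AlignmentError",
    "generate_population",
    "extract_base",
    "write_population",
    "read_population",
]

MAX_AGE = 100  # bands cover ages [0, MAX_AGE)


class AlignmentError(ValueError):
    """Requested interval does not align with band boundaries."""


@dataclass(frozen=True)
class Band:
    sex: str
    age_lo: int
    age_hi: int  # half-open: [age_lo, age_hi)
    count: int


@dataclass(frozen=True)
class PopulationTable:
    rows: tuple[Band, ...]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        by_sex: dict[str, list[Band]] = {}
        for b in self.rows:
            if b.count < 0 or b.age_hi <= b.age_lo:
                raise ValueError(f"invalid band {b}")
            by_sex.setdefault(b.sex, []).append(b)
        for sex, bands in by_sex.items():
            bands.sort(key=lambda b: b.age_lo)
            for a, b in zip(bands, bands[1:]):
                if b.age_lo < a.age_hi:
                    raise ValueError(f"overlapping bands for {sex!r}: {a} / {b}")

    def bands(self, sex: str) -> list[Band]:
        return sorted((b for b in self.rows if b.sex == sex), key=lambda b: b.age_lo)

    def total(self, sex: str) -> int:
        return sum(b.count for b in self.bands(sex))


def generate_population(
    seed: int,
    total_by_sex: Mapping[str, int],
    band_width: int = 1,
    age_range_by_sex: Mapping[str, tuple[int, int]] | None = None,
) -> PopulationTable:
    """Deterministically allocate per-sex totals across age bands.

    Bands tile ``[0, 100)`` at ``band_width``.  If ``age_range_by_sex`` gives
    a half-open ``[lo, hi)`` for a sex, that sex's total is spread (uniform
    multinomial) only over bands inside the range — the range must align with
    band boundaries — and all other bands get zero.  Per-sex sums are exact.
    """
    if band_width < 1:
        raise ValueError(f"band_width must be >= 1, got {band_width}")
    age_range_by_sex = dict(age_range_by_sex or {})
    rng = np.random.default_rng(seed)
    edges = list(range(0, MAX_AGE, band_width))
    bands = [(lo, min(lo + band_width, MAX_AGE)) for lo in edges]

    rows: list[Band] = []
    for sex in sorted(total_by_sex):
        total = int(total_by_sex[sex])
        if total < 0:
            raise ValueError(f"total for {sex!r} must be non-negative")
        lo_r, hi_r = age_range_by_sex.get(sex, (0, MAX_AGE))
        eligible = [i for i, (lo, hi) in enumerate(bands) if lo >= lo_r and hi <= hi_r]
        covered = sum(bands[i][1] - bands[i][0] for i in eligible)
        if covered != hi_r - lo_r:
            raise AlignmentError(
                f"age range [{lo_r}, {hi_r}) for {sex!r} does not align with "
                f"band width {band_width}"
            )
        counts = [0] * len(bands)
        if eligible and total:
            alloc = rng.multinomial(total, [1.0 / len(eligible)] * len(eligible))
            for i, c in zip(eligible, alloc):
                counts[i] = int(c)
        rows.extend(
            Band(sex, lo, hi, c) for (lo, hi), c in zip(bands, counts)
        )
    return PopulationTable(
        rows=tuple(rows),
        metadata={
            "seed": seed,
            "band_width": band_width,
            "total_by_sex": dict(total_by_sex),
            "age_range_by_sex": age_range_by_sex,
        },
    )


def extract_base(table: PopulationTable, sex: str, age_lo: int, age_hi: int) -> int:
    """Sum counts over ``[age_lo, age_hi)``; the interval must tile exact bands.

    Misaligned intervals raise :class:`AlignmentError` — no silent pro-rating.
    """
    if age_hi < age_lo:
        raise ValueError(f"empty-ordered interval [{age_lo}, {age_hi})")
    if age_hi == age_lo:
        return 0
    inside = [b for b in table.bands(sex) if b.age_lo >= age_lo and b.age_hi <= age_hi]
    if not inside or inside[0].age_lo != age_lo or inside[-1].age_hi != age_hi:
        raise AlignmentError(
            f"interval [{age_lo}, {age_hi}) for {sex!r} does not align with band edges"
        )
    for a, b in zip(inside, inside[1:]):
        if b.age_lo != a.age_hi:
            raise AlignmentError(
                f"bands for {sex!r} do not tile [{age_lo}, {age_hi}) contiguously"
            )
    return sum(b.count for b in inside)


def write_population(table: PopulationTable) -> str:
    """Serialize as TSV with header ``sex, age_lo, age_hi, count``."""
    df = pd.DataFrame(
        [(b.sex, b.age_lo, b.age_hi, b.count) for b in table.rows],
        columns=["sex", "age_lo", "age_hi", "count"],
    )
    return df.to_csv(sep="\t", index=False)


def read_population(text: str) -> PopulationTable:
    """Parse the TSV emitted by :func:`write_population` (metadata not kept)."""
    df = pd.read_csv(io.StringIO(text), sep="\t")
    expected = ["sex", "age_lo", "age_hi", "count"]
    if list(df.columns) != expected:
        raise ValueError(f"expected columns {expected}, got {list(df.columns)}")
    rows = tuple(
        Band(str(r.sex), int(r.age_lo), int(r.age_hi), int(r.count))
        for r in df.itertuples()
    )
    return PopulationTable(rows=rows)
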