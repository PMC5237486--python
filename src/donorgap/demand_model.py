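"""Per-segment demand for donor insemination, totals, and ratio calibration.

Each segment's expected demand is ``base units × seeking chain × recipient
eligibility`` at full rational precision; reported demands are integerized
per segment (half away from zero) and the total is the sum of the reported
integers, which is what makes the published per-segment/total cells add up
exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

from ._format import (
    delimited_table,
    format_count,
    format_percent_sig,
    markdown_table,
    round_half_away,
)
from .scenario_config import DemandSegmentSpec

__all__ = [
    "SegmentDemand",
    "DemandResult",
    "RatioSpec",
    "InfeasibleRateError",
    "base_units",
    "segment_demand",
    "total_demand",
    "demand_fraction",
    "calibrate_rate_from_ratio",
    "to_delimited",
    "to_markdown",
]


class InfeasibleRateError(ValueError):
    """The demanded rate would have to exceed 1 (or the segment is empty)."""


@dataclass(frozen=True)
class SegmentDemand:
    label: str
    expected: Fraction
    reported: int


@dataclass(frozen=True)
class DemandResult:
    per_segment: tuple[SegmentDemand, ...]
    total: int


@dataclass(frozen=True)
class RatioSpec:
    """Relative utilization ratio across segments, anchored at one of them."""

    reference_label: str
    ratios: Mapping[str, Fraction]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratios", dict(self.ratios))
        if self.reference_label not in self.ratios:
            raise ValueError(f"reference {self.reference_label!r} missing from ratios")
        for label, r in self.ratios.items():
            if not r > 0:
                raise ValueError(f"ratio for {label!r} must be positive, got {r}")


def base_units(segment: DemandSegmentSpec) -> Fraction:
    """Units at risk (women or couples) before the seeking chain, exact."""
    if segment.base_count is not None:
        return Fraction(segment.base_count)
    units = Fraction(segment.base_population)
    for p in segment.base_chain:
        units *= p.value
    return units


def segment_demand(segment: DemandSegmentSpec) -> tuple[Fraction, int]:
    """Expected (exact) and reported (integer) demand for one segment."""
    expected = base_units(segment)
    for p in segment.seeking_chain:
        expected *= p.value
    expected *= segment.recipient_eligibility.value
    return expected, round_half_away(expected)


def total_demand(segments: Sequence[DemandSegmentSpec]) -> DemandResult:
    """Reported per-segment demands and their integer sum."""
    if not segments:
        raise ValueError("need at least one demand segment")
    per = tuple(
        SegmentDemand(seg.label, *segment_demand(seg)) for seg in segments
    )
    return DemandResult(per_segment=per, total=sum(s.reported for s in per))


def demand_fraction(result: DemandResult, population_base: int) -> Fraction:
    """Total demand as an exact fraction of a population base.

    Format with :func:`donorgap._format.format_percent_sig` (two significant
    figures of percent) for display.
    """
    if population_base <= 0:
        raise ValueError(f"population base must be positive, got {population_base}")
    return Fraction(result.total, population_base)


def calibrate_rate_from_ratio(
    reference_demand: int,
    ratio: RatioSpec,
    target: DemandSegmentSpec,
) -> Fraction:
    """Solve a segment's missing seeking rate from a utilization ratio.

    ``target`` is the segment spec *without* the rate being solved for (its
    ``seeking_chain`` holds only the known factors).  Returns the exact rate
    ``p`` such that the segment's expected demand equals
    ``reference_demand × ratio[target] / ratio[reference]``.
    """
    if reference_demand <= 0:
        raise ValueError(f"reference_demand must be positive, got {reference_demand}")
    if target.label not in ratio.ratios:
        raise KeyError(f"segment {target.label!r} missing from ratio spec")
    needed = (
        Fraction(reference_demand)
        * Fraction(ratio.ratios[target.label])
        / Fraction(ratio.ratios[ratio.reference_label])
    )
    denom = base_units(target) * target.recipient_eligibility.value
    for p in target.seeking_chain:
        denom *= p.value
    if denom == 0:
        raise InfeasibleRateError(
            f"segment {target.label!r} has no at-risk units; cannot reach {needed}"
        )
    rate = needed / denom
    if rate > 1:
        raise InfeasibleRateError(
            f"segment {target.label!r} would need rate {float(rate):.4g} > 1 to supply "
            f"{float(needed):.1f} requests"
        )
    return rate


def _rows(result: DemandResult, pretty: bool) -> list[list[object]]:
    fmt = format_count if pretty else str
    rows: list[list[object]] = [
        [s.label, s.expected, fmt(s.reported)] for s in result.per_segment
    ]
    rows.append(["total", "", fmt(result.total)])
    return rows


def to_delimited(result: DemandResult, sep: str = ",") -> str:
    """Value-preserving export: exact expectations as ``num/den`` strings."""
    return delimited_table(["segment", "expected", "reported"], _rows(result, pretty=False), sep)


def to_markdown(result: DemandResult, population_base: int | None = None) -> str:
    rows = _rows(result, pretty=True)
    if population_base:
        pct = format_percent_sig(demand_fraction(result, population_base))
        rows[-1][2] = f"{rows[-1][2]} ({pct} of base)"
    rows = [[label, "" if exp == "" else format_count(round_half_away(exp)), rep]
            for label, exp, rep in rows]
    return markdown_table(["Segment", "Expected (rounded)", "Reported"], rows)
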