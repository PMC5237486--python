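"""Top-down supply funnel: population base thinned through ordered proportions.

Expected counts are carried at full rational precision along the funnel; only
the per-stage *reported* counts and the final donor count are integerized
(round half away from zero).  Donation capacity is donors times the
births-per-donor cap, applied after integerization — donors are whole people.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from ._format import (
    delimited_table,
    format_count,
    format_percent,
    markdown_table,
    round_half_away,
)
from .scenario_config import SupplySpec

__all__ = ["StageCount", "SupplyResult", "run_funnel", "donor_fraction",
           "to_delimited", "to_markdown"]


@dataclass(frozen=True)
class StageCount:
    label: str
    expected: Fraction  # exact, pre-rounding
    reported: int


@dataclass(frozen=True)
class SupplyResult:
    population_base: int
    births_per_donor: int
    stage_counts: tuple[StageCount, ...]
    donors: int
    donations: int


def run_funnel(spec: SupplySpec) -> SupplyResult:
    """Evaluate the multiplicative funnel for one supply specification."""
    expected = Fraction(spec.population_base)
    stages: list[StageCount] = []
    for param in spec.stages:
        expected *= param.value
        stages.append(StageCount(param.name, expected, round_half_away(expected)))
    donors = stages[-1].reported
    return SupplyResult(
        population_base=spec.population_base,
        births_per_donor=spec.births_per_donor,
        stage_counts=tuple(stages),
        donors=donors,
        donations=donors * spec.births_per_donor,
    )


def donor_fraction(result: SupplyResult, population_base: int | None = None) -> Fraction:
    """Donors as an exact fraction of the population base.

    Display code should format this with :func:`donorgap._format.format_percent`
    (4 decimal places of percent).
    """
    base = result.population_base if population_base is None else population_base
    if base <= 0:
        raise ValueError(f"population base must be positive, got {base}")
    return Fraction(result.donors, base)


def _rows(result: SupplyResult, pretty: bool) -> list[list[object]]:
    fmt = format_count if pretty else str
    rows: list[list[object]] = [
        ["population_base", Fraction(result.population_base), fmt(result.population_base)]
    ]
    for stage in result.stage_counts:
        rows.append([stage.label, stage.expected, fmt(stage.reported)])
    pct = format_percent(donor_fraction(result)) if result.population_base else "n/a"
    rows.append(["donors_pct_of_base", "", pct])
    rows.append(["donations", "", fmt(result.donations)])
    return rows


def to_delimited(result: SupplyResult, sep: str = ",") -> str:
    """Value-preserving export: exact expectations as ``num/den`` strings."""
    return delimited_table(["stage", "expected", "reported"], _rows(result, pretty=False), sep)


def to_markdown(result: SupplyResult) -> str:
    rows = [[label, format_count(int(round_half_away(exp))) if exp != "" else "", rep]
            for label, exp, rep in _rows(result, pretty=True)]
    return markdown_table(["Stage", "Expected (rounded)", "Reported"], rows)
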