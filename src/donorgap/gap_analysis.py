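"""Supply-demand gap in donation units and its whole-donor equivalent.

Shortfalls convert to donors with a ceiling (whole donors must fully cover
demand); surpluses with a floor (only complete spare donors count).  Also
hosts the scenario-level pipeline and a break-even solver for a single
funnel proportion.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from ._format import delimited_table, format_count, markdown_table
from .demand_model import DemandResult, total_demand
from .scenario_config import ScenarioSpec, set_parameter
from .supply_funnel import SupplyResult, run_funnel

__all__ = [
    "GapResult",
    "ScenarioOutcome",
    "BreakEvenResult",
    "compute_gap",
    "donors_to_balance",
    "gap_result",
    "analyze_scenario",
    "break_even_parameter",
    "to_delimited",
    "to_markdown",
]

OVERSUPPLY_FOOTNOTE = "^a oversupply of donors"


@dataclass(frozen=True)
class GapResult:
    demand_total: int
    supply_donations: int
    gap: int  # demand - supply; positive = shortfall
    donors_to_balance: int  # positive = additional donors required


def compute_gap(demand_total: int, supply_donations: int) -> int:
    """Signed donation gap: demand minus supply."""
    if demand_total < 0 or supply_donations < 0:
        raise ValueError("demand and supply must be non-negative")
    return demand_total - supply_donations


def donors_to_balance(gap: int, births_per_donor: int) -> int:
    """Whole donors to close a shortfall (ceiling) or spare donors (floor)."""
    if births_per_donor < 1:
        raise ValueError(f"births_per_donor must be >= 1, got {births_per_donor}")
    if gap > 0:
        return -((-gap) // births_per_donor)  # ceil
    if gap < 0:
        return -((-gap) // births_per_donor)  # -floor(|gap|/b)
    return 0


def gap_result(demand_total: int, supply_donations: int, births_per_donor: int) -> GapResult:
    gap = compute_gap(demand_total, supply_donations)
    return GapResult(
        demand_total=demand_total,
        supply_donations=supply_donations,
        gap=gap,
        donors_to_balance=donors_to_balance(gap, births_per_donor),
    )


@dataclass(frozen=True)
class ScenarioOutcome:
    scenario: ScenarioSpec
    supply: SupplyResult
    demand: DemandResult
    gap: GapResult


def analyze_scenario(scenario: ScenarioSpec) -> ScenarioOutcome:
    """Run the full deterministic pipeline: funnel, demand, gap."""
    supply = run_funnel(scenario.supply)
    demand = total_demand(scenario.demand_segments)
    return ScenarioOutcome(
        scenario=scenario,
        supply=supply,
        demand=demand,
        gap=gap_result(demand.total, supply.donations, scenario.supply.births_per_donor),
    )


@dataclass(frozen=True)
class BreakEvenResult:
    """Smallest value of one funnel proportion at which supply meets demand.

    ``value`` is the reported grid point (``None`` when infeasible);
    ``relaxed_value`` solves the continuous relaxation (no integerization of
    donors), logged for reference.
    """

    parameter_path: str
    demand_total: int
    feasible: bool
    value: Fraction | None
    relaxed_value: Fraction | None


def _donations_at(scenario: ScenarioSpec, path: str, v: Fraction) -> int:
    return run_funnel(set_parameter(scenario, path, v).supply).donations


def break_even_parameter(
    scenario: ScenarioSpec,
    parameter_path: str,
    step: Fraction = Fraction(1, 10_000),
) -> BreakEvenResult:
    """Find the smallest grid value of a supply-stage proportion that closes the gap.

    The integerized supply curve is a nondecreasing step function of the
    proportion, so a binary search over the grid locates the first feasible
    point.  The continuous relaxation is linear in the parameter and is
    solved in closed form for the logged ``relaxed_value``.
    """
    parts = parameter_path.split(".")
    if len(parts) != 3 or parts[0] != "supply" or parts[1] != "stages":
        raise KeyError(
            f"break-even requires a supply-stage proportion path "
            f"('supply.stages.<name>'), got {parameter_path!r}"
        )
    stage_name = parts[2]
    scenario.supply.stage(stage_name)  # raises KeyError if unknown

    demand = total_demand(scenario.demand_segments).total
    if demand == 0:
        return BreakEvenResult(parameter_path, 0, True, Fraction(0), Fraction(0))

    if _donations_at(scenario, parameter_path, Fraction(1)) < demand:
        return BreakEvenResult(parameter_path, demand, False, None, None)

    # continuous relaxation: base * prod(other p) * v * births >= demand
    other = Fraction(scenario.supply.population_base) * scenario.supply.births_per_donor
    for p in scenario.supply.stages:
        if p.name != stage_name:
            other *= p.value
    relaxed = None if other == 0 else min(Fraction(1), Fraction(demand) / other)

    # binary search over grid points k*step, k = 0..N (last point clipped to 1)
    n_steps = int(Fraction(1) / step) + (0 if (Fraction(1) / step).denominator == 1 else 1)
    def value_at(k: int) -> Fraction:
        return min(Fraction(1), k * step)
    lo, hi = 0, n_steps  # invariant: feasible at hi
    while lo < hi:
        mid = (lo + hi) // 2
        if _donations_at(scenario, parameter_path, value_at(mid)) >= demand:
            hi = mid
        else:
            lo = mid + 1
    return BreakEvenResult(parameter_path, demand, True, value_at(hi), relaxed)


def _rows(result: GapResult, pretty: bool) -> list[list[object]]:
    fmt = format_count if pretty else str
    mark = "^a" if (pretty and result.gap < 0) else ""
    return [
        ["demand_total", fmt(result.demand_total)],
        ["supply_donations", fmt(result.supply_donations)],
        ["gap", fmt(result.gap) + mark],
        ["donors_to_balance", fmt(result.donors_to_balance) + mark],
    ]


def to_delimited(result: GapResult, sep: str = ",") -> str:
    return delimited_table(["quantity", "value"], _rows(result, pretty=False), sep)


def to_markdown(result: GapResult) -> str:
    table = markdown_table(["Quantity", "Value"], _rows(result, pretty=True))
    if result.gap < 0:
        table += "\n" + OVERSUPPLY_FOOTNOTE + "\n"
    return table
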