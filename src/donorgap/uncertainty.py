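"""One-way deterministic sweeps and binomial-thinning Monte Carlo.

The stochastic model treats each individual as independently passing each
gate with the stage probability, so every replicate count is an integer by
construction and the expectation of the chain equals the deterministic
funnel's pre-rounding value (base × ∏p).  Replicate donors are therefore
compared against that expectation, not the rounded point estimate.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from ._format import delimited_table
from .gap_analysis import analyze_scenario
from .scenario_config import DemandSegmentSpec, ScenarioSpec, set_parameter

__all__ = [
    "SweepPoint",
    "SweepResult",
    "OutputStats",
    "MonteCarloSummary",
    "one_way_sweep",
    "stochastic_funnel",
    "sweep_to_delimited",
    "mc_to_delimited",
    "plot_gap_curve",
    "plot_donor_histogram",
]


@dataclass(frozen=True)
class SweepPoint:
    value: Fraction
    donors: int
    donations: int
    demand_total: int
    gap: int
    donors_to_balance: int


@dataclass(frozen=True)
class SweepResult:
    parameter_path: str
    points: tuple[SweepPoint, ...]

    @property
    def grid(self) -> tuple[Fraction, ...]:
        return tuple(p.value for p in self.points)


def one_way_sweep(
    scenario: ScenarioSpec, parameter_path: str, grid: Sequence
) -> SweepResult:
    """Re-run the full deterministic pipeline at each grid value.

    ``grid`` must be strictly increasing fractions in [0, 1]; all other
    parameters stay fixed at the scenario's values.
    """
    values = [Fraction(v) if not isinstance(v, float) else Fraction(str(v)) for v in grid]
    if not values:
        raise ValueError("grid must be non-empty")
    for v in values:
        if not (0 <= v <= 1):
            raise ValueError(f"grid value {v} outside [0, 1]")
    if any(b <= a for a, b in zip(values, values[1:])):
        raise ValueError("grid must be strictly increasing")

    points = []
    for v in values:
        outcome = analyze_scenario(set_parameter(scenario, parameter_path, v))
        points.append(
            SweepPoint(
                value=v,
                donors=outcome.supply.donors,
                donations=outcome.supply.donations,
                demand_total=outcome.demand.total,
                gap=outcome.gap.gap,
                donors_to_balance=outcome.gap.donors_to_balance,
            )
        )
    return SweepResult(parameter_path=parameter_path, points=tuple(points))


@dataclass(frozen=True)
class OutputStats:
    mean: float
    sd: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class MonteCarloSummary:
    n_reps: int
    seed: int
    stats: Mapping[str, OutputStats]
    samples: Mapping[str, np.ndarray] | None = None


def _thin(rng: np.random.Generator, counts: np.ndarray, p: Fraction) -> np.ndarray:
    return rng.binomial(counts, float(p))


def _segment_samples(
    rng: np.random.Generator, segment: DemandSegmentSpec, n_reps: int
) -> np.ndarray:
    if segment.base_count is not None:
        units = np.full(n_reps, segment.base_count, dtype=np.int64)
    else:
        units = np.full(n_reps, segment.base_population, dtype=np.int64)
        for p in segment.base_chain:
            units = _thin(rng, units, p.value)
    for p in segment.seeking_chain:
        units = _thin(rng, units, p.value)
    return _thin(rng, units, segment.recipient_eligibility.value)


def stochastic_funnel(
    scenario: ScenarioSpec,
    n_reps: int,
    seed: int,
    return_samples: bool = False,
) -> MonteCarloSummary:
    """Chained-binomial replicates of supply and demand with summary statistics.

    A single seeded generator drives the whole run; identical ``(seed,
    n_reps)`` give identical summaries.  The 95% interval is the central
    2.5/97.5 percentile range of the replicates.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    rng = np.random.default_rng(seed)

    counts = np.full(n_reps, scenario.supply.population_base, dtype=np.int64)
    for stage in scenario.supply.stages:
        counts = _thin(rng, counts, stage.value)
    donors = counts
    donations = donors * scenario.supply.births_per_donor

    demand_total = np.zeros(n_reps, dtype=np.int64)
    for segment in scenario.demand_segments:
        demand_total = demand_total + _segment_samples(rng, segment, n_reps)

    gap = demand_total - donations
    outputs = {
        "donors": donors,
        "donations": donations,
        "demand_total": demand_total,
        "gap": gap,
    }
    stats = {}
    for name, x in outputs.items():
        lo, hi = np.percentile(x, [2.5, 97.5])
        sd = float(np.std(x, ddof=1)) if n_reps > 1 else 0.0
        stats[name] = OutputStats(mean=float(np.mean(x)), sd=sd,
                                  ci_low=float(lo), ci_high=float(hi))
    return MonteCarloSummary(
        n_reps=n_reps,
        seed=seed,
        stats=stats,
        samples=outputs if return_samples else None,
    )


def sweep_to_delimited(result: SweepResult, sep: str = ",") -> str:
    rows = [
        [p.value, p.donors, p.donations, p.demand_total, p.gap, p.donors_to_balance]
        for p in result.points
    ]
    return delimited_table(
        ["value", "donors", "donations", "demand_total", "gap", "donors_to_balance"],
        rows,
        sep,
    )


def mc_to_delimited(summary: MonteCarloSummary, sep: str = ",") -> str:
    rows = [
        [name, s.mean, s.sd, s.ci_low, s.ci_high]
        for name, s in summary.stats.items()
    ]
    return delimited_table(["output", "mean", "sd", "ci_low", "ci_high"], rows, sep)


def plot_gap_curve(result: SweepResult, path: str) -> None:
    """Plot the gap against the swept parameter (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [float(p.value) for p in result.points]
    fig, ax = plt.subplots()
    ax.plot(xs, [p.gap for p in result.points], marker="o")
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel(result.parameter_path)
    ax.set_ylabel("demand − supply (donations)")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_donor_histogram(summary: MonteCarloSummary, path: str) -> None:
    """Histogram of replicate donor counts (requires samples + matplotlib)."""
    if summary.samples is None:
        raise ValueError("summary has no samples; run with return_samples=True")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.hist(summary.samples["donors"], bins=30)
    ax.set_xlabel("donors per replicate")
    ax.set_ylabel("frequency")
    fig.savefig(path, dpi=150)
    plt.close(fig)
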