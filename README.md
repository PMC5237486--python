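# donorgap

Scenario-driven supply/demand modelling for altruistic gamete donation
programs. Two deterministic population models are implemented:

- a **supply funnel**: a male population base thinned through an ordered
  chain of proportions (program awareness → willingness to donate →
  presenting for screening → passing medical screening), capped by an
  allowable-live-births policy that converts whole donors into donation
  capacity;
- a **demand model**: per-segment demand for donor insemination from
  same-sex female couples, single women, and heterosexual couples with
  male-factor infertility, each derived from its own parameter chain and a
  recipient-eligibility filter.

On top of these sit a **gap analysis** (signed donation gap and its
whole-donor equivalent: ceiling for shortfalls, floor for surpluses, plus a
break-even solver for any single funnel proportion), **one-way sensitivity
sweeps**, a **binomial-thinning Monte Carlo** whose expectation equals the
deterministic funnel, and a **synthetic census-like population table
generator** so everything runs offline.

All model arithmetic is carried as exact rationals (`fractions.Fraction`);
proportions are stored losslessly at their printed precision (`"25%"`,
`"0.013"`, `"1/78"`), and integerization is round-half-away-from-zero,
applied only to reported per-stage counts and to the final donor count
before the capacity multiplication. This is what makes the packaged
base/best/worst scenario results reproduce their reference tables
cell-for-cell.

## CLI

```sh
donorgap run -s base -o out/base          # supply/demand/gap report for a scenario
donorgap run -c my_scenarios.yaml -s x    # ... from your own config file
donorgap sweep -s base -p supply.stages.awareness --grid 0:1:0.05 -o out/sweep
donorgap mc -s base -n 10000 --seed 7 -o out/mc
donorgap fixtures -o scenarios.yaml       # export the built-in base/best/worst
donorgap make-population --seed 1 -o pop.tsv
```

`run` writes value-preserving CSVs (exact expectations serialized as
`num/den`), Markdown tables (oversupply rendered in parentheses with a
footnote marker), and a provenance JSON (package version, config digest,
seed, timestamp). Logs go to stderr; results to stdout and files.

Scenario configuration is a small YAML dialect; see `donorgap fixtures` for
a complete, canonical example. Parameter paths are dotted identifiers such
as `supply.stages.awareness` or `demand.single_women.seeking.seeking_donation`.

## Python API

```python
import donorgap as dg

scenarios = dg.builtin_scenarios()          # {"base": ..., "best": ..., "worst": ...}
outcome = dg.analyze_scenario(scenarios["base"])
outcome.supply.donors                        # 63
outcome.supply.donations                     # 1575
outcome.demand.total                         # 7866
outcome.gap.donors_to_balance                # 252

dg.break_even_parameter(scenarios["base"], "supply.stages.awareness")
dg.one_way_sweep(scenarios["base"], "supply.stages.awareness", grid)
dg.stochastic_funnel(scenarios["base"], n_reps=10_000, seed=1)
```

## Known reconciliation notes

- The best-case funnel requires the medical-eligibility rate encoded as the
  exact rational `1/78`; the decimal `1.3%` yields 3,850 donors instead of
  3,797. The base scenario conversely requires `1.3%` (0.013). The built-in
  fixtures pin that split.
- The same-sex segment uses a calibrated direct base of 29,380 couples; the
  alternative 0.528%-of-females derivation gives 29,399 couples and demand
  4,322 rather than 4,319 (selectable via
  `builtin_scenarios(same_sex_base="fraction")`, which warns).
- Recomputing the worst-case demand rows gives 21,444 (single women), 3,766
  (heterosexual couples) and total 32,408; the reference values 21,447 /
  3,767 / 32,412 are not reproducible from the stated parameters. Both
  demand totals lead to the same 1,234-donor shortfall.
- Literal algebraic inversion of the 5:2 utilization ratio gives a
  single-women seeking rate of ≈0.081%, not the 0.06% used by the fixtures;
  `calibrate_rate_from_ratio` reports the algebraic value.
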