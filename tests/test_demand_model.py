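from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from donorgap._format import format_percent_sig, round_half_away
from donorgap.demand_model import (
    InfeasibleRateError,
    RatioSpec,
    calibrate_rate_from_ratio,
    demand_fraction,
    segment_demand,
    to_delimited,
    to_markdown,
    total_demand,
)
from donorgap.scenario_config import DemandSegmentSpec, ProportionParam


def make_segment(label="seg", base_count=None, base_population=None, base_chain=(),
                 seeking=(), eligibility=Fraction(1)):
    return DemandSegmentSpec(
        label=label,
        base_count=base_count,
        base_population=base_population,
        base_chain=tuple(
            ProportionParam.from_value(f"b{i}", v) for i, v in enumerate(base_chain)
        ),
        seeking_chain=tuple(
            ProportionParam.from_value(f"s{i}", v) for i, v in enumerate(seeking)
        ),
        recipient_eligibility=ProportionParam.from_value("recipient_eligibility", eligibility),
    )


class TestSegmentDemand:
    def test_single_women_base_case(self, base):
        expected, reported = segment_demand(base.segment("single_women"))
        assert reported == 1_287
        assert expected == Fraction(5_567_965) * Fraction("0.393") * Fraction("0.0006") * Fraction("0.98")

    def test_heterosexual_base_case(self, base):
        _, reported = segment_demand(base.segment("heterosexual_couples"))
        assert reported == 2_260

    def test_same_sex_base_case(self, base):
        _, reported = segment_demand(base.segment("same_sex_couples"))
        assert reported == 4_319

    def test_same_sex_worst_case(self, worst):
        _, reported = segment_demand(worst.segment("same_sex_couples"))
        assert reported == 7_198

    def test_calibrated_base_found_by_brute_force(self):
        """Oracle: scan integer couple counts for the ones hitting both
        published demands (4,319 at 15% wishing children, 7,198 at 25%)."""
        feasible = [
            b
            for b in range(29_000, 30_000)
            if round_half_away(Fraction(b) * Fraction("0.15") * Fraction("0.98")) == 4_319
            and round_half_away(Fraction(b) * Fraction("0.25") * Fraction("0.98")) == 7_198
        ]
        assert feasible == [29_378, 29_379, 29_380, 29_381]
        assert 29_380 in feasible  # the pinned fixture base

    def test_fraction_route_gives_documented_discrepancy(self):
        seg = make_segment(
            base_population=5_567_965,
            base_chain=[Fraction("0.00528")],
            seeking=[Fraction("0.15")],
            eligibility=Fraction("0.98"),
        )
        assert round_half_away(Fraction(5_567_965) * Fraction("0.00528")) == 29_399
        assert segment_demand(seg)[1] == 4_322  # off by 3 from the direct-count route

    def test_zero_eligibility_annihilates(self):
        seg = make_segment(base_count=10_000, seeking=[Fraction(1, 2)], eligibility=0)
        assert segment_demand(seg) == (Fraction(0), 0)


class TestTotalDemand:
    def test_base_total(self, base):
        result = total_demand(base.demand_segments)
        assert [s.reported for s in result.per_segment] == [4_319, 1_287, 2_260]
        assert result.total == 7_866

    def test_worst_total_is_reconciliation_value(self, worst):
        # Recomputed worst-case rows are 21,444 and 3,766 (published: 21,447
        # and 3,767); the recomputed total is 32,408 vs the published 32,412.
        result = total_demand(worst.demand_segments)
        assert [s.reported for s in result.per_segment] == [7_198, 21_444, 3_766]
        assert result.total == 32_408

    def test_single_segment(self):
        seg = make_segment(base_count=100, eligibility=Fraction(1, 2))
        result = total_demand([seg])
        assert result.total == result.per_segment[0].reported == 50

    def test_all_eligibilities_zero(self, base):
        segs = [
            make_segment(label=s.label, base_count=1000, eligibility=0)
            for s in base.demand_segments
        ]
        assert total_demand(segs).total == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            total_demand([])

    @given(perm=st.randoms())
    def test_permutation_invariant_total(self, base, perm):
        segs = list(base.demand_segments)
        perm.shuffle(segs)
        assert total_demand(segs).total == total_demand(base.demand_segments).total

    @given(
        base_count=st.integers(0, 10**6),
        p=st.fractions(min_value=0, max_value=1, max_denominator=1000),
        bump=st.fractions(min_value=0, max_value=1, max_denominator=1000),
    )
    def test_monotone_in_seeking_rate(self, base_count, p, bump):
        hi_p = min(Fraction(1), p + bump)
        lo = segment_demand(make_segment(base_count=base_count, seeking=[p]))
        hi = segment_demand(make_segment(base_count=base_count, seeking=[hi_p]))
        assert hi[0] >= lo[0] and hi[1] >= lo[1]


class TestDemandFraction:
    def test_worst_case_percent(self, worst):
        # published cell: 32,412 (0.58%); the exact-percent formatting is
        # checked on the published total
        from donorgap.demand_model import DemandResult

        assert format_percent_sig(Fraction(32_412, 5_567_965)) == "0.58%"

    def test_base_case_percent_two_sig_figs(self, base):
        # 7,866/5,567,965 = 0.1413% -> "0.14%" at two significant figures;
        # the published table prints "0.1%", which no rule consistent with
        # the 0.58% cell reproduces (documented inconsistency).
        frac = demand_fraction(total_demand(base.demand_segments), 5_567_965)
        assert format_percent_sig(frac) == "0.14%"

    def test_zero_total(self):
        seg = make_segment(base_count=0)
        assert format_percent_sig(demand_fraction(total_demand([seg]), 100)) == "0%"

    def test_zero_base_rejected(self, base):
        with pytest.raises(ValueError):
            demand_fraction(total_demand(base.demand_segments), 0)


class TestRatioCalibration:
    def test_single_women_rate_from_5_2_ratio(self, base):
        """Literal algebraic inversion of the 5:2 utilization ratio.

        This does NOT reproduce the published 0.06% rate — the inversion
        gives ~0.081% (1,727.6 / 2,144,446) — so the utility reports the
        algebraic value rather than forcing agreement.
        """
        target = make_segment(
            label="single_women",
            base_population=5_567_965,
            base_chain=[Fraction("0.393")],
            eligibility=Fraction("0.98"),
        )
        ratio = RatioSpec("same_sex_couples", {"same_sex_couples": 5, "single_women": 2})
        rate = calibrate_rate_from_ratio(4_319, ratio, target)
        needed = Fraction(4_319) * Fraction(2, 5)
        denom = Fraction(5_567_965) * Fraction("0.393") * Fraction("0.98")
        assert rate == needed / denom
        assert rate == pytest.approx(8.06e-4, rel=1e-2)
        assert rate != Fraction("0.0006")  # documented non-reproducibility

    def test_feeding_rate_back_recovers_target_demand(self):
        target = make_segment(
            label="b", base_population=1_000_000, base_chain=[Fraction(1, 2)],
            eligibility=Fraction("0.9"),
        )
        ratio = RatioSpec("a", {"a": 5, "b": 2})
        rate = calibrate_rate_from_ratio(4_000, ratio, target)
        solved = make_segment(
            label="b", base_population=1_000_000, base_chain=[Fraction(1, 2)],
            seeking=[rate], eligibility=Fraction("0.9"),
        )
        assert segment_demand(solved)[0] == Fraction(4_000) * Fraction(2, 5)

    def test_symmetric_ratio_recovers_reference_rate(self):
        ref_rate = Fraction(3, 100)
        ref = make_segment(label="a", base_count=50_000, seeking=[ref_rate],
                           eligibility=Fraction("0.98"))
        ref_expected, _ = segment_demand(ref)
        target = make_segment(label="b", base_count=50_000, eligibility=Fraction("0.98"))
        ratio = RatioSpec("a", {"a": 7, "b": 7})
        # identical segments + equal ratio terms -> same rate (up to the
        # integerization of the reported reference demand)
        rate = calibrate_rate_from_ratio(round_half_away(ref_expected), ratio, target)
        assert rate == pytest.approx(float(ref_rate), rel=1e-3)

    def test_infeasible_rate_raises(self):
        target = make_segment(label="b", base_count=100, eligibility=Fraction(1))
        ratio = RatioSpec("a", {"a": 1, "b": 1})
        with pytest.raises(InfeasibleRateError):
            calibrate_rate_from_ratio(10_000, ratio, target)

    def test_empty_segment_raises(self):
        target = make_segment(label="b", base_count=0, eligibility=Fraction(1))
        ratio = RatioSpec("a", {"a": 1, "b": 1})
        with pytest.raises(InfeasibleRateError):
            calibrate_rate_from_ratio(10, ratio, target)

    def test_ratio_spec_validation(self):
        with pytest.raises(ValueError):
            RatioSpec("a", {"b": 1})
        with pytest.raises(ValueError):
            RatioSpec("a", {"a": 0})


class TestExports:
    def test_delimited_roundtrip_exact(self, base):
        result = total_demand(base.demand_segments)
        lines = to_delimited(result).strip().splitlines()
        assert lines[0] == "segment,expected,reported"
        for line, seg in zip(lines[1:], result.per_segment):
            label, expected, reported = line.split(",")
            assert label == seg.label
            assert Fraction(expected) == seg.expected
            assert int(reported) == seg.reported
        assert lines[-1].split(",")[2] == str(result.total)

    def test_markdown_rows(self, base):
        md = to_markdown(total_demand(base.demand_segments), population_base=5_567_965)
        for token in ("same_sex_couples", "single_women", "heterosexual_couples",
                      "4,319", "1,287", "2,260", "7,866"):
            assert token in md
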