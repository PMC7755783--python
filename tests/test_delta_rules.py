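"""Delta-check metrics, rule evaluation, and RCV-based rule construction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deltacheck.delta_rules import (
    DeltaRule,
    build_rcv_rule,
    delta_difference,
    delta_percent_change,
    evaluate_pairs,
    evaluate_rule,
    rate_difference,
    rate_percent_change,
)
from deltacheck.uncertainty_rcv import compute_rcv

from conftest import make_pair


class TestMetrics:
    def test_delta_difference_is_signed(self):
        assert delta_difference(make_pair(9.0, 10.5)) == pytest.approx(1.5)
        assert delta_difference(make_pair(10.5, 9.0)) == pytest.approx(-1.5)
        assert delta_difference(make_pair(9.0, 9.0)) == 0.0

    def test_delta_percent_change(self):
        assert delta_percent_change(make_pair(100.0, 150.0)) == pytest.approx(50.0)
        assert delta_percent_change(make_pair(150.0, 100.0)) == pytest.approx(-33.33, abs=0.01)

    def test_dpc_non_evaluable_on_zero_previous(self):
        assert delta_percent_change(make_pair(0.0, 0.3)) is None

    def test_rates_divide_by_interval(self):
        assert rate_difference(make_pair(9.0, 10.0, days=2.0)) == pytest.approx(0.5)
        assert rate_percent_change(make_pair(100.0, 150.0, days=5.0)) == pytest.approx(10.0)

    def test_rates_non_evaluable_below_half_day_floor(self):
        pair = make_pair(9.0, 10.0, days=0.25)
        assert rate_difference(pair) is None
        assert rate_percent_change(pair) is None

    def test_rpc_inherits_dpc_guard(self):
        assert rate_percent_change(make_pair(0.0, 1.0, days=2.0)) is None


class TestRuleValidation:
    def test_limits_must_straddle_zero(self):
        with pytest.raises(ValueError, match="lower <= 0 <= upper"):
            DeltaRule(analyte="calcium", method="DD", upper_limit=-1.0,
                      lower_limit=-2.0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            DeltaRule(analyte="calcium", method="XX", upper_limit=1, lower_limit=-1)


class TestEvaluateRule:
    def test_calcium_inpatient_dd_rule_flags_large_rise(self, spec_of):
        spec = spec_of("calcium")
        rule = spec.conventional_rules["inpatient"]  # DD +-1.3 mg/dL
        assert evaluate_rule(rule, make_pair(9.0, 10.5), spec).flagged
        assert not evaluate_rule(rule, make_pair(9.0, 10.0), spec).flagged

    def test_value_exactly_at_cutoff_does_not_flag(self, spec_of):
        # cutoff 1.5 and the difference 10.5 - 9.0 are exact in binary
        spec = spec_of("calcium")
        rule = DeltaRule(analyte="calcium", method="DD", upper_limit=1.5,
                         lower_limit=-1.5)
        assert not evaluate_rule(rule, make_pair(9.0, 10.5), spec).flagged
        assert not evaluate_rule(rule, make_pair(10.5, 9.0), spec).flagged
        assert evaluate_rule(rule, make_pair(9.0, 10.75), spec).flagged

    def test_asymmetric_limits_use_signed_metric(self, spec_of):
        spec = spec_of("ast")
        rule = spec.conventional_rules["inpatient"]  # DPC +277.78 / -70.27
        # -72% fall flags, +72% rise does not
        assert evaluate_rule(rule, make_pair(100.0, 28.0, analyte="ast"), spec).flagged
        assert not evaluate_rule(rule, make_pair(100.0, 172.0, analyte="ast"), spec).flagged

    def test_within_ri_exclusion_suppresses_flag(self, spec_of):
        spec = spec_of("calcium")
        rule = DeltaRule(analyte="calcium", method="DPC", upper_limit=10.37,
                         lower_limit=-10.37, exclude_within_ri=True)
        # 8.8 -> 9.9: DPC = 100*1.1/8.8 = 12.5% > 10.37, but both in [8.6, 10.2]
        v = evaluate_rule(rule, make_pair(8.8, 9.9), spec)
        assert v.metric_value == pytest.approx(12.5)
        assert v.excluded_within_ri and not v.flagged
        # same change from outside the interval is flagged
        v2 = evaluate_rule(rule, make_pair(10.4, 11.7), spec)
        assert v2.flagged and not v2.excluded_within_ri

    def test_non_evaluable_metric_yields_unflagged_verdict(self, spec_of):
        spec = spec_of("calcium")
        rule = DeltaRule(analyte="calcium", method="DPC", upper_limit=10,
                         lower_limit=-10)
        v = evaluate_rule(rule, make_pair(0.0, 5.0), spec)
        assert v.metric_value is None and not v.flagged and not v.evaluable

    def test_rule_spec_mismatch_rejected(self, spec_of):
        rule = DeltaRule(analyte="sodium", method="DD", upper_limit=7, lower_limit=-8)
        with pytest.raises(ValueError, match="sodium"):
            evaluate_rule(rule, make_pair(9.0, 9.5), spec_of("calcium"))

    @given(
        prev=st.floats(5.0, 15.0),
        delta=st.floats(0.01, 10.0),
        days=st.floats(0.5, 40.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_within_ri_exclusion_only_removes_flags(self, spec_of, prev, delta, days):
        """Flags with the exclusion are a subset of flags without it."""
        spec = spec_of("calcium")
        base = DeltaRule(analyte="calcium", method="DPC", upper_limit=10.37,
                         lower_limit=-10.37)
        excl = DeltaRule(analyte="calcium", method="DPC", upper_limit=10.37,
                         lower_limit=-10.37, exclude_within_ri=True)
        pair = make_pair(prev, prev + delta, days=days)
        if evaluate_rule(excl, pair, spec).flagged:
            assert evaluate_rule(base, pair, spec).flagged


class TestBuildRcvRule:
    def test_base_variant_is_symmetric_dpc(self, spec_of):
        spec = spec_of("calcium")
        rcv = compute_rcv(2.10, 1.92, 2.58, analyte="calcium")
        rule = build_rcv_rule(spec, rcv, variant="base")
        assert rule.method == "DPC"
        assert rule.upper_limit == pytest.approx(10.37, abs=0.05)
        assert rule.lower_limit == -rule.upper_limit

    def test_time_scaled_variant_is_rpc_in_percent_per_day(self, spec_of):
        spec = spec_of("alt")
        rcv = compute_rcv(19.40, 5.59, 2.58, analyte="alt")
        rule = build_rcv_rule(spec, rcv, variant="time_scaled")
        assert rule.method == "RPC"
        assert rule.limit_units == "%/day"
        assert rule.upper_limit == pytest.approx(73.69, abs=0.05)

    def test_abs_2uln_variant_anchors_percentage_at_twice_uln(self, spec_of):
        from deltacheck.uncertainty_rcv import RCVResult

        spec = spec_of("calcium")
        rcv = RCVResult(analyte="calcium", cvi_percent=2.10, cva_percent=1.92,
                        k=2.58, combined_u_percent=2.845, rcv_percent=10.37)
        rule = build_rcv_rule(spec, rcv, variant="abs_2uln")
        assert rule.method == "DD"
        assert rule.upper_limit == pytest.approx(0.1037 * 2 * 10.2)  # = 2.11548 mg/dL
        assert rule.limit_units == "mg/dL"

    def test_abs_2uln_requires_positive_uln(self):
        from deltacheck.panel_model import AnalyteSpec
        from deltacheck.uncertainty_rcv import RCVResult

        spec = AnalyteSpec(name="x", units="u", ref_low=-2.0, ref_high=0.0,
                           cvi_percent=1.0)
        rcv = RCVResult(analyte="x", cvi_percent=1, cva_percent=1, k=2.58,
                        combined_u_percent=1.4, rcv_percent=5.0)
        with pytest.raises(ValueError, match="upper normal limit"):
            build_rcv_rule(spec, rcv, variant="abs_2uln")

    def test_literal_time_scaling_divides_limits_not_metric(self, spec_of):
        """The literal reading tightens with time; the default relaxes."""
        spec = spec_of("alt")
        rcv = compute_rcv(19.40, 5.59, 2.58, analyte="alt")
        literal = build_rcv_rule(spec, rcv, variant="time_scaled",
                                 literal_time_scaling=True)
        default = build_rcv_rule(spec, rcv, variant="time_scaled")
        # +40% over 10 days: RPC = 4 %/day << 73.69 -> default does not flag;
        # literal cutoff shrinks to 7.369% < 40% -> literal flags.
        pair = make_pair(50.0, 70.0, days=10.0, analyte="alt")
        assert not evaluate_rule(default, pair, spec).flagged
        assert evaluate_rule(literal, pair, spec).flagged

    @given(dpc=st.floats(-90.0, 300.0))
    @settings(max_examples=100, deadline=None)
    def test_base_rule_flags_exactly_when_abs_dpc_exceeds_rcv(self, spec_of, dpc):
        spec = spec_of("calcium")
        rcv = compute_rcv(spec.cvi_percent, spec.cva_percent, 2.58,
                          analyte="calcium")
        rule = build_rcv_rule(spec, rcv, variant="base")
        prev = 9.0
        pair = make_pair(prev, prev * (1 + dpc / 100.0))
        v = evaluate_rule(rule, pair, spec)
        assert v.flagged == (abs(v.metric_value) > rcv.rcv_percent)

    @given(days=st.floats(0.5, 30.0), extra=st.floats(0.1, 30.0))
    @settings(max_examples=60, deadline=None)
    def test_longer_interval_never_turns_time_scaled_flag_on(self, spec_of, days, extra):
        """At fixed percent change, more elapsed time can only unflag."""
        spec = spec_of("alt")
        rcv = compute_rcv(spec.cvi_percent, spec.cva_percent, 2.58, analyte="alt")
        rule = build_rcv_rule(spec, rcv, variant="time_scaled")
        short = make_pair(50.0, 120.0, days=days, analyte="alt")
        long = make_pair(50.0, 120.0, days=days + extra, analyte="alt")
        if evaluate_rule(rule, long, spec).flagged:
            assert evaluate_rule(rule, short, spec).flagged

    def test_evaluate_pairs_matches_elementwise(self, spec_of):
        spec = spec_of("calcium")
        rule = spec.conventional_rules["inpatient"]
        pairs = [make_pair(9.0, 10.5), make_pair(9.0, 9.1)]
        flags = [v.flagged for v in evaluate_pairs(rule, pairs, spec)]
        assert flags == [True, False]
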