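"""Mamdani engine: membership evaluation, inference, defuzzification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parafuzz.fuzzy import (
    FuzzyConfigError,
    FuzzyPartition,
    FuzzyRule,
    InferenceConfig,
    MembershipFunction,
    RuleBase,
    default_rule_base,
    defuzzify,
    fuzzify,
    infer,
    membership_degree,
    predict_r0,
    predict_r0_detailed,
    predict_r0_many,
    rule_base_from_dict,
    rule_base_to_dict,
)


def reference_trapezoid(x, a, b, c, d):
    """Independent scalar trapezoid (plateau precedence at vertical edges)."""
    if b <= x <= c:
        return 1.0
    if a < x < b:
        return (x - a) / (b - a)
    if c < x < d:
        return (d - x) / (d - c)
    return 0.0


class TestMembership:
    @pytest.mark.parametrize(
        "x,expected",
        [(22.0, 1.0), (18.0, 0.0), (19.0, 0.5), (28.0, 0.0),
         (20.0, 1.0), (25.0, 1.0), (26.5, 0.5), (5.0, 0.0), (40.0, 0.0)],
    )
    def test_trapezoid_examples(self, x, expected):
        mf = MembershipFunction("opt", 18, 20, 25, 28)
        assert membership_degree(mf, x) == pytest.approx(expected, abs=1e-15)

    def test_degenerate_vertical_edges(self):
        left = MembershipFunction("shoulder", 10, 10, 14, 20)
        assert membership_degree(left, 10.0) == 1.0  # plateau wins at a == b
        assert membership_degree(left, 9.999) == 0.0
        right = MembershipFunction("shoulder", 26, 30, 35, 35)
        assert membership_degree(right, 35.0) == 1.0
        assert membership_degree(right, 35.001) == 0.0

    def test_vectorized_matches_scalar(self, rng):
        mf = MembershipFunction("s", 1.0, 2.5, 4.0, 7.0)
        xs = rng.uniform(-2, 10, size=200)
        vec = mf.degree(xs)
        ref = np.array([reference_trapezoid(x, 1.0, 2.5, 4.0, 7.0) for x in xs])
        np.testing.assert_allclose(vec, ref, atol=1e-15)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        knots=st.lists(st.floats(-50, 50, allow_nan=False), min_size=4, max_size=4),
        x=st.floats(-100, 100, allow_nan=False),
    )
    def test_degree_always_in_unit_interval(self, knots, x):
        a, b, c, d = sorted(knots)
        mf = MembershipFunction("h", a, b, c, d)
        assert 0.0 <= membership_degree(mf, x) <= 1.0

    def test_invalid_breakpoints_rejected(self):
        with pytest.raises(FuzzyConfigError):
            MembershipFunction("bad", 5, 4, 6, 7)
        with pytest.raises(FuzzyConfigError):
            MembershipFunction("bad", 0, 1, np.nan, 2)


class TestPartition:
    def test_fuzzify_on_plateau_is_exclusive(self):
        rb = default_rule_base()
        deg = fuzzify(rb.temp_partition, 22.0)
        assert deg["optimal"] == 1.0
        assert deg["suboptimal_low"] == 0.0
        assert deg["suboptimal_high"] == 0.0

    def test_fuzzify_shared_edge_is_graded(self):
        rb = default_rule_base()
        deg = fuzzify(rb.temp_partition, 17.0)  # low falling, optimal rising
        assert 0.0 < deg["suboptimal_low"] < 1.0
        assert 0.0 < deg["optimal"] < 1.0

    def test_fuzzify_out_of_range_policies(self):
        rb = default_rule_base()
        zero = fuzzify(rb.temp_partition, 5.0, policy="zero")
        assert all(v == 0.0 for v in zero.values())
        clamp = fuzzify(rb.temp_partition, 5.0, policy="clamp")
        assert clamp["suboptimal_low"] == 1.0  # evaluated at the 10 degC bound

    def test_fuzzify_nonfinite_rejected(self):
        rb = default_rule_base()
        with pytest.raises(ValueError):
            fuzzify(rb.temp_partition, float("nan"))

    def test_duplicate_set_names_rejected(self):
        with pytest.raises(FuzzyConfigError):
            FuzzyPartition(
                universe=(0, 1),
                sets=(MembershipFunction("a", 0, 0, 1, 1),
                      MembershipFunction("a", 0, 0, 1, 1)),
            )

    def test_coverage_detection(self):
        gappy = FuzzyPartition(
            universe=(0.0, 10.0),
            sets=(MembershipFunction("lo", 0, 0, 2, 3),
                  MembershipFunction("hi", 7, 8, 10, 10)),
        )
        assert not gappy.covers_universe()
        assert default_rule_base().temp_partition.covers_universe()


class TestRuleBase:
    def test_empty_rules_rejected(self):
        rb = default_rule_base()
        with pytest.raises(FuzzyConfigError):
            RuleBase(rb.temp_partition, rb.r0_partition, ())

    def test_unresolved_names_rejected(self):
        rb = default_rule_base()
        with pytest.raises(FuzzyConfigError):
            RuleBase(rb.temp_partition, rb.r0_partition,
                     (FuzzyRule("nope", "low_r0"),))

    def test_uncovered_antecedent_partition_rejected(self):
        temp = FuzzyPartition(
            universe=(0.0, 10.0),
            sets=(MembershipFunction("lo", 0, 0, 2, 3),),
        )
        r0 = default_rule_base().r0_partition
        with pytest.raises(FuzzyConfigError):
            RuleBase(temp, r0, (FuzzyRule("lo", "low_r0"),))

    def test_serialization_roundtrip_lossless(self, fitted_rb):
        back = rule_base_from_dict(rule_base_to_dict(fitted_rb))
        assert back == fitted_rb

    def test_yaml_file_roundtrip_lossless(self, fitted_rb, tmp_path):
        from parafuzz.fuzzy import load_rule_base, save_rule_base

        path = tmp_path / "rules.yaml"
        save_rule_base(fitted_rb, path)
        assert load_rule_base(path) == fitted_rb


def brute_force_aggregate(rb, x, y_grid, policy):
    """Literal double loop: max over rules of min(w_i, N_i(y_j))."""
    lo, hi = rb.temp_partition.universe
    if policy == "clamp":
        x = min(max(x, lo), hi)
    out = np.zeros(len(y_grid))
    for rule in rb.rules:
        mf = rb.temp_partition[rule.antecedent]
        if policy == "zero" and (x < lo or x > hi):
            w = 0.0
        else:
            w = reference_trapezoid(x, mf.a, mf.b, mf.c, mf.d)
        cons = rb.r0_partition[rule.consequent]
        for j, y in enumerate(y_grid):
            nj = reference_trapezoid(y, cons.a, cons.b, cons.c, cons.d)
            out[j] = max(out[j], min(w, nj))
    return out


class TestInference:
    def test_plateau_input_reproduces_consequent_curve(self, cfg):
        # w = 1 on the optimal plateau clips nothing: the aggregate must
        # dominate the optimal consequent exactly wherever others are below it
        rb = default_rule_base()
        agg = infer(rb, cfg, 22.0)
        y = cfg.y_grid(rb.r0_partition)
        opt = rb.r0_partition["optimal_r0"].degree(y)
        np.testing.assert_allclose(agg, opt, atol=1e-15)

    def test_no_rule_fires_gives_zero_aggregate(self, cfg):
        rb = default_rule_base()
        agg = infer(rb, cfg, 5.0)  # below universe, zero policy
        assert np.all(agg == 0.0)

    def test_three_point_grid_matches_brute_force(self):
        rb = default_rule_base()
        cfg = InferenceConfig(output_grid=3)
        for x in (12.0, 17.0, 22.0, 27.5, 33.0):
            agg = infer(rb, cfg, x)
            ref = brute_force_aggregate(rb, x, cfg.y_grid(rb.r0_partition), "zero")
            np.testing.assert_allclose(agg, ref, atol=1e-12)

    def test_nonfinite_input_rejected(self, cfg):
        with pytest.raises(ValueError):
            infer(default_rule_base(), cfg, float("inf"))

    def test_aggregate_in_unit_interval(self, cfg, rng):
        rb = default_rule_base()
        for x in rng.uniform(0, 45, size=50):
            agg = infer(rb, cfg, float(x))
            assert agg.min() >= 0.0 and agg.max() <= 1.0


class TestDefuzzify:
    def test_symmetric_clipped_trapezoid_centroid_at_axis(self, cfg):
        y = np.linspace(0, 20, 2001)
        mf = MembershipFunction("sym", 4, 8, 12, 16)  # symmetric about 10
        agg = np.minimum(0.6, mf.degree(y))
        value, fired = defuzzify(agg, cfg, y)
        assert fired
        assert value == pytest.approx(10.0, abs=1e-9)

    def test_all_zero_aggregate_flags_no_fire(self, cfg):
        y = np.linspace(0, 20, 11)
        value, fired = defuzzify(np.zeros(11), cfg, y)
        assert value == 0.0 and not fired

    def test_coarse_grid_matches_hand_weighted_mean(self, cfg):
        # grid y = 0,5,10,15,20 with memberships 0.2,0.8,0,0.4,0.6:
        # centroid = (0*0.2+5*0.8+0+15*0.4+20*0.6)/(0.2+0.8+0+0.4+0.6) = 22/2
        y = np.linspace(0, 20, 5)
        agg = np.array([0.2, 0.8, 0.0, 0.4, 0.6])
        value, fired = defuzzify(agg, cfg, y)
        assert fired
        assert value == pytest.approx(11.0, abs=1e-12)

    def test_mean_of_maxima(self):
        cfg = InferenceConfig(defuzz_method="mom")
        y = np.linspace(0, 20, 5)
        agg = np.array([0.1, 0.9, 0.9, 0.1, 0.0])
        value, fired = defuzzify(agg, cfg, y)
        assert fired and value == pytest.approx(7.5)


class TestPredict:
    def test_out_of_range_zero_policy_flags_no_fire(self, fitted_rb, cfg):
        value, fired = predict_r0_detailed(fitted_rb, cfg, 5.0)
        assert value == 0.0 and not fired

    def test_sweep_is_unimodal(self, fitted_rb, cfg):
        # thermal response must rise to the optimum plateau then fall
        temps = np.linspace(10, 35, 201)
        r0, _ = predict_r0_many(fitted_rb, cfg, temps)
        peak = int(np.argmax(r0))
        assert 15 < temps[peak] < 30
        assert np.all(np.diff(r0[: peak + 1]) >= -1e-9)
        assert np.all(np.diff(r0[peak:]) <= 1e-9)

    def test_constant_where_only_optimal_rule_fires(self, fitted_rb, cfg):
        # On the part of the optimal plateau that no other rule's support
        # overlaps, w_opt = 1 and the prediction is constant. (The fitted
        # high-temperature set deliberately overlaps the upper plateau —
        # that is what separates R0(20)=15 from R0(25)=14.)
        for rb in (default_rule_base(), fitted_rb):
            opt = rb.temp_partition["optimal"]
            others = [rb.temp_partition[r.antecedent] for r in rb.rules
                      if r.antecedent != "optimal"]
            lo = max([opt.b] + [s.support[1] for s in others
                                if s.support[1] < opt.c])
            hi = min([opt.c] + [s.support[0] for s in others
                                if s.support[0] > opt.b])
            assert lo < hi, "plateau fully overlapped; fixture unusable"
            inside = np.linspace(lo + 1e-6, hi - 1e-6, 9)
            vals = [predict_r0(rb, cfg, float(t)) for t in inside]
            assert max(vals) - min(vals) < 1e-12

    def test_rule_order_invariance(self, fitted_rb, cfg):
        reordered = RuleBase(
            fitted_rb.temp_partition,
            fitted_rb.r0_partition,
            tuple(reversed(fitted_rb.rules)),
        )
        for x in (11.0, 17.3, 22.0, 28.6, 34.0):
            assert predict_r0(reordered, cfg, x) == predict_r0(fitted_rb, cfg, x)

    def test_output_within_union_of_fired_supports(self, fitted_rb, cfg, rng):
        for x in rng.uniform(10, 35, size=60):
            value, fired = predict_r0_detailed(fitted_rb, cfg, float(x))
            if not fired:
                continue
            supports = []
            for rule in fitted_rb.rules:
                w = membership_degree(fitted_rb.temp_partition[rule.antecedent], x)
                if w > 0:
                    supports.append(fitted_rb.r0_partition[rule.consequent].support)
            lo = min(s[0] for s in supports)
            hi = max(s[1] for s in supports)
            assert lo - 1e-9 <= value <= hi + 1e-9

    def test_vectorized_equals_scalar(self, fitted_rb, cfg, rng):
        temps = rng.uniform(5, 40, size=120)
        vec, fired = predict_r0_many(fitted_rb, cfg, temps)
        for i, t in enumerate(temps):
            v, f = predict_r0_detailed(fitted_rb, cfg, float(t))
            assert vec[i] == pytest.approx(v, abs=1e-12)
            assert fired[i] == f
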