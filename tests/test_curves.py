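"""Influence-curve construction, evaluation and the jump decomposition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lockin.curves import (CurveError, InfluenceCurve, LogisticCurve,
                           MixtureCurve, PiecewiseConstantCurve, StepCurve,
                           aggregate_curves, check_feasibility,
                           curve_from_config, decompose_curve, evaluate_curve)

# frozen from an independent evaluation of 1 / (1 + 1.5 * exp(-2))
LOGISTIC_D02_B4_AT_075 = 0.831253174318424


class TestEvaluation:
    @pytest.mark.parametrize("curve, x, expected", [
        (StepCurve(0.45, 0.55), 0.3, 0.45),
        (StepCurve(0.45, 0.55), 0.7, 0.55),
        (StepCurve(0.45, 0.55), 0.5, 0.50),       # default mid = (low+high)/2
        (LogisticCurve(d=0.2, b=7), 0.5, 0.4),    # exponent vanishes: (1-d)/2
        (LogisticCurve(d=0.2, b=4), 0.75, LOGISTIC_D02_B4_AT_075),
    ])
    def test_known_values(self, curve, x, expected):
        assert evaluate_curve(curve, x) == pytest.approx(expected, abs=1e-12)

    def test_domain_error_outside_unit_interval(self):
        c = StepCurve(0.2, 0.8)
        for bad in (-0.1, 1.0001):
            with pytest.raises(CurveError):
                c(bad)

    def test_vectorised_evaluation_matches_scalar(self):
        c = LogisticCurve(d=0.1, b=3)
        xs = np.linspace(0, 1, 11)
        assert np.allclose(c(xs), [c(float(x)) for x in xs])

    def test_piecewise_constant_bins_and_mid_convention(self):
        c = PiecewiseConstantCurve([0, 0.5, 1], [0.3, 0.7])
        assert c(0.2) == 0.3 and c(0.8) == 0.7
        assert c(0.5) == pytest.approx(0.5)  # mean of adjacent bins at the edge

    def test_non_monotone_construction_fails_loudly(self):
        with pytest.raises(CurveError):
            StepCurve(0.7, 0.3)
        with pytest.raises(CurveError):
            PiecewiseConstantCurve([0, 0.5, 1], [0.8, 0.2])

    def test_curve_invariants_on_grid(self):
        for c in (StepCurve(0.1, 0.9), LogisticCurve(d=0.3, b=5),
                  PiecewiseConstantCurve([0, 0.4, 0.5, 0.6, 1],
                                         [0.2, 0.4, 0.6, 0.8])):
            c.validate()
            grid = np.linspace(0, 1, 1001)
            vals = c(grid)
            assert np.all((vals >= 0) & (vals <= 1))
            assert np.all(np.diff(vals) >= -1e-12)
            assert c.left_limit() <= c.right_limit() + 1e-12


class TestDecomposition:
    @pytest.mark.parametrize("curve, M, d", [
        (StepCurve(0.3, 0.6), 0.3, 0.1),
        (StepCurve(0.45, 0.55), 0.1, 0.0),
        (LogisticCurve(d=0.25, b=4), 0.0, 0.25),
    ])
    def test_examples(self, curve, M, d):
        dec = decompose_curve(curve)
        assert dec.M == pytest.approx(M, abs=1e-12)
        assert dec.d == pytest.approx(d, abs=1e-12)
        assert dec.g_half == pytest.approx((dec.left_limit + dec.right_limit) / 2)
        assert dec.c == pytest.approx(dec.g_half + dec.M / 2)

    @pytest.mark.parametrize("d", [0.0, 0.1, 0.2, 0.4])
    @pytest.mark.parametrize("b", [0.0, 2.0, 5.0])
    def test_logistic_d_round_trips(self, d, b):
        dec = decompose_curve(LogisticCurve(d=d, b=b))
        assert dec.M == pytest.approx(0.0, abs=1e-12)
        assert dec.d == pytest.approx(d, abs=1e-12)

    def test_numeric_limits_fall_back_for_custom_curves(self):
        # base-class numeric limits on a plain continuous curve
        class Smooth(InfluenceCurve):
            def _value(self, x):
                return 0.2 + 0.6 * x ** 2

        dec = decompose_curve(Smooth(), eps=1e-5)
        assert dec.M == pytest.approx(0.0, abs=1e-6)
        assert dec.g_half == pytest.approx(0.35, abs=1e-6)

    @given(low=st.floats(0, 1), width=st.floats(0, 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_feasibility_holds_for_every_step_curve(self, low, width):
        high = min(low + width * (1 - low), 1.0)
        dec = decompose_curve(StepCurve(low, high))
        assert dec.left_limit >= -1e-12
        assert dec.M + dec.d <= 1 + 1e-9


class TestFeasibility:
    @pytest.mark.parametrize("M, d, ok", [
        (0.2, 0.1, True), (0.6, 0.5, False), (0.5, 0.5, True),
        (-0.1, 0.2, False), (0.2, -0.05, False), (1.0, 0.0, True),
    ])
    def test_predicate(self, M, d, ok):
        assert check_feasibility(M, d) is ok


class TestAggregation:
    @pytest.mark.parametrize("w", [0.1, 0.5, 0.9])
    def test_majority_follower_mixture_jump(self, w):
        # weight w on a pure majority-follower + (1-w) on indifference
        mix = aggregate_curves([StepCurve(0.0, 1.0), StepCurve(0.5, 0.5)],
                               [w, 1 - w])
        assert decompose_curve(mix).M == pytest.approx(w, abs=1e-12)

    def test_single_component_identity(self):
        c = LogisticCurve(d=0.2, b=3)
        mix = aggregate_curves([c], [1.0])
        xs = np.linspace(0, 1, 101)
        assert np.allclose(mix(xs), c(xs))

    def test_two_continuous_components_stay_continuous(self):
        mix = aggregate_curves([LogisticCurve(d=0.1, b=2),
                                LogisticCurve(d=0.3, b=6)], [0.4, 0.6])
        assert decompose_curve(mix).M == pytest.approx(0.0, abs=1e-12)

    def test_invalid_weights_rejected(self):
        with pytest.raises(CurveError):
            aggregate_curves([StepCurve(0.2, 0.8)], [0.9])
        with pytest.raises(CurveError):
            aggregate_curves([], [])

    @given(st.lists(st.tuples(st.floats(0, 0.5), st.floats(0.5, 1),
                              st.floats(0.01, 1)),
                    min_size=1, max_size=5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mixture_jump_is_weight_average_of_jumps(self, comps):
        curves = [StepCurve(lo, hi) for lo, hi, _ in comps]
        raw = np.array([w for _, _, w in comps])
        weights = raw / raw.sum()
        mix = MixtureCurve(curves, weights)
        expected = sum(wi * c.jump for wi, c in zip(weights, curves))
        assert decompose_curve(mix).M == pytest.approx(expected, abs=1e-12)


class TestConfig:
    def test_round_trip_configs(self):
        for cfg, x, val in [
            ({"type": "step", "low": 0.4, "high": 0.6}, 0.9, 0.6),
            ({"type": "logistic", "d": 0.2, "b": 7}, 0.5, 0.4),
            ({"type": "piecewise", "edges": [0, 0.5, 1],
              "values": [0.2, 0.8]}, 0.25, 0.2),
            ({"type": "mixture", "weights": [0.5, 0.5],
              "components": [{"type": "step", "low": 0, "high": 1},
                             {"type": "step", "low": 0.5, "high": 0.5}]},
             0.75, 0.75),
        ]:
            assert curve_from_config(cfg)(x) == pytest.approx(val)

    def test_unknown_type_rejected(self):
        with pytest.raises(CurveError):
            curve_from_config({"type": "spline"})
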