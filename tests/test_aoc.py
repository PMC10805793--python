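"""Geometry of the capacity-model AOC predictions and distance estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from dualcap import (
    AOCPoint,
    ObserverParams,
    aoc_summary,
    apply_exclusions,
    fixed_capacity_prediction,
    independent_prediction,
    serial_prediction,
    signed_distance,
    simulate_experiment,
)

acc = st.floats(0.55, 0.98)


class TestSerialPrediction:
    def test_endpoints(self):
        curve = serial_prediction(0.9, 0.8)
        np.testing.assert_allclose(curve.point_at(1.0), [0.5, 0.9])
        np.testing.assert_allclose(curve.point_at(0.0), [0.8, 0.5])

    def test_midpoint(self):
        np.testing.assert_allclose(
            serial_prediction(0.8, 0.8).point_at(0.5), [0.65, 0.65]
        )

    def test_chance_anchors_collapse_to_point(self):
        curve = serial_prediction(0.5, 0.5)
        assert np.allclose(curve.locus(11), 0.5)

    def test_below_chance_warns_but_proceeds(self):
        with pytest.warns(UserWarning, match="below chance"):
            curve = serial_prediction(0.45, 0.8)
        np.testing.assert_allclose(curve.point_at(1.0), [0.5, 0.45])


class TestFixedCapacityPrediction:
    def test_zero_share_side_drops_to_chance(self):
        curve = fixed_capacity_prediction(0.9, 0.8)
        np.testing.assert_allclose(curve.point_at(1.0), [0.5, 0.9], atol=1e-12)
        np.testing.assert_allclose(curve.point_at(0.0), [0.8, 0.5], atol=1e-12)

    def test_equal_split_closed_form(self):
        curve = fixed_capacity_prediction(0.8, 0.8)
        expected = norm.cdf(norm.ppf(0.8) / np.sqrt(2))
        np.testing.assert_allclose(
            curve.point_at(0.5), [expected, expected], atol=1e-9
        )

    def test_perfect_accuracy_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            curve = fixed_capacity_prediction(1.0, 0.8)
        assert np.isfinite(curve.locus(11)).all()

    @given(a_top=acc, a_bottom=acc)
    @settings(max_examples=50, deadline=None)
    def test_curve_weakly_outside_serial_segment(self, a_top, a_bottom):
        serial = serial_prediction(a_top, a_bottom)
        fixed = fixed_capacity_prediction(a_top, a_bottom)
        for pt in fixed.locus(41):
            res = signed_distance(AOCPoint(pt[0], pt[1]), serial)
            assert res.signed_distance >= -1e-9

    @given(a_top=acc, a_bottom=acc)
    @settings(max_examples=50, deadline=None)
    def test_shares_endpoints_with_serial_exactly(self, a_top, a_bottom):
        serial = serial_prediction(a_top, a_bottom)
        fixed = fixed_capacity_prediction(a_top, a_bottom)
        for p in (0.0, 1.0):
            np.testing.assert_allclose(
                serial.point_at(p), fixed.point_at(p), atol=1e-12
            )


class TestIndependentPrediction:
    def test_is_the_single_task_point(self):
        curve = independent_prediction(0.8, 0.9)
        np.testing.assert_allclose(curve.point_at(0.3), [0.9, 0.8])

    def test_distance_to_itself_is_zero(self):
        curve = independent_prediction(0.8, 0.9)
        res = signed_distance(AOCPoint(0.9, 0.8), curve)
        assert res.signed_distance == pytest.approx(0.0, abs=1e-12)


class TestSignedDistance:
    def test_point_on_serial_segment_has_zero_distance(self):
        curve = serial_prediction(0.86, 0.82)
        on = curve.point_at(0.37)
        res = signed_distance(AOCPoint(on[0], on[1]), curve)
        assert res.signed_distance == pytest.approx(0.0, abs=1e-9)
        assert res.p_top_hat == pytest.approx(0.37, abs=1e-6)

    @pytest.mark.parametrize("a", [0.7, 0.8, 0.9])
    def test_independent_point_to_serial_segment_analytic(self, a):
        # For equal single-task accuracies the chord is x + y = a + 0.5,
        # so the independent point (a, a) sits (a - 0.5)/sqrt(2) beyond it.
        res = signed_distance(AOCPoint(a, a), serial_prediction(a, a))
        assert res.signed_distance == pytest.approx((a - 0.5) / np.sqrt(2), abs=1e-9)

    def test_endpoint_projection_estimates_full_top_bias(self):
        res = signed_distance(AOCPoint(0.5, 0.9), serial_prediction(0.9, 0.8))
        assert res.p_top_hat == pytest.approx(1.0)

    def test_point_inside_fixed_capacity_curve_is_negative(self):
        curve = fixed_capacity_prediction(0.85, 0.85)
        res = signed_distance(AOCPoint(0.67, 0.67), curve)
        assert res.signed_distance < 0

    @given(a_top=acc, a_bottom=acc, x=acc, y=acc)
    @settings(max_examples=50, deadline=None)
    def test_distance_invariant_to_side_relabeling(self, a_top, a_bottom, x, y):
        for builder in (serial_prediction, fixed_capacity_prediction,
                        independent_prediction):
            d1 = signed_distance(AOCPoint(x, y), builder(a_top, a_bottom))
            d2 = signed_distance(AOCPoint(y, x), builder(a_bottom, a_top))
            assert d1.signed_distance == pytest.approx(
                d2.signed_distance, abs=1e-6
            )


class TestAocSummary:
    def test_independent_observer_sits_on_independent_point(
        self, independent_experiment
    ):
        kept, _ = apply_exclusions(independent_experiment)
        summary = aoc_summary(kept)
        assert len(summary) == 11
        assert abs(summary["dist_independent"].mean()) < 0.02

    def test_serial_observer_recovers_top_bias(self, serial_experiment):
        kept, _ = apply_exclusions(serial_experiment)
        summary = aoc_summary(kept)
        assert summary["p_top_hat"].mean() == pytest.approx(0.74, abs=0.05)

    def test_serial_observer_lies_inside_fixed_capacity_curve(
        self, serial_experiment
    ):
        kept, _ = apply_exclusions(serial_experiment)
        summary = aoc_summary(kept)
        assert summary["dist_fixed_capacity"].mean() < -0.03

    def test_subject_missing_a_condition_excluded_with_warning(self, caplog):
        trials = simulate_experiment(ObserverParams(), n_subjects=3, seed=11)
        broken = trials[
            ~((trials["subject"] == "S02") & (trials["cue"] == "dual"))
        ]
        with caplog.at_level("WARNING"):
            summary = aoc_summary(broken[~broken["fixation_break"]])
        assert set(summary["subject"]) == {"S01", "S03"}
        assert any("S02" in rec.message for rec in caplog.records)
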