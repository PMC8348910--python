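"""Factor scores, per-posture risk, general factors and cycle aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ergoforces import (
    angle_score,
    angular_acceleration_score,
    assess,
    factors_per_posture,
    force_score,
    general_factors,
    generate_synthetic_capture,
    grip_score,
    repetitiveness_factor,
    risk_level,
    risk_per_minute,
    risk_per_posture,
    torque_score,
)
from ergoforces.risk import (
    WorkstationContext,
    additional_factor,
    duration_factor,
    recovery_factor,
)


class TestAngleScore:
    @pytest.mark.parametrize("joint", ["lumbar", "cervical", "shoulder_r",
                                       "elbow_r", "wrist_r", "knee_r"])
    def test_neutral_posture_scores_one(self, joint, graphs):
        assert angle_score(joint, 0.0, 0.0, 0.0, graphs) == pytest.approx(1.0)

    def test_extreme_angle_saturates(self, graphs):
        assert angle_score("lumbar", 90.0, 0.0, 0.0, graphs) == pytest.approx(2.0)
        assert angle_score("wrist_r", 80.0, 0.0, 0.0, graphs) == pytest.approx(1.6)

    def test_halfway_breakpoint_interpolates(self, graphs):
        # lumbar flexion: plateau ends at 20 deg, saturates at 60 deg
        assert angle_score("lumbar", 40.0, 0.0, 0.0, graphs) == pytest.approx(1.5)

    def test_max_over_axes(self, graphs):
        only_rz = angle_score("lumbar", 0.0, 0.0, 30.0, graphs)
        both = angle_score("lumbar", 40.0, 0.0, 30.0, graphs)
        assert both == pytest.approx(max(1.5, only_rz))

    def test_shoulder_two_input_table(self, graphs):
        assert angle_score("shoulder_r", 0.0, 0.0, 0.0, graphs) == pytest.approx(1.0)
        # elevation beyond the last node saturates regardless of flexion
        assert angle_score("shoulder_r", 0.0, 0.0, 200.0, graphs) == pytest.approx(2.0)

    def test_unknown_joint_named(self, graphs):
        with pytest.raises(KeyError, match="tail"):
            angle_score("tail", 0, 0, 0, graphs)


class TestAccelerationScore:
    @pytest.mark.parametrize("accel,expected", [
        (0.0, 1.0), (50.0, 1.0), (152.5, 1.25), (255.0, 1.5), (400.0, 1.5),
    ])
    def test_lumbar_breakpoints(self, accel, expected, thresholds):
        got = angular_acceleration_score("lumbar", accel, thresholds)
        assert got == pytest.approx(expected)


class TestStressScores:
    def test_lumbar_force_bounds_male_p50(self, thresholds):
        kw = dict(thresholds=thresholds, sex="male", height=1.759)
        assert force_score("lumbar", 44.6, **kw) == pytest.approx(1.0)
        assert force_score("lumbar", 65.1, **kw) == pytest.approx(2.0)
        assert force_score("lumbar", (44.6 + 65.1) / 2, **kw) == pytest.approx(1.5)

    def test_preparation_raises_the_ceiling(self, thresholds):
        trained = force_score("lumbar", 65.1, thresholds, "male", 1.759,
                              preparation=3)
        assert trained < 2.0
        # ceiling moves to 65.1 * 1.2
        assert force_score("lumbar", 65.1 * 1.2, thresholds, "male", 1.759,
                           preparation=3) == pytest.approx(2.0)

    def test_lumbar_torque_bounds_male_p50(self, thresholds):
        kw = dict(thresholds=thresholds, sex="male", height=1.759)
        assert torque_score("lumbar", 0.0, **kw) == pytest.approx(1.0)
        assert torque_score("lumbar", 1.81, **kw) == pytest.approx(1.0)
        assert torque_score("lumbar", 22.95, **kw) == pytest.approx(2.5)
        assert torque_score("lumbar", (1.81 + 22.95) / 2, **kw) == pytest.approx(1.75)

    def test_percentile_columns_use_coefficients(self, thresholds):
        lo05, hi05 = thresholds.stress_bounds("force", "lumbar", "male", 1.649,
                                              percentile="P05")
        assert hi05 == pytest.approx(65.1 * 0.87)
        # height interpolation at the P05 stature matches the P05 column
        lo, hi = thresholds.stress_bounds("force", "lumbar", "male", 1.649)
        assert (lo, hi) == pytest.approx((lo05, hi05))


class TestGripAndFactors:
    @pytest.mark.parametrize("code,expected", [(0, 1.0), (4, 1.6), (9, 2.0)])
    def test_grip_codes(self, code, expected, thresholds):
        assert grip_score(code, thresholds) == pytest.approx(expected)

    def test_invalid_grip_code(self, thresholds):
        with pytest.raises(ValueError):
            grip_score(11, thresholds)

    def test_all_unit_scores_give_zero_factors(self):
        assert factors_per_posture(1, 1, 1, 1, 1) == pytest.approx(0.0)

    def test_wrist_maxima_reach_23(self):
        assert factors_per_posture(1.6, 1.5, 2.0, 2.5, 2.0) == pytest.approx(23.0)

    def test_lumbar_example_product(self):
        assert factors_per_posture(1.5, 1.2, 1.3, 1.4) == pytest.approx(2.276)

    def test_risk_per_posture_normalisation(self, thresholds):
        assert risk_per_posture(0.0, "lumbar", thresholds) == pytest.approx(0.0)
        assert risk_per_posture(14.0, "lumbar", thresholds) == pytest.approx(100.0)
        assert risk_per_posture(7.0, "lumbar", thresholds) == pytest.approx(50.0)
        assert risk_per_posture(23.0, "wrist_r", thresholds) == pytest.approx(100.0)


class TestGeneralFactors:
    def test_reference_workday(self):
        ctx = WorkstationContext(nonrecovery_hours=0, micropauses_factor=1.0,
                                 repetitive_hours=8.0, additional_proportion=0.0)
        assert general_factors(ctx) == pytest.approx(1.1)

    def test_component_ranges(self):
        assert recovery_factor(0) == 1.0
        assert recovery_factor(99) == 2.6
        assert duration_factor(16.0) == 2.0
        assert additional_factor(1.0) == pytest.approx(1.18)
        ctx = WorkstationContext(nonrecovery_hours=0, micropauses_factor=0.7,
                                 repetitive_hours=0.1, additional_proportion=0.0)
        # duration floor ~0.5 at vanishing repetitive time
        assert general_factors(ctx) == pytest.approx(0.7 * 0.5, rel=0.02)

    @pytest.mark.parametrize("kwargs", [
        dict(micropauses_factor=0.5), dict(repetitive_hours=0),
        dict(repetitive_hours=20), dict(nonrecovery_hours=-1),
        dict(additional_proportion=1.5), dict(cycle_time=0),
    ])
    def test_context_validation(self, kwargs):
        with pytest.raises(ValueError):
            WorkstationContext(**kwargs)


class TestRiskPerMinute:
    def test_constant_posture_collapses_to_risk_per_posture(self, thresholds):
        """Cycle-long constant factors at cycle_time duration: RPM = RPP."""
        fr, ct = 60.0, 4.0
        n = int(fr * ct)
        factors = np.full(n, 3.5)
        ctx = WorkstationContext(repetitive_hours=8.0)
        gf = general_factors(ctx)  # 1.1 at the reference workday
        rpm = risk_per_minute(factors, np.ones(n), ctx, thresholds, "lumbar",
                              fr, ct)
        assert rpm == pytest.approx(100 * 3.5 / 14 * gf)

    def test_halving_cycle_time_doubles_risk(self, thresholds):
        factors = np.full(120, 2.0)
        ctx = WorkstationContext()
        args = (factors, np.ones(120), ctx, thresholds, "lumbar", 60.0)
        assert risk_per_minute(*args, 2.0) == pytest.approx(
            2 * risk_per_minute(*args, 4.0))

    def test_zero_factors_zero_risk(self, thresholds):
        rpm = risk_per_minute(np.zeros(60), np.ones(60), WorkstationContext(),
                              thresholds, "wrist_r", 60.0, 1.0)
        assert rpm == 0.0

    def test_sixty_hz_denominator_constant(self, thresholds):
        assert thresholds.max_factors_per_posture("lumbar") * 3600 == 14 * 3600
        assert thresholds.max_factors_per_posture("wrist_l") * 3600 == 23 * 3600

    def test_duplicated_capture_with_doubled_cycle_time_invariant(self, thresholds):
        factors = np.abs(np.sin(np.arange(120) / 7.0)) * 3
        rep = repetitiveness_factor(100 * factors / 14)
        ctx = WorkstationContext()
        once = risk_per_minute(factors, rep, ctx, thresholds, "lumbar", 60.0, 2.0)
        twice = risk_per_minute(np.tile(factors, 2), np.tile(rep, 2), ctx,
                                thresholds, "lumbar", 60.0, 4.0)
        assert twice == pytest.approx(once)


class TestRepetitiveness:
    def test_anchors(self):
        assert repetitiveness_factor(0.0) == pytest.approx(1.0)
        assert repetitiveness_factor(100.0) == pytest.approx(2.0)

    @given(a=st.floats(0, 100), b=st.floats(0, 100))
    @settings(max_examples=50, derandomize=True)
    def test_nondecreasing(self, a, b):
        if a > b:
            a, b = b, a
        assert repetitiveness_factor(a) <= repetitiveness_factor(b) + 1e-12


class TestRiskLevel:
    @pytest.mark.parametrize("pct,level,valuation,interpretation", [
        (10.0, 1.0, "No risk", "Acceptable"),
        (26.9, None, "High risk", "Conditional"),
        (55.0, 4.5, "Very high risk", "Unacceptable"),
        (0.0, 0.0, "No risk", "Acceptable"),
        (85.0, 5.5, "Severe risk", "Unacceptable"),
    ])
    def test_banding(self, pct, level, valuation, interpretation):
        lvl = risk_level(pct)
        assert lvl.valuation == valuation
        assert lvl.interpretation == interpretation
        if level is not None:
            assert lvl.level == pytest.approx(level)

    @given(a=st.floats(0, 120), b=st.floats(0, 120))
    @settings(max_examples=50, derandomize=True)
    def test_level_monotone_in_risk(self, a, b):
        if a > b:
            a, b = b, a
        assert risk_level(a).level <= risk_level(b).level + 1e-12


class TestMonotonicity:
    """Raising any single scored input never lowers the per-minute risk."""

    def _rpm(self, thresholds, force=50.0, torque=5.0, accel=100.0, angle=30.0,
             grasp=0, hours=0, additional=0.0):
        s_angle = angle_score("lumbar", angle, 0, 0)
        s_acc = angular_acceleration_score("lumbar", accel, thresholds)
        s_force = force_score("lumbar", force, thresholds, "male", 1.759)
        s_torque = torque_score("lumbar", torque, thresholds, "male", 1.759)
        s_grip = grip_score(grasp, thresholds)
        fac = np.full(60, factors_per_posture(s_angle, s_acc, s_force,
                                              s_torque, s_grip))
        rep = repetitiveness_factor(100 * fac / 14)
        ctx = WorkstationContext(nonrecovery_hours=hours,
                                 additional_proportion=additional)
        return risk_per_minute(fac, rep, ctx, thresholds, "lumbar", 60.0, 1.0)

    @pytest.mark.parametrize("param,lo,hi", [
        ("force", 44.6, 60.0), ("torque", 2.0, 20.0), ("accel", 60.0, 200.0),
        ("angle", 25.0, 55.0), ("grasp", 0, 9), ("hours", 0, 5),
        ("additional", 0.0, 1.0),
    ])
    def test_each_input_nondecreasing(self, thresholds, param, lo, hi):
        assert self._rpm(thresholds, **{param: lo}) <= \
            self._rpm(thresholds, **{param: hi}) + 1e-12


class TestEndToEnd:
    def test_lift_raises_lumbar_risk_over_static(self, male_p50):
        static, _ = generate_synthetic_capture("static_stand", seed=1)
        lift, actions = generate_synthetic_capture("lift_place", seed=1)
        p_static = assess(male_p50, static)
        p_lift = assess(male_p50, lift, actions)
        assert p_lift.risk_per_posture["lumbar"].max() > \
            p_static.risk_per_posture["lumbar"].max()

    def test_static_benign_context_all_acceptable(self, male_p50):
        series, _ = generate_synthetic_capture("static_stand", seed=1)
        profile = assess(male_p50, series)
        for joint in profile.joints:
            assert profile.levels[joint].interpretation == "Acceptable"

    def test_report_frame_has_all_scored_joints(self, male_p50):
        series, _ = generate_synthetic_capture("static_stand", seed=1)
        df = assess(male_p50, series).to_frame()
        assert set(df["joint"]) == set(assess(male_p50, series).joints)
        assert {"risk_per_minute_pct", "risk_level", "valuation"} <= set(df.columns)
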