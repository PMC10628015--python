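"""Inverse planning: model inversion, power snapping, dwell equivalence,
profile planning, pauses, multi-trajectory plans and archetype targets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ablashape.planner import (
    PlanInfeasibleError,
    PlanOptions,
    TargetShape,
    achievable_envelope,
    archetype_target,
    dwell_for_width,
    insert_pauses,
    invert_width,
    plan_multi_trajectory,
    plan_profile,
    snap_power,
)
from ablashape.profiles import total_energy, validate_profile
from ablashape.shape_margin import synthesize_shape
from ablashape.width_model import CalibrationCoefficients, width_mean


class TestInvertWidth:
    def test_identity_coefficients(self):
        c = CalibrationCoefficients(0.0, 0.0, 1.0)
        assert invert_width(c, 0.0, 100.0) == pytest.approx(1.0)

    def test_forward_substitution(self):
        c = CalibrationCoefficients(30.0, 8.0, -6.0)
        v = invert_width(c, 20.0, 100.0)
        assert v == pytest.approx(np.exp((20 - 30 - 8 * np.log(100)) / -6))
        assert width_mean(c, 100.0, v) == pytest.approx(20.0, abs=1e-9)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        alpha=st.floats(-50, 50),
        bp=st.floats(0.5, 15),
        bv=st.floats(-15, -0.5),
        w=st.floats(5, 40),
        p=st.floats(20, 200),
    )
    def test_round_trip_property(self, alpha, bp, bv, w, p):
        c = CalibrationCoefficients(alpha, bp, bv)
        assert width_mean(c, p, invert_width(c, w, p)) == pytest.approx(w, abs=1e-9)

    def test_no_velocity_control_rejected(self):
        c = CalibrationCoefficients(0.0, 1.0, 0.0)
        with pytest.raises(ZeroDivisionError):
            invert_width(c, 10.0, 100.0)


class TestSnapPower:
    @pytest.mark.parametrize(
        "p_in,expected",
        [(93.0, 100.0), (90.0, 80.0), (150.0, 140.0), (10.0, 60.0), (100.0, 100.0)],
    )
    def test_nearest_with_tie_down_and_clamping(self, p_in, expected, device):
        assert snap_power(p_in, device) == expected


class TestDwellForWidth:
    def test_reference_length_over_velocity(self, coeffs):
        v = invert_width(coeffs, 20.0, 100.0)
        t = dwell_for_width(coeffs, 100.0, 20.0, d_ref=6.0)
        assert t == pytest.approx(6.0 / v)

    def test_linear_in_reference_length(self, coeffs):
        t1 = dwell_for_width(coeffs, 100.0, 20.0, d_ref=6.0)
        t2 = dwell_for_width(coeffs, 100.0, 20.0, d_ref=12.0)
        assert t2 == pytest.approx(2 * t1)

    def test_equivalent_velocity_reproduces_target(self, coeffs):
        t = dwell_for_width(coeffs, 100.0, 20.0, d_ref=6.0)
        assert width_mean(coeffs, 100.0, 6.0 / t) == pytest.approx(20.0, abs=1e-9)

    def test_capped_at_cycle_limit_with_warning(self, coeffs, device):
        # an extreme width requires an extreme dwell
        with pytest.warns(UserWarning, match="capped"):
            t = dwell_for_width(coeffs, 60.0, 31.0, d_ref=6.0, device=device)
        assert t == device.max_cycle_duration


class TestPlanProfile:
    def test_constant_cylinder_single_setting(self, coeffs, device):
        target = archetype_target("elongated", length=75.0, width=20.0)
        res = plan_profile(target, coeffs, device, PlanOptions(policy="max-throughput"))
        active = res.profile.active_segments()
        assert len({(s.power, round(s.velocity, 9)) for s in active}) == 1
        assert np.max(np.abs(res.predicted_width - 20.0)) <= 1.0
        assert validate_profile(res.profile, device) == []

    def test_infeasible_target_names_positions(self, coeffs, device):
        x = np.arange(0.0, 41.0)
        w = np.full_like(x, 20.0)
        w[20:25] = 2.0  # far below the achievable envelope
        target = TargetShape(x, w)
        with pytest.raises(PlanInfeasibleError) as err:
            plan_profile(target, coeffs, device)
        assert err.value.positions  # offending x listed
        lo, hi = err.value.envelope
        assert lo == pytest.approx(achievable_envelope(coeffs, device)[0])

    def test_randomized_targets_round_trip_within_tolerance(self, coeffs, device):
        """50 seeded piecewise-linear targets inside the envelope: planned
        profiles reproduce the target within 1 mm at every sample."""
        rng = np.random.default_rng(17)
        lo_env, hi_env = achievable_envelope(coeffs, device)
        for _ in range(50):
            length = rng.uniform(50, 90)
            knots_x = np.sort(np.concatenate([[0, length], rng.uniform(0, length, 3)]))
            knots_w = rng.uniform(lo_env + 2, hi_env - 2, knots_x.size)
            x = np.arange(0.0, length + 0.5)
            target = TargetShape(x, np.interp(x, knots_x, knots_w))
            res = plan_profile(target, coeffs, device)
            shape = synthesize_shape(res.profile, coeffs)
            err = np.abs(shape.width_at(res.x) - res.target_width)
            assert np.max(err) <= 1.0
            assert validate_profile(res.profile, device) == []

    def test_boundary_zone_avoids_maximum_power(self, coeffs, device):
        target = archetype_target("teardrop")
        res = plan_profile(
            target, coeffs, device, PlanOptions(policy="boundary-accuracy",
                                                boundary_zone_mm=10.0)
        )
        x0, x1 = res.x[0], res.x[-1]
        near = (res.x - x0 <= 10.0) | (x1 - res.x <= 10.0)
        assert np.all(res.power[near] < max(device.allowed_powers))

    def test_planner_is_deterministic(self, coeffs, device):
        target = archetype_target("dumbbell")
        a = plan_profile(target, coeffs, device)
        b = plan_profile(target, coeffs, device)
        assert a.profile.segments == b.profile.segments

    def test_long_plan_split_into_cycles(self, coeffs, device):
        # low-power boundary policy on a long cylinder needs > 6 min active
        target = archetype_target("elongated", length=95.0, width=20.0)
        res = plan_profile(target, coeffs, device, PlanOptions(policy="boundary-accuracy"))
        assert validate_profile(res.profile, device) == []
        assert any(not s.is_active for s in res.profile.segments)


class TestInsertPauses:
    def test_no_boundaries_is_identity(self, simple_profile):
        assert insert_pauses(simple_profile, []).segments == simple_profile.segments

    def test_pause_adds_segment_preserves_energy(self, simple_profile, device):
        q = insert_pauses(simple_profile, [17.5])
        assert len(q.segments) == len(simple_profile.segments) + 2
        assert total_energy(q) == pytest.approx(total_energy(simple_profile))
        assert validate_profile(q, device) == []

    def test_boundary_outside_span_rejected(self, simple_profile):
        with pytest.raises(ValueError):
            insert_pauses(simple_profile, [99.0])


class TestMultiTrajectory:
    def test_single_target_reduces_to_plan_profile(self, coeffs, device):
        target = archetype_target("elongated")
        multi = plan_multi_trajectory([target], coeffs, device)
        single = plan_profile(target, coeffs, device)
        assert multi[0].profile.segments == single.profile.segments

    def test_second_trajectory_offset_by_minus_20(self, coeffs, device):
        target = archetype_target("elongated", length=60.0, width=20.0)
        opts = PlanOptions(policy="max-throughput")
        first, second = plan_multi_trajectory([target, target], coeffs, device, opts)
        p1 = {s.power for s in first.profile.active_segments()}
        p2 = {s.power for s in second.profile.active_segments()}
        assert p2 == {p - 20.0 for p in p1}

    def test_zero_offset_gives_identical_profiles(self, coeffs, device):
        target = archetype_target("elongated", length=60.0, width=20.0)
        opts = PlanOptions(policy="max-throughput", trajectory_power_offset=0.0)
        first, second = plan_multi_trajectory([target, target], coeffs, device, opts)
        assert first.profile.segments == second.profile.segments

    def test_empty_target_list_rejected(self, coeffs, device):
        with pytest.raises(ValueError):
            plan_multi_trajectory([], coeffs, device)


class TestArchetypes:
    def test_elongated_constant_width(self):
        t = archetype_target("elongated", length=75.0, width=20.0)
        assert t.length == pytest.approx(75.0)
        assert np.all(t.width == 20.0)

    def test_teardrop_monotone_taper(self):
        t = archetype_target("teardrop", length=68.0, width_start=25.0, width_end=17.0)
        assert t.width[0] == pytest.approx(25.0)
        assert t.width[-1] == pytest.approx(17.0)
        assert np.all(np.diff(t.width) <= 0)

    def test_connected_spheres_symmetric_two_lobes(self):
        t = archetype_target("connected_spheres", length=91.0, lobe_width=22.0)
        assert t.width.max() == pytest.approx(22.0)
        np.testing.assert_allclose(t.width, t.width[::-1], atol=1e-9)
        # two local maxima at the lobe centers
        c1, c2 = 11.0, 80.0
        assert t.width_at(c1) == pytest.approx(22.0)
        assert t.width_at(c2) == pytest.approx(22.0)
        assert t.width_at(45.5) < 22.0

    def test_dumbbell_two_bulges_with_waist(self):
        t = archetype_target("dumbbell", length=63.0, lobe_widths=(26.0, 26.0),
                             waist_width=9.0)
        # lobe peaks sit between 1 mm grid samples; allow interpolation slack
        assert t.width.max() == pytest.approx(26.0, abs=0.05)
        assert t.width_at(31.5) == pytest.approx(9.0, abs=0.1)
        assert t.width_at(63.0 / 4) == pytest.approx(26.0, abs=0.05)

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ValueError):
            archetype_target("banana")

    def test_sphere_target_planned_as_stationary_dwell(self, coeffs, device):
        t = archetype_target("connected_spheres", length=22.0, lobe_width=22.0,
                             neck_width=1e-3)
        res = plan_profile(t, coeffs, device)
        assert "stationary-dwell" in res.flags
        (seg,) = res.profile.segments
        assert seg.is_dwell and seg.is_active
        assert res.predicted_width[0] == pytest.approx(22.0, abs=1e-9)
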