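"""Mechanism model: kinematics, speed planning, quantization, homing."""

import numpy as np
import pytest

from lungtwin import (
    BreathingSpec,
    GeometryConfig,
    MachineState,
    MotorSpec,
    SpeedProfile,
    forward_kinematics,
    home,
    quantize,
    required_vertical_angle,
    sample_loop,
    simulate_run,
    solve_speed_profile,
)
from lungtwin._geom import polyline_distances


class TestMotorSpec:
    def test_full_step_resolution(self):
        assert MotorSpec(1.8, 1).steps_per_rev == 200
        assert MotorSpec(1.8, 32).pulses_per_rev == 6400
        assert MotorSpec(1.8, 32).microstep_deg == pytest.approx(0.05625)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            MotorSpec(full_step_deg=1.7)
        with pytest.raises(ValueError):
            MotorSpec(microstep_divisor=3)


class TestForwardKinematics:
    @pytest.mark.parametrize(
        "th, tv, xy",
        [(0.0, 0.0, (0.0, 0.0)), (180.0, 180.0, (20.0, 20.0)),
         (90.0, 90.0, (10.0, 10.0))],
    )
    def test_landmarks(self, geometry, th, tv, xy):
        assert forward_kinematics(th, tv, geometry) == pytest.approx(xy, abs=1e-12)

    def test_periodic_in_both_angles(self, geometry, rng):
        th = rng.uniform(0, 360, 16)
        tv = rng.uniform(0, 360, 16)
        a = forward_kinematics(th, tv, geometry)
        b = forward_kinematics(th + 360.0, tv + 720.0, geometry)
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestRequiredVerticalAngle:
    def test_landmarks(self, geometry, breathing):
        T = breathing.period_s
        assert required_vertical_angle(0.0, geometry, breathing) == 0.0
        assert required_vertical_angle(T / 2, geometry, breathing) == pytest.approx(180.0)
        assert required_vertical_angle(T, geometry, breathing) == pytest.approx(360.0)
        # at T/4: x = r, y = h/4, so cos th = 1 - 1/2
        assert required_vertical_angle(T / 4, geometry, breathing) == pytest.approx(60.0)

    def test_monotone_and_inverts_kinematics(self, geometry, breathing):
        """th*(t) must be nondecreasing and map back onto the ideal loop."""
        t = np.linspace(0.0, breathing.period_s, 2001)
        th = required_vertical_angle(t, geometry, breathing)
        assert np.all(np.diff(th) >= -1e-9)
        _, y_back = forward_kinematics(np.zeros_like(th), th, geometry)
        from lungtwin import y_of_time

        np.testing.assert_allclose(y_back, y_of_time(t, geometry, breathing),
                                   atol=1e-9)

    def test_flat_loop_rejected(self, breathing):
        flat = GeometryConfig(r=10.0, d1=0.0, d2=20.0, l=20.0)
        with pytest.raises(ValueError, match="h = 0"):
            required_vertical_angle(1.0, flat, breathing)


class TestSpeedProfile:
    def test_collocation_invariants(self, geometry, breathing):
        p = solve_speed_profile(geometry, breathing)
        tb = np.asarray(p.section_boundaries_s)
        w = np.asarray(p.section_speeds_dps)
        assert tb[-1] - tb[0] == pytest.approx(breathing.period_s, abs=1e-9)
        np.testing.assert_allclose(w * np.diff(tb), 60.0, atol=1e-6)
        assert p.horizontal_speed_dps == pytest.approx(360.0 / breathing.period_s)
        # collocation exactness: accumulated angle hits k*60 at each boundary
        np.testing.assert_allclose(
            p.theta_v(tb), np.arange(7) * 60.0, atol=1e-7
        )
        np.testing.assert_allclose(
            required_vertical_angle(tb, geometry, breathing),
            np.arange(7) * 60.0, atol=1e-7,
        )

    def test_mean_speed_is_96_dps_at_16_bpm(self, geometry):
        p = solve_speed_profile(geometry, BreathingSpec(period_s=3.75))
        assert p.horizontal_speed_dps == pytest.approx(96.0)

    def test_cosine_target_needs_no_modulation(self, geometry, breathing):
        """If the ideal vertical motion already is the crank's natural
        cosine, all six section speeds equal the horizontal speed."""
        T, h = breathing.period_s, geometry.h
        cosine = lambda t: (h / 2) * (1 - np.cos(2 * np.pi * np.asarray(t) / T))
        p = solve_speed_profile(geometry, breathing, y_fn=cosine)
        np.testing.assert_allclose(p.section_speeds_dps, 360.0 / T, rtol=1e-6)

    def test_profile_tracks_angle_better_than_uniform(self, geometry, breathing):
        t = np.linspace(0.0, breathing.period_s, 1001)
        target = required_vertical_angle(t, geometry, breathing)
        uniform = SpeedProfile.uniform(breathing.period_s)
        colloc = solve_speed_profile(geometry, breathing)
        err_u = np.max(np.abs(uniform.theta_v(t) - target))
        err_c = np.max(np.abs(colloc.theta_v(t) - target))
        assert err_c < err_u

    def test_refinement_reduces_path_deviation(self, geometry, breathing):
        loop = sample_loop(geometry, breathing, 2000)
        t = np.linspace(0.0, breathing.period_s, 400)
        from lungtwin import x_of_time

        def max_dev(profile):
            th = profile.theta_v(t)
            x = x_of_time(t, geometry, breathing)
            y = (geometry.h / 2) * (1 - np.cos(np.radians(th)))
            return polyline_distances(np.column_stack([x, y]),
                                      loop.vertices).max()

        colloc = solve_speed_profile(geometry, breathing)
        refined = solve_speed_profile(geometry, breathing, refine=True,
                                      refine_grid=101, refine_polyline=601)
        assert max_dev(refined) < max_dev(colloc)

    def test_flat_loop_rejected(self, breathing):
        flat = GeometryConfig(r=10.0, d1=0.0, d2=20.0, l=20.0)
        with pytest.raises(ValueError):
            solve_speed_profile(flat, breathing)

    def test_invalid_profile_rejected(self, breathing):
        with pytest.raises(ValueError, match="60 degrees"):
            SpeedProfile(96.0, (96.0,) * 6,
                         tuple(np.linspace(0, 3.75, 7) * 0.9))


class TestQuantize:
    @pytest.mark.parametrize("divisor, expected", [(1, 200), (32, 6400)])
    def test_pulse_count_per_revolution(self, geometry, breathing, divisor, expected):
        p = solve_speed_profile(geometry, breathing)
        stream = quantize(p, MotorSpec(1.8, divisor), n_cycles=1)
        assert (stream.motor == "horizontal").sum() == expected
        assert (stream.motor == "vertical").sum() == expected
        assert np.all(stream.direction == 1)

    def test_uniform_full_step_interval(self):
        p = SpeedProfile.uniform(4.0)
        stream = quantize(p, MotorSpec(1.8, 1), n_cycles=1)
        for m in ("horizontal", "vertical"):
            np.testing.assert_allclose(np.diff(stream.times(m)), 0.020,
                                       atol=1e-12)

    def test_timestamps_monotone(self, geometry, breathing, motor):
        p = solve_speed_profile(geometry, breathing)
        stream = quantize(p, motor, n_cycles=2)
        assert np.all(np.diff(stream.t) >= 0)
        for m in ("horizontal", "vertical"):
            assert np.all(np.diff(stream.times(m)) > 0)

    def test_stream_integration_matches_profile(self, geometry, breathing, motor):
        """Angle reconstructed by counting pulses equals the profile's
        piecewise-linear integral within one microstep at every pulse."""
        p = solve_speed_profile(geometry, breathing)
        stream = quantize(p, motor, n_cycles=1)
        t_v = stream.times("vertical")
        reconstructed = np.arange(1, len(t_v) + 1) * motor.microstep_deg
        np.testing.assert_allclose(reconstructed, p.theta_v(t_v),
                                   atol=motor.microstep_deg)

    def test_csv_export_header(self, tmp_path, geometry, breathing):
        p = solve_speed_profile(geometry, breathing)
        path = tmp_path / "steps.csv"
        quantize(p, MotorSpec(1.8, 1)).to_csv(path)
        assert path.read_text().splitlines()[0] == "t_s,motor,direction"


class TestHoming:
    def test_forward_only_from_past_endstop(self, motor):
        state = home(MachineState(angle_h_deg=90.0, angle_v_deg=90.0), motor)
        assert state.homed
        # rotates 270 deg forward (never backward) to re-trigger
        assert state.angle_h_deg - 90.0 == pytest.approx(270.0,
                                                         abs=motor.microstep_deg)
        assert state.angle_h_deg % 360.0 < motor.microstep_deg

    def test_exactly_at_endstop(self, motor):
        state = home(MachineState(), motor)
        assert state.homed
        assert state.angle_h_deg % 360.0 in (0.0,)

    def test_idempotent(self, motor):
        once = home(MachineState(angle_h_deg=123.4, angle_v_deg=7.0), motor)
        assert home(once, motor) == once

    def test_lands_within_one_microstep(self, motor, rng):
        for a in rng.uniform(0.0, 360.0, 25):
            state = home(MachineState(angle_h_deg=a, angle_v_deg=a / 2), motor)
            for ang in (state.angle_h_deg, state.angle_v_deg):
                assert (ang % 360.0) < motor.microstep_deg + 1e-9


class TestSimulateRun:
    def test_full_range_single_cycle(self, geometry, breathing, motor):
        sim = simulate_run(geometry, breathing, motor, n_cycles=1,
                           include_homing=False)
        inc = max(geometry.r, geometry.h / 2) * np.radians(motor.microstep_deg)
        assert sim.x.min() == 0.0 and sim.y.min() == 0.0
        assert sim.x.max() == pytest.approx(2 * geometry.r, abs=2 * inc)
        assert sim.y.max() == pytest.approx(geometry.h, abs=2 * inc)

    def test_sample_count_bookkeeping(self, geometry, breathing, motor):
        sim = simulate_run(geometry, breathing, motor, n_cycles=20, seed=3)
        assert len(sim) == 20 * 2 * 6400
        assert sim.cycle_index.min() == 0 and sim.cycle_index.max() == 19
        np.testing.assert_array_equal(np.unique(sim.cycle_index), np.arange(20))

    def test_continuity_one_microstep(self, geometry, breathing, motor):
        sim = simulate_run(geometry, breathing, motor, n_cycles=1,
                           include_homing=False)
        inc = max(geometry.r, geometry.h / 2) * np.radians(motor.microstep_deg)
        steps = np.hypot(np.diff(sim.x), np.diff(sim.y))
        assert steps.max() <= inc + 1e-12

    def test_uniform_profile_traces_diagonal(self, geometry, breathing, motor):
        """Equal motor speeds degenerate the loop to the straight segment
        y = (h/2r) x, up to one microstep."""
        p = SpeedProfile.uniform(breathing.period_s)
        sim = simulate_run(geometry, breathing, motor, n_cycles=1,
                           include_homing=False, profile=p)
        slope = geometry.h / (2 * geometry.r)
        line_dev = np.abs(sim.y - slope * sim.x) / np.hypot(1.0, slope)
        inc = max(geometry.r, geometry.h / 2) * np.radians(motor.microstep_deg)
        assert line_dev.max() <= inc + 1e-12

    def test_deviation_shrinks_with_finer_microstepping(self, geometry, breathing):
        loop = sample_loop(geometry, breathing, 2000)
        devs = []
        for divisor in (1, 32):
            sim = simulate_run(geometry, breathing, MotorSpec(1.8, divisor),
                               n_cycles=1, include_homing=False)
            pts = np.column_stack([sim.x, sim.y])
            devs.append(polyline_distances(pts, loop.vertices).max())
        assert devs[1] <= devs[0]

    def test_transient_settles_by_cycle_three(self, geometry, breathing, motor):
        """With homing, the first two cycles run unsynchronized and deviate;
        from cycle 2 the profile engages and deviations drop."""
        from lungtwin import deviation_report

        sim = simulate_run(geometry, breathing, motor, n_cycles=4, seed=11,
                           include_homing=True)
        loop = sample_loop(geometry, breathing, 2000)
        rep = deviation_report(sim, loop, n_sync=2)
        per = rep.per_cycle["max_dev_mm"].to_numpy()
        assert per[0] > 2 * per[2]
        assert per[1] > 2 * per[3]
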