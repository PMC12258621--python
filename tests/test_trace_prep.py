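"""Raw-trajectory preparation: drift correction, angle extraction,
unit conversion, filtering and re-zeroing."""

import numpy as np
import pytest

import rloopkinetics as rk
from rloopkinetics.states import State, StateSequence
from rloopkinetics.trace import (
    TwistTrace,
    XYTrajectory,
    angle_trace_to_bp,
    bp_to_turns,
    drift_correct,
    filter_trace,
    repair_zero_crossings,
    rezero,
    turns_to_bp,
    xy_to_angle,
)


def _circle_traj(n=1000, center=(0.0, 0.0), rate=1000.0, noise=0.0, seed=0,
                 omega=7.0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate
    ang = omega * t
    x = center[0] + np.cos(ang) + noise * rng.standard_normal(n)
    y = center[1] + np.sin(ang) + noise * rng.standard_normal(n)
    return XYTrajectory(t, x, y)


class TestDriftCorrect:
    def test_circle_center_removed(self):
        traj = _circle_traj(center=(3.0, -2.0))
        out = drift_correct(traj, window=1.0)
        # the fitted center (3, -2) is subtracted exactly: what remains
        # is the unit circle itself
        ang = 7.0 * traj.time
        np.testing.assert_allclose(out.x, np.cos(ang), atol=1e-6)
        np.testing.assert_allclose(out.y, np.sin(ang), atol=1e-6)

    def test_linear_drift_across_windows_recovered(self):
        # center drifts 0.3 units/s; per-window centers must be removed
        rate = 1000.0
        n = 5000
        t = np.arange(n) / rate
        ang = 9.0 * t
        drift = 0.3 * t
        traj = XYTrajectory(t, np.cos(ang) + drift, np.sin(ang) - drift)
        out = drift_correct(traj, window=0.5)
        r = np.hypot(out.x, out.y)
        # within-window residual drift is at most ~0.15; centers removed
        assert np.abs(np.mean(out.x)) < 0.02
        assert np.abs(r.mean() - 1.0) < 0.02

    def test_idempotent_on_circle_data(self):
        traj = _circle_traj(center=(1.0, 1.0), noise=0.01, seed=3)
        once = drift_correct(traj)
        twice = drift_correct(once)
        np.testing.assert_allclose(once.x, twice.x, atol=5e-3)
        np.testing.assert_allclose(once.y, twice.y, atol=5e-3)

    def test_degenerate_window_falls_back_to_centroid(self):
        t = np.arange(4) / 1000.0
        traj = XYTrajectory(t, np.full(4, 2.0), np.full(4, 5.0))
        out = drift_correct(traj, window=1.0)
        np.testing.assert_allclose(out.x, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.y, 0.0, atol=1e-12)


class TestAngleExtraction:
    def test_quadrant_walk_unwraps_to_full_turn(self):
        t = np.arange(5) / 100.0
        traj = XYTrajectory(t, [1, 0, -1, 0, 1], [0, 1, 0, -1, 0])
        trace = xy_to_angle(traj)
        np.testing.assert_allclose(trace.theta, [0, 0.25, 0.5, 0.75, 1.0])

    def test_constant_position_constant_angle(self):
        t = np.arange(10) / 100.0
        traj = XYTrajectory(t, np.full(10, 0.4), np.full(10, 0.4))
        trace = xy_to_angle(traj)
        np.testing.assert_allclose(trace.theta, trace.theta[0])

    def test_angular_velocity_recovered_by_regression(self):
        omega = 11.0  # rad/s
        traj = _circle_traj(n=4000, noise=0.05, seed=1, omega=omega)
        trace = xy_to_angle(traj)
        slope = np.polyfit(trace.time, trace.theta, 1)[0]
        assert slope * 2 * np.pi == pytest.approx(omega, rel=0.01)

    def test_winding_number_matches_total_turns(self):
        # noise-free path: unwrapped angle span equals the winding number
        traj = _circle_traj(n=3000, rate=1000.0, omega=4 * np.pi)
        trace = xy_to_angle(traj)
        winding = 4 * np.pi * (trace.time[-1] - trace.time[0]) / (2 * np.pi)
        assert trace.theta[-1] - trace.theta[0] == pytest.approx(winding, rel=1e-6)

    def test_origin_sample_propagates_previous_angle(self):
        t = np.arange(4) / 100.0
        traj = XYTrajectory(t, [1.0, 0.0, 0.0, 1.0], [0.0, 0.0, 1.0, 0.0])
        trace = xy_to_angle(traj)
        assert trace.theta[1] == trace.theta[0]

    def test_artifact_jump_repaired(self):
        turns = np.zeros(100)
        turns[40:60] += 1.0  # spurious integer-rotation excursion
        fixed = repair_zero_crossings(turns)
        np.testing.assert_allclose(fixed, 0.0)


class TestUnits:
    def test_turns_bp_round_trip_exact(self):
        x = np.array([-3.25, 0.0, 1.0, 10.5, 21.0])
        np.testing.assert_array_equal(turns_to_bp(bp_to_turns(x)), x)

    def test_unwinding_is_positive_bp(self):
        # negative rotation (unwinding) maps to positive bp
        assert turns_to_bp(-1.0) == pytest.approx(10.5)

    def test_angle_trace_conversion_sets_metadata(self):
        t = np.arange(5) / 100.0
        tr = TwistTrace(t, np.full(5, -2.0), 100.0, metadata={"units": "turns"})
        out = angle_trace_to_bp(tr)
        assert out.metadata["units"] == "bp"
        np.testing.assert_allclose(out.theta, 21.0)


class TestFilter:
    def test_constant_trace_unchanged(self):
        t = np.arange(100) / 5000.0
        tr = TwistTrace(t, np.full(100, 2.5), 5000.0)
        out = filter_trace(tr, 500.0)
        np.testing.assert_allclose(out.theta, 2.5)
        assert out.sample_rate == 500.0

    def test_white_noise_variance_reduced_by_block_size(self):
        rng = np.random.default_rng(2)
        n = 200000
        tr = TwistTrace(np.arange(n) / 5000.0, rng.standard_normal(n), 5000.0)
        out = filter_trace(tr, 500.0)
        assert np.var(out.theta) == pytest.approx(1 / 10, rel=0.05)

    def test_step_smeared_by_at_most_one_output_sample(self):
        n = 1000
        theta = np.where(np.arange(n) < 503, 0.0, 4.0)
        tr = TwistTrace(np.arange(n) / 5000.0, theta, 5000.0)
        out = filter_trace(tr, 500.0)
        interior = (out.theta > 0.01) & (out.theta < 3.99)
        assert interior.sum() <= 1

    def test_mean_preserved(self):
        rng = np.random.default_rng(3)
        tr = TwistTrace(np.arange(5000) / 5000.0, rng.standard_normal(5000), 5000.0)
        out = filter_trace(tr, 500.0)
        assert out.theta.mean() == pytest.approx(tr.theta.mean(), abs=1e-12)

    def test_upsampling_rejected(self):
        tr = TwistTrace(np.arange(10) / 500.0, np.zeros(10), 500.0)
        with pytest.raises(ValueError, match="exceeds"):
            filter_trace(tr, 5000.0)


class TestRezero:
    def _states(self, closed_level):
        return StateSequence(
            [
                State("C", closed_level, 5.0, 0.0, 5.0),
                State("I", closed_level + 10, 1.0, 5.0, 6.0),
            ]
        )

    def test_offset_recorded_and_removed(self):
        t = np.arange(10) / 500.0
        tr = TwistTrace(t, np.full(10, 1.4), 500.0)
        out = rezero(tr, self._states(1.4))
        np.testing.assert_allclose(out.theta, 0.0)
        assert out.zero_reference == pytest.approx(1.4)

    def test_idempotent_when_already_zeroed(self):
        t = np.arange(10) / 500.0
        tr = TwistTrace(t, np.zeros(10), 500.0)
        out = rezero(tr, self._states(0.0))
        assert out.zero_reference == 0.0

    def test_no_closed_state_rejected(self):
        t = np.arange(10) / 500.0
        tr = TwistTrace(t, np.zeros(10), 500.0)
        seq = StateSequence([State("I", 10.0, 1.0, 0.0, 1.0)])
        with pytest.raises(ValueError, match="closed"):
            rezero(tr, seq)

    def test_simulated_langmuir_offsets_average_to_injected_shift(self):
        """Round trip: per-tether recorded offsets vs the generative shift."""
        base = rk.LangmuirBaseline(delta_theta_sat=3.7, kd_eff=14.0)
        offsets = []
        for seed in range(5):
            cfg = rk.simulate.dspry_config(
                rate_kCI_law=rk.FixedLaw(0.02),
                duration=300.0,
                rnp_conc=25.0,
                baseline_shift=base,
                seed=700 + seed,
            )
            _, tr = rk.simulate.simulate_experiment(cfg)
            base_cfg = rk.simulate.dspry_config(
                rate_kCI_law=rk.FixedLaw(0.0), duration=120.0, seed=800 + seed
            )
            _, btr = rk.simulate.simulate_experiment(base_cfg)
            ou = rk.calibrate_ou(btr)
            from rloopkinetics.pipeline import analyze_trace

            offsets.append(analyze_trace(tr, ou)["offset_bp"])
        true_shift = base.offset(25.0)
        assert np.mean(offsets) == pytest.approx(true_shift, abs=0.25)


class TestIO:
    def test_trace_round_trip(self, tmp_path):
        t = np.arange(20) / 500.0
        tr = TwistTrace(
            t, np.linspace(0, 5, 20), 500.0, zero_reference=1.2,
            metadata={"enzyme": "dSpRY", "conc_nM": 4.0},
        )
        p = tmp_path / "trace.tsv"
        tr.write(p)
        back = TwistTrace.read(p)
        np.testing.assert_allclose(back.theta, tr.theta)
        assert back.sample_rate == 500.0
        assert back.zero_reference == 1.2
        assert back.metadata["enzyme"] == "dSpRY"
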