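import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsttc.gs_model import (
    HOLD,
    MOVE_BACKWARD,
    PriorSpec,
    approach_speed_from_size,
    combine_mle,
    distance_from_size,
    navigation_signal,
    ttc_gs,
    ttc_gs_series,
)
from gsttc.scenarios import offset_landing_grid


class TestCalibrationEquations:
    def test_distance_arithmetic(self):
        assert distance_from_size(0.074, 0.0074) == pytest.approx(10.0)

    def test_distance_geometry_oracle(self):
        theta = 2 * np.arctan(0.037 / 30.0)
        assert distance_from_size(0.074, theta) == pytest.approx(30.0, rel=1e-4)

    def test_distance_rejects_nonpositive_theta(self):
        with pytest.raises(ValueError):
            distance_from_size(0.074, 0.0)

    def test_approach_speed_kinematic_oracle(self):
        # constant approach: theta_dot = s V / D^2 in the small-angle limit
        d, v, s = 10.0, 5.0, 0.074
        theta = s / d
        theta_dot = s * v / d**2
        assert approach_speed_from_size(s, theta, theta_dot) == pytest.approx(v, rel=1e-3)

    def test_approach_speed_signs(self):
        assert approach_speed_from_size(0.074, 0.01, 0.0) == 0.0
        assert approach_speed_from_size(0.074, 0.01, -0.002) < 0


class TestTtcGs:
    def test_launch_instant_identity(self):
        # at launch the estimate equals the full flight time up to the
        # small-angle approximation s/theta ~ D
        for z in (15.0, 20.0, 30.0, 40.0, 50.0):
            theta = 2 * np.arctan(0.037 / z)
            est = ttc_gs(theta, 0.0, 9.807 / z, PriorSpec())
            assert abs(est - 2.0) / 2.0 <= 1e-4

    def test_zero_elevation_rate_gives_zero(self):
        assert ttc_gs(0.01, 0.1, 0.0, PriorSpec()) == 0.0

    def test_prior_proportionality(self):
        base = ttc_gs(0.005, 0.1, 0.3, PriorSpec(gravity=9.807, size=0.074))
        assert ttc_gs(0.005, 0.1, 0.3, PriorSpec(gravity=2 * 9.807, size=0.074)) == pytest.approx(base / 2)
        assert ttc_gs(0.005, 0.1, 0.3, PriorSpec(gravity=9.807, size=2 * 0.074)) == pytest.approx(2 * base)

    def test_prior_error_propagates_proportionally(self):
        # first-order: relative TTC error at launch = relative size-prior error
        theta = 2 * np.arctan(0.037 / 30.0)
        for eps in (-0.05, 0.05):
            est = ttc_gs(theta, 0.0, 9.807 / 30.0, PriorSpec(size=0.074 * (1 + eps)))
            assert (est - 2.0) / 2.0 == pytest.approx(eps, abs=2e-4)
            est_g = ttc_gs(theta, 0.0, 9.807 / 30.0, PriorSpec(gravity=9.807 * (1 + eps)))
            assert (est_g - 2.0) / 2.0 == pytest.approx(-eps / (1 + eps), abs=2e-4)


class TestTtcSeries:
    def test_collision_course_error_below_10ms(self, family_runs):
        for sc, traj, obs, stream in family_runs:
            series = ttc_gs_series(stream, sc.priors, traj.flight_time)
            pre = series.times < traj.flight_time
            assert np.nanmax(np.abs(series.error[pre])) < 0.010

    def test_exact_prediction_has_slope_minus_one(self, family_runs):
        sc, traj, obs, stream = family_runs[2]
        series = ttc_gs_series(stream, sc.priors, traj.flight_time)
        defined = np.isfinite(series.slope) & (series.times < traj.flight_time)
        np.testing.assert_allclose(series.slope[defined], -1.0, atol=0.01)

    def test_overshoot_overestimates(self):
        # ball landing 5 m beyond a stationary observer
        sc = next(s for s in offset_landing_grid() if s.name == "offset_x+0_z-5")
        traj, _, stream = sc.run()
        series = ttc_gs_series(stream, sc.priors, traj.flight_time)
        # before the ball passes overhead (~1.8 s), after which the
        # elevation geometry degenerates
        late = (series.times > 1.0) & (series.times < 1.7)
        assert np.nanmin(series.error[late]) > 0
        assert np.nanmean(series.slope[late]) > -1

    def test_undershoot_underestimates(self):
        sc = next(s for s in offset_landing_grid() if s.name == "offset_x+0_z+5")
        traj, _, stream = sc.run()
        series = ttc_gs_series(stream, sc.priors, traj.flight_time)
        late = series.times > 1.5
        assert np.nanmax(series.error[late]) < 0
        assert np.nanmean(series.slope[late]) < -1


class TestNavigationSignal:
    def test_hold_at_interception_point(self, family_runs):
        sc, traj, obs, stream = family_runs[0]
        series = ttc_gs_series(stream, sc.priors, traj.flight_time)
        signal = navigation_signal(series)
        defined = np.isfinite(series.slope) & (series.times < traj.flight_time - 0.05)
        assert set(signal[defined]) == {HOLD}

    def test_overshoot_signals_move_backward(self):
        sc = next(s for s in offset_landing_grid() if s.name == "offset_x+0_z-5")
        traj, _, stream = sc.run()
        series = ttc_gs_series(stream, sc.priors, traj.flight_time)
        signal = navigation_signal(series)
        late = (series.times > 1.0) & (series.times < 1.7)
        assert (signal[late] == MOVE_BACKWARD).mean() > 0.9

    def test_moving_observer_relinearizes(self):
        sc = next(
            s for s in offset_landing_grid(moving=True) if s.name == "offset_x+0_z-5_moving"
        )
        traj, _, stream = sc.run()
        series = ttc_gs_series(stream, sc.priors, traj.flight_time)
        # once the observer runs toward the landing point, the slope comes
        # back to the -1 band and the signal returns to hold
        window = (series.times > 1.2) & (series.times < traj.flight_time - 0.05)
        assert np.nanmax(np.abs(series.slope[window] + 1.0)) < 0.2
        signal = navigation_signal(series, tol=0.2)
        assert set(signal[window]) == {HOLD}


class TestCueFusion:
    def test_equal_cues(self):
        est, wf = combine_mle(2.0, 0.1, 2.0, 0.1)
        assert est == pytest.approx(2.0)
        assert wf == pytest.approx(0.1 / np.sqrt(2))

    def test_very_noisy_cue_is_ignored(self):
        est, wf = combine_mle(2.0, 0.1, 3.0, 1e6)
        assert est == pytest.approx(2.0, rel=1e-6)
        assert wf == pytest.approx(0.1, rel=1e-6)

    def test_undefined_cue_falls_back(self):
        est, wf = combine_mle(np.nan, 0.1, 1.5, 0.2)
        assert est == pytest.approx(1.5)
        assert wf == pytest.approx(0.2)

    def test_both_undefined_raises(self):
        with pytest.raises(ValueError):
            combine_mle(np.nan, 0.1, np.nan, 0.2)

    @settings(deadline=None, derandomize=True)
    @given(
        ttc_a=st.floats(0.1, 10.0),
        ratio=st.floats(0.8, 1.25),
        wf_a=st.floats(0.01, 1.0),
        wf_b=st.floats(0.01, 1.0),
    )
    def test_combined_wf_never_exceeds_best_cue(self, ttc_a, ratio, wf_a, wf_b):
        # both cues estimate the same TTC, so their values roughly agree
        _, wf = combine_mle(ttc_a, wf_a, ttc_a * ratio, wf_b)
        assert wf <= min(wf_a, wf_b) * (1 + 1e-9)
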