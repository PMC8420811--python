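import numpy as np
import pytest

from gsttc.optics import expansion_discriminable, project, tau
from gsttc.trajectory import (
    BASEBALL,
    EARTH,
    SOCCER,
    LaunchState,
    Trajectory,
    make_head_on,
    observer_path,
    simulate_vacuum,
    stationary_observer,
)


def head_on_stream(z=30.0, dt=0.01, ball=BASEBALL):
    traj = simulate_vacuum(make_head_on(z, 2.0, EARTH), EARTH, dt=dt)
    return traj, project(traj, ball=ball)


def small_ball():
    from gsttc.trajectory import BallSpec

    return BallSpec(radius=0.005)


def constant_velocity_trajectory(d0=10.0, v=5.0, dt=0.001):
    """Straight head-on approach at constant speed (synthetic, no gravity)."""
    t = np.arange(0.0, d0 / v, dt)
    pos = np.zeros((t.size, 3))
    pos[:, 2] = d0 - v * t
    vel = np.zeros((t.size, 3))
    vel[:, 2] = -v
    return Trajectory(times=t, positions=pos, velocities=vel, flight_time=d0 / v, dt=dt)


class TestProjection:
    def test_launch_geometry(self):
        _, stream = head_on_stream()
        assert stream.gamma[0] == pytest.approx(0.0, abs=1e-12)
        assert stream.distance[0] == pytest.approx(30.0)
        assert stream.theta[0] == pytest.approx(2 * np.arctan(0.037 / 30.0), rel=1e-12)
        assert stream.theta[0] == pytest.approx(0.0024666, rel=1e-3)

    def test_launch_elevation_rate(self):
        # at gamma = 0 the elevation rate is vertical speed over distance
        _, stream = head_on_stream()
        assert stream.gamma_dot[0] == pytest.approx(9.807 / 30.0, rel=1e-12)
        assert stream.gamma_dot[0] == pytest.approx(0.32690, rel=1e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_analytic_derivatives_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.uniform(5, 50)
        x_end = rng.uniform(-5, 5)
        z_end = rng.uniform(-5, 5)
        launch = LaunchState(
            (0, 0, z), (x_end / 2.0, 9.807, (z_end - z) / 2.0)
        )
        traj = simulate_vacuum(launch, EARTH, dt=0.001)
        stream = project(traj, ball=BASEBALL)
        dt = 0.001
        # 4th-order central stencil keeps the oracle's truncation error well
        # under the comparison tolerance; skip the stencil margins and the
        # final approach where the landing sample may be undefined
        ok = np.zeros(traj.times.size, dtype=bool)
        ok[2:-3] = True
        ok &= stream.distance > 0.5
        for series, deriv in ((stream.gamma, stream.gamma_dot), (stream.theta, stream.theta_dot)):
            fd = np.full_like(series, np.nan)
            fd[2:-2] = (-series[4:] + 8 * series[3:-1] - 8 * series[1:-3] + series[:-4]) / (
                12 * dt
            )
            np.testing.assert_allclose(deriv[ok], fd[ok], atol=1e-6)

    def test_elevation_monotone_for_head_on(self):
        _, stream = head_on_stream()
        pre = np.isfinite(stream.gamma)
        assert np.all(np.diff(stream.gamma[pre]) > 0)

    def test_theta_decreases_with_distance(self):
        d = np.linspace(1.0, 50.0, 200)
        theta = 2 * np.arctan(BASEBALL.radius / d)
        assert np.all(np.diff(theta) < 0)

    def test_size_over_theta_distance_bound(self):
        # s / theta approximates D with relative error <= (r/D)^2 / 3
        _, stream = head_on_stream()
        ok = np.isfinite(stream.distance) & (stream.distance > 1.0)
        d_hat = BASEBALL.size / stream.theta[ok]
        rel = np.abs(d_hat - stream.distance[ok]) / stream.distance[ok]
        bound = (BASEBALL.radius / stream.distance[ok]) ** 2 / 3.0
        assert np.all(rel <= bound * 1.01)

    def test_translation_equivariance(self):
        traj = simulate_vacuum(make_head_on(50.0, 2.0, EARTH), EARTH)
        obs = observer_path((0, 0, 10.0), (0, 0, 0.0), traj.flight_time, 0.5, times=traj.times)
        moving = project(traj, obs, BASEBALL)
        relative = Trajectory(
            times=traj.times,
            positions=traj.positions - obs.positions,
            velocities=traj.velocities - obs.velocities,
            flight_time=traj.flight_time,
            dt=traj.dt,
        )
        still = project(relative, stationary_observer(traj.times), BASEBALL)
        np.testing.assert_allclose(moving.theta, still.theta, rtol=1e-12)
        np.testing.assert_allclose(moving.gamma_dot, still.gamma_dot, rtol=1e-12)

    def test_head_on_landing_sample_is_nan(self):
        _, stream = head_on_stream()
        assert np.isnan(stream.theta[-1]) and np.isfinite(stream.theta[:-1]).all()

    def test_interior_eye_contact_rejected(self):
        t = np.array([0.0, 0.1, 0.2])
        pos = np.array([[0, 0, 1.0], [0, 0, 0.0], [0, 0, -1.0]])
        vel = np.full((3, 3), [0.0, 0.0, -10.0])
        traj = Trajectory(times=t, positions=pos, velocities=vel, flight_time=0.2, dt=0.1)
        with pytest.raises(ValueError):
            project(traj, ball=BASEBALL)


class TestTau:
    def test_constant_velocity_approach(self):
        traj = constant_velocity_trajectory(d0=10.0, v=5.0)
        stream = project(traj, ball=small_ball())
        t = tau(stream)
        # first-order correlate of true remaining time D / V
        true_remaining = stream.distance / 5.0
        ok = stream.distance > 0.5
        np.testing.assert_allclose(t[ok], true_remaining[ok], rtol=1e-3)
        assert t[0] == pytest.approx(2.0, rel=1e-3)

    def test_receding_phase_undefined(self):
        # steep launch close by: the ball initially moves away from the eye
        traj = simulate_vacuum(make_head_on(2.0, 2.857, EARTH), EARTH)
        stream = project(traj, ball=BASEBALL)
        t = tau(stream)
        early = (stream.times > 0.1) & (stream.times < 0.5)
        assert np.isnan(t[early]).all()
        assert np.isfinite(t[np.nan_to_num(stream.theta_dot) > 0]).all()

    def test_zero_expansion_undefined(self):
        traj = constant_velocity_trajectory()
        stream = project(traj, ball=small_ball())
        stream.theta_dot[:] = 0.0
        assert np.isnan(tau(stream)).all()


class TestExpansionDiscriminability:
    def test_baseball_mostly_below_threshold(self, family_runs):
        for sc, traj, obs, stream in family_runs:
            _, frac = expansion_discriminable(stream, 0.004)
            assert frac > 0.5

    def test_soccer_fraction_smaller(self):
        from gsttc.scenarios import collision_course_family

        for sc_b, sc_s in zip(
            collision_course_family(ball=BASEBALL), collision_course_family(ball=SOCCER)
        ):
            _, _, st_b = sc_b.run()
            _, _, st_s = sc_s.run()
            _, frac_b = expansion_discriminable(st_b)
            _, frac_s = expansion_discriminable(st_s)
            assert frac_s < frac_b

    def test_zero_threshold_counts_receding(self):
        _, stream = head_on_stream()
        _, frac = expansion_discriminable(stream, threshold=0.0)
        finite = np.isfinite(stream.theta_dot)
        assert frac == pytest.approx((stream.theta_dot[finite] < 0).mean())
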