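"""Canonical simulation scenarios.

Three scenario families cover the situations the TTC estimator is meant to
handle:

* ``collision_course_family`` — head-on 2 s flights of a baseball from
  five launch distances, landing exactly at the (stationary) observer;
  the accuracy and noise-precision benchmarks run on these.
* ``offset_landing_grid`` — 2 s flights from 50 m landing on a 3x3 grid
  of points around the observer (origin excluded, 8 endpoints), with the
  observer either stationary or running to the interception point from
  0.5 s after launch; probes the rate-of-change navigation signal.
* ``drag_worst_case`` — a soccer ball at high approach speed under
  quadratic air drag (the trajectory most distorted relative to the
  gravity-only parabola), with the observer at the drag interception
  point, stationary at the midpoint between the vacuum and drag landing
  points, or running from that midpoint to the interception point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gs_model import PriorSpec, TTCSeries, ttc_gs_series
from .optics import OpticalStream, project
from .trajectory import (
    BASEBALL,
    EARTH,
    SOCCER,
    BallSpec,
    EnvSpec,
    LaunchState,
    ObserverPath,
    Trajectory,
    make_head_on,
    observer_path,
    simulate_drag,
    simulate_vacuum,
    stationary_observer,
)

__all__ = [
    "Scenario",
    "collision_course_family",
    "offset_landing_grid",
    "drag_worst_case",
]

#: Start delay (s) of a running observer: typical time before catchers
#: start moving in the right direction.
START_DELAY = 0.5


@dataclass
class Scenario:
    """A fully specified runnable simulation.

    ``observer_start`` and ``observer_target`` define the eye path: equal
    (or no target) means a stationary observer; otherwise the observer
    runs from start to target beginning at ``start_delay``, timed to
    arrive at landing.
    """

    name: str
    ball: BallSpec
    env: EnvSpec
    launch: LaunchState
    observer_start: np.ndarray = field(default_factory=lambda: np.zeros(3))
    observer_target: np.ndarray | None = None
    start_delay: float = START_DELAY
    priors: PriorSpec = field(default_factory=PriorSpec)
    dt: float = 0.01

    def simulate(self) -> Trajectory:
        if self.env.drag_enabled:
            return simulate_drag(self.launch, self.ball, self.env, self.dt)
        return simulate_vacuum(self.launch, self.env, self.dt)

    def observer(self, traj: Trajectory) -> ObserverPath:
        start = np.asarray(self.observer_start, dtype=float)
        if self.observer_target is None or np.allclose(self.observer_target, start):
            return stationary_observer(traj.times, start)
        return observer_path(
            start,
            np.asarray(self.observer_target, dtype=float),
            traj.flight_time,
            self.start_delay,
            self.dt,
            times=traj.times,
        )

    def run(self) -> tuple[Trajectory, ObserverPath, OpticalStream]:
        traj = self.simulate()
        obs = self.observer(traj)
        return traj, obs, project(traj, obs, self.ball)

    def ttc_series(self) -> TTCSeries:
        traj, _, stream = self.run()
        return ttc_gs_series(stream, self.priors, traj.flight_time)


def collision_course_family(
    distances: tuple[float, ...] = (15.0, 20.0, 30.0, 40.0, 50.0),
    flight_time: float = 2.0,
    ball: BallSpec = BASEBALL,
    env: EnvSpec = EARTH,
    dt: float = 0.01,
) -> list[Scenario]:
    """Head-on collision courses landing at the stationary observer."""
    priors = PriorSpec(gravity=env.g, size=ball.size)
    return [
        Scenario(
            name=f"collision_z{int(z)}",
            ball=ball,
            env=env,
            launch=make_head_on(z, flight_time, env),
            priors=priors,
            dt=dt,
        )
        for z in distances
    ]


def offset_landing_grid(
    moving: bool = False,
    z_init: float = 50.0,
    flight_time: float = 2.0,
    offsets: tuple[float, ...] = (-5.0, 0.0, 5.0),
    ball: BallSpec = BASEBALL,
    env: EnvSpec = EARTH,
    dt: float = 0.01,
) -> list[Scenario]:
    """Trajectories landing around (not at) the observer.

    Landing points form the 3x3 grid ``offsets`` x ``offsets`` in lateral
    (x) and depth (z) around the origin, excluding the origin itself
    (8 endpoints).  Negative z_end means the ball overflies the observer
    and lands beyond.  With ``moving`` the observer runs to the landing
    point starting 0.5 s after launch.
    """
    priors = PriorSpec(gravity=env.g, size=ball.size)
    scenarios = []
    for x_end in offsets:
        for z_end in offsets:
            if x_end == 0 and z_end == 0:
                continue
            velocity = (
                x_end / flight_time,
                env.g * flight_time / 2.0,
                (z_end - z_init) / flight_time,
            )
            scenarios.append(
                Scenario(
                    name=f"offset_x{x_end:+.0f}_z{z_end:+.0f}" + ("_moving" if moving else ""),
                    ball=ball,
                    env=env,
                    launch=LaunchState(position=(0.0, 0.0, z_init), velocity=velocity),
                    observer_target=np.array([x_end, 0.0, z_end]) if moving else None,
                    priors=priors,
                    dt=dt,
                )
            )
    return scenarios


def drag_worst_case(
    case: str,
    ball: BallSpec = SOCCER,
    v_y0: float = 9.807,
    v_z0: float = 25.0,
    env: EnvSpec | None = None,
    dt: float = 0.01,
) -> Scenario:
    """Soccer ball at high approach speed under air drag.

    ``case`` is one of:

    * ``"at_interception"`` — observer stationary at the drag landing point;
    * ``"midpoint_stationary"`` — observer stationary midway between the
      gravity-only and drag landing points;
    * ``"midpoint_moving"`` — observer starts at that midpoint and runs to
      the drag landing point from 0.5 s after launch.

    The launch depth is chosen so the drag trajectory lands at the origin;
    the gravity-only trajectory then lands beyond it (drag shortens the
    flight), so the midpoint lies behind the interception point.
    """
    if env is None:
        env = EnvSpec(drag_enabled=True)
    if not env.drag_enabled:
        raise ValueError("drag_worst_case requires a drag-enabled environment")

    # First pass from the origin to measure the drag and vacuum ranges.
    probe_launch = LaunchState(position=(0.0, 0.0, 0.0), velocity=(0.0, v_y0, v_z0))
    drag_traj = simulate_drag(probe_launch, ball, env, dt)
    range_drag = float(drag_traj.positions[-1, 2])
    vac = simulate_vacuum(probe_launch, EnvSpec(g=env.g), dt)
    range_vac = float(vac.positions[-1, 2])

    launch = LaunchState(position=(0.0, 0.0, range_drag), velocity=(0.0, v_y0, -v_z0))
    midpoint = np.array([0.0, 0.0, (range_drag - range_vac) / 2.0])
    priors = PriorSpec(gravity=env.g, size=ball.size)

    if case == "at_interception":
        start, target = np.zeros(3), None
    elif case == "midpoint_stationary":
        start, target = midpoint, None
    elif case == "midpoint_moving":
        start, target = midpoint, np.zeros(3)
    else:
        raise ValueError(f"unknown case: {case!r}")
    return Scenario(
        name=f"drag_{case}",
        ball=ball,
        env=env,
        launch=launch,
        observer_start=start,
        observer_target=target,
        priors=priors,
        dt=dt,
    )
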