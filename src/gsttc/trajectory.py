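"""Projectile dynamics and observer motion.

Coordinate frame
----------------
The observer's eye sits at the origin; x is lateral, y is vertical (up),
z is depth, positive toward the launch point.  Balls are launched at eye
level (y = 0) and the flight ends when the ball returns to eye level.

Two dynamical regimes are supported: ideal gravity-only flight (sampled
from the closed-form parabola) and flight with quadratic aerodynamic
drag, integrated with a fixed-step fourth-order Runge-Kutta scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BallSpec",
    "EnvSpec",
    "LaunchState",
    "Trajectory",
    "ObserverPath",
    "BASEBALL",
    "SOCCER",
    "EARTH",
    "make_head_on",
    "simulate_vacuum",
    "simulate_drag",
    "observer_path",
    "stationary_observer",
]

#: Standard terrestrial gravitational acceleration (m/s^2).
G_EARTH = 9.807

#: Air density at sea level (kg/m^3).
RHO_SEA_LEVEL = 1.225


@dataclass(frozen=True)
class BallSpec:
    """Physical ball: radius (m), drag coefficient, mass (kg)."""

    radius: float
    drag_coefficient: float = 0.0
    mass: float = 0.145

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.drag_coefficient < 0:
            raise ValueError("drag coefficient must be non-negative")

    @property
    def size(self) -> float:
        """Physical diameter s = 2 r (m), the quantity the size prior refers to."""
        return 2.0 * self.radius

    @property
    def cross_section(self) -> float:
        """Frontal area A = pi r^2 (m^2) entering the drag force."""
        return math.pi * self.radius**2


#: Regulation baseball: radius 0.037 m, C_d 0.346, mass 0.145 kg.
BASEBALL = BallSpec(radius=0.037, drag_coefficient=0.346, mass=0.145)

#: Regulation soccer ball: radius 0.11 m, C_d 0.4, mass 0.43 kg.
SOCCER = BallSpec(radius=0.11, drag_coefficient=0.4, mass=0.43)


@dataclass(frozen=True)
class EnvSpec:
    """Environment: gravity g (m/s^2, downward) and air density rho (kg/m^3)."""

    g: float = G_EARTH
    air_density: float = RHO_SEA_LEVEL
    drag_enabled: bool = False

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("g must be positive")
        if self.air_density < 0:
            raise ValueError("air density must be non-negative")


#: Earth gravity, sea-level air, drag off (vacuum kinematics).
EARTH = EnvSpec()


@dataclass(frozen=True)
class LaunchState:
    """Initial ball state: position and velocity, both 3-vectors (m, m/s)."""

    position: np.ndarray
    velocity: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "velocity", np.asarray(self.velocity, dtype=float))
        if self.position.shape != (3,) or self.velocity.shape != (3,):
            raise ValueError("position and velocity must be 3-vectors")
        if not (np.isfinite(self.position).all() and np.isfinite(self.velocity).all()):
            raise ValueError("launch state must be finite")


@dataclass
class Trajectory:
    """Time-sampled ball state on a uniform dt grid ending at the landing event.

    The final sample is the eye-level crossing (y returns to launch height
    from above) at t = ``flight_time``; interior samples lie on the dt grid.
    """

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    flight_time: float
    dt: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        n = self.times.size
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError("positions/velocities must match the time grid")
        if n < 2 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing with >= 2 samples")

    @property
    def landing_point(self) -> np.ndarray:
        return self.positions[-1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with columns t, x, y, z, vx, vy, vz."""
        return pd.DataFrame(
            {
                "t": self.times,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "vx": self.velocities[:, 0],
                "vy": self.velocities[:, 1],
                "vz": self.velocities[:, 2],
            }
        )


@dataclass
class ObserverPath:
    """Eye position over time, on the same grid as the paired trajectory.

    The observer is stationary until ``start_delay`` and then moves in a
    straight line at constant ``speed``.
    """

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    start_delay: float = 0.0
    speed: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        n = self.times.size
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError("positions/velocities must match the time grid")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "vx": self.velocities[:, 0],
                "vy": self.velocities[:, 1],
                "vz": self.velocities[:, 2],
            }
        )


def _time_grid(flight_time: float, dt: float) -> np.ndarray:
    """Uniform grid [0, dt, 2 dt, ...] closed with the exact landing time."""
    grid = np.arange(0.0, flight_time, dt)
    if flight_time - grid[-1] < 1e-12 * max(1.0, flight_time):
        grid = grid[:-1]
    return np.append(grid, flight_time)


def make_head_on(z_init: float, flight_time: float, env: EnvSpec = EARTH) -> LaunchState:
    """Launch state for a collision course ending at the observer.

    The ball starts at eye level a depth ``z_init`` away and, under
    gravity-only dynamics, lands exactly at the eye after ``flight_time``:
    vertical speed V_y0 = g T / 2, horizontal speed z_init / T directed at
    the origin.
    """
    if z_init <= 0:
        raise ValueError("z_init must be positive")
    if flight_time <= 0:
        raise ValueError("flight_time must be positive")
    v_y0 = env.g * flight_time / 2.0
    v_z = -z_init / flight_time
    return LaunchState(position=(0.0, 0.0, z_init), velocity=(0.0, v_y0, v_z))


def simulate_vacuum(launch: LaunchState, env: EnvSpec = EARTH, dt: float = 0.01) -> Trajectory:
    """Sample the exact gravity-only parabola on a dt grid.

    The flight time solves y(T) = y(0) with y decreasing, i.e. T = 2 V_y0 / g.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v_y0 = launch.velocity[1]
    if v_y0 <= 0:
        raise ValueError("vacuum launch needs positive initial vertical speed")
    flight_time = 2.0 * v_y0 / env.g
    t = _time_grid(flight_time, dt)
    pos = launch.position[None, :] + launch.velocity[None, :] * t[:, None]
    pos[:, 1] -= 0.5 * env.g * t**2
    vel = np.broadcast_to(launch.velocity, (t.size, 3)).copy()
    vel[:, 1] = v_y0 - env.g * t
    return Trajectory(times=t, positions=pos, velocities=vel, flight_time=flight_time, dt=dt)


def _drag_acceleration(vel: np.ndarray, ball: BallSpec, env: EnvSpec) -> np.ndarray:
    k = env.air_density * ball.drag_coefficient * ball.cross_section / (2.0 * ball.mass)
    speed = np.linalg.norm(vel)
    acc = -k * speed * vel
    acc[1] -= env.g
    return acc


def simulate_drag(
    launch: LaunchState,
    ball: BallSpec,
    env: EnvSpec = EARTH,
    dt: float = 0.01,
    max_time: float = 60.0,
) -> Trajectory:
    """Integrate flight under gravity + quadratic drag (fixed-step RK4).

    The drag force is F = -(rho C_d A / 2) |v| v, so
    dv/dt = -g yhat - (rho C_d A / (2 m)) |v| v.  Integration stops at the
    eye-level crossing (y falls below launch height while descending); the
    crossing time is located by bisection on a Runge-Kutta substep from
    the last sample above eye level, and the crossing state is appended as
    the final sample.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    y0 = launch.position[1]
    pos = [launch.position.copy()]
    vel = [launch.velocity.copy()]
    t_list = [0.0]

    def deriv(state: np.ndarray) -> np.ndarray:
        p, v = state[:3], state[3:]
        return np.concatenate([v, _drag_acceleration(v, ball, env)])

    def rk4_step(s: np.ndarray, h: float) -> np.ndarray:
        k1 = deriv(s)
        k2 = deriv(s + 0.5 * h * k1)
        k3 = deriv(s + 0.5 * h * k2)
        k4 = deriv(s + h * k3)
        return s + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    state = np.concatenate([launch.position, launch.velocity])
    t = 0.0
    n_max = int(math.ceil(max_time / dt))
    for _ in range(n_max):
        new_state = rk4_step(state, dt)
        if not np.isfinite(new_state).all():
            raise FloatingPointError("non-finite state during drag integration")
        t += dt
        if new_state[1] < y0 and new_state[4] < 0 and state[1] >= y0 and t > dt:
            # locate the eye-level crossing inside this step by bisection on
            # the substep length (a single RK4 substep is far more accurate
            # than the crossing tolerance)
            lo, hi = 0.0, dt
            for _ in range(50):
                mid = 0.5 * (lo + hi)
                if rk4_step(state, mid)[1] >= y0:
                    lo = mid
                else:
                    hi = mid
            h_land = 0.5 * (lo + hi)
            landing = rk4_step(state, h_land)
            t_land = (t - dt) + h_land
            pos.append(landing[:3])
            vel.append(landing[3:])
            t_list.append(t_land)
            return Trajectory(
                times=np.array(t_list),
                positions=np.array(pos),
                velocities=np.array(vel),
                flight_time=t_land,
                dt=dt,
            )
        state = new_state
        pos.append(state[:3].copy())
        vel.append(state[3:].copy())
        t_list.append(t)
    raise RuntimeError("ball did not return to launch height within max_time")


def observer_path(
    start: np.ndarray,
    interception_point: np.ndarray,
    flight_time: float,
    start_delay: float,
    dt: float = 0.01,
    times: np.ndarray | None = None,
) -> ObserverPath:
    """Straight-line run reaching the interception point exactly at landing.

    The eye stays at ``start`` until ``start_delay``, then moves at the
    constant speed |interception - start| / (flight_time - start_delay).
    Pass ``times`` (e.g. ``traj.times``) to share the trajectory grid.
    """
    if start_delay >= flight_time:
        raise ValueError("start_delay must be smaller than flight_time")
    start = np.asarray(start, dtype=float)
    end = np.asarray(interception_point, dtype=float)
    if times is None:
        times = _time_grid(flight_time, dt)
    times = np.asarray(times, dtype=float)
    disp = end - start
    dist = float(np.linalg.norm(disp))
    duration = flight_time - start_delay
    speed = dist / duration
    direction = disp / dist if dist > 0 else np.zeros(3)

    moving = times >= start_delay
    travel = np.clip(times - start_delay, 0.0, duration)
    positions = start[None, :] + direction[None, :] * (speed * travel)[:, None]
    velocities = np.where(moving[:, None], direction[None, :] * speed, 0.0)
    return ObserverPath(
        times=times,
        positions=positions,
        velocities=velocities,
        start_delay=start_delay,
        speed=speed,
    )


def stationary_observer(times: np.ndarray, position: np.ndarray = (0.0, 0.0, 0.0)) -> ObserverPath:
    """Observer fixed at ``position`` for the whole flight."""
    times = np.asarray(times, dtype=float)
    position = np.asarray(position, dtype=float)
    return ObserverPath(
        times=times,
        positions=np.broadcast_to(position, (times.size, 3)).copy(),
        velocities=np.zeros((times.size, 3)),
        start_delay=0.0,
        speed=0.0,
    )
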