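"""Egocentric optical projection of ball trajectories.

Maps the 3D relative geometry between ball and (possibly moving) eye into
the angular variables an observer can actually measure: retinal size
(theta), elevation angle (gamma), their time derivatives, eye-ball
distance and radial approach speed.  Derivatives are computed analytically
from the relative velocity, so their accuracy does not depend on the
sampling step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import BallSpec, ObserverPath, Trajectory, stationary_observer

__all__ = ["OpticalStream", "project", "tau", "expansion_discriminable"]


@dataclass
class OpticalStream:
    """Egocentric optical variables on the trajectory time grid.

    Attributes
    ----------
    distance : eye-to-ball distance D (m).
    theta : retinal size, the angular subtense 2 arctan(r / D) (rad).
    gamma : elevation angle above the eye-level plane (rad).
    gamma_dot, theta_dot : analytic time derivatives (rad/s).  A negative
        theta_dot means the image is contracting (ball receding).
    radial_speed : V_r = -dD/dt (m/s), positive while approaching.
    """

    times: np.ndarray
    distance: np.ndarray
    theta: np.ndarray
    gamma: np.ndarray
    gamma_dot: np.ndarray
    theta_dot: np.ndarray
    radial_speed: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "D": self.distance,
                "theta": self.theta,
                "gamma": self.gamma,
                "gamma_dot": self.gamma_dot,
                "theta_dot": self.theta_dot,
                "Vr": self.radial_speed,
            }
        )


def project(
    traj: Trajectory,
    observer: ObserverPath | None = None,
    ball: BallSpec | None = None,
) -> OpticalStream:
    """Project a trajectory into the optical variables seen by an observer.

    ``observer`` defaults to an eye fixed at the origin.  A landing sample
    that coincides exactly with the eye (D = 0, a perfect head-on catch)
    is emitted as NaN; a zero distance anywhere else is an error.
    """
    if ball is None:
        raise ValueError("a BallSpec is required to compute retinal size")
    if observer is None:
        observer = stationary_observer(traj.times)
    if observer.times.size != traj.times.size or not np.allclose(observer.times, traj.times):
        raise ValueError("observer and trajectory must share the time grid")

    rel_p = traj.positions - observer.positions
    rel_v = traj.velocities - observer.velocities
    dist = np.linalg.norm(rel_p, axis=1)

    zero = dist == 0.0
    if zero[:-1].any():
        raise ValueError("ball coincides with the eye before landing")
    safe_d = np.where(zero, np.nan, dist)

    px, py, pz = rel_p[:, 0], rel_p[:, 1], rel_p[:, 2]
    vx, vy, vz = rel_v[:, 0], rel_v[:, 1], rel_v[:, 2]

    d_dot = (px * vx + py * vy + pz * vz) / safe_d
    theta = 2.0 * np.arctan(ball.radius / safe_d)
    theta_dot = -2.0 * ball.radius * d_dot / (safe_d**2 + ball.radius**2)

    h = np.hypot(px, pz)  # horizontal range in the eye plane
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.arctan2(py, h)
        h_dot = np.where(h > 0, (px * vx + pz * vz) / np.where(h > 0, h, 1.0), 0.0)
        gamma_dot = (vy * h - py * h_dot) / (h**2 + py**2)
    gamma = np.where(zero, np.nan, gamma)
    gamma_dot = np.where(zero, np.nan, gamma_dot)

    return OpticalStream(
        times=traj.times.copy(),
        distance=safe_d,
        theta=theta,
        gamma=gamma,
        gamma_dot=gamma_dot,
        theta_dot=theta_dot,
        radial_speed=-d_dot,
    )


def tau(stream: OpticalStream) -> np.ndarray:
    """First-order TTC correlate tau = theta / theta_dot (s).

    Valid only while the image expands; samples with theta_dot <= 0
    (receding phase, where the ratio is meaningless or infinite) are
    returned as NaN.
    """
    out = np.full(stream.times.shape, np.nan)
    expanding = stream.theta_dot > 0
    out[expanding] = stream.theta[expanding] / stream.theta_dot[expanding]
    return out


def expansion_discriminable(
    stream: OpticalStream, threshold: float = 0.004
) -> tuple[np.ndarray, float]:
    """Flag samples whose expansion rate falls below a discrimination threshold.

    The comparison uses the rate of change of the radius subtense
    (theta_dot / 2), the image-edge angular speed that psychophysical
    expansion-discrimination thresholds refer to.  Rates under
    ``threshold`` (default 0.004 rad/s) are too slow for an observer to
    discriminate; receding samples (negative rate) count as below
    threshold.  Returns the boolean below-threshold mask and the fraction
    of the flight it covers.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    rate = stream.theta_dot / 2.0
    finite = np.isfinite(rate)
    below = finite & (rate < threshold)
    frac = float(below.sum()) / float(finite.sum())
    return below, frac
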