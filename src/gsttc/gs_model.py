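"""TTC estimation from optics calibrated by gravity and size priors.

The core estimator maps three monocular angular variables — retinal size
theta, elevation angle gamma and its rate gamma_dot — into a prediction of
the remaining time to contact using two pieces of internalized knowledge,
the gravitational acceleration g and the physical ball diameter s:

    TTC = (2 / g) * (s / theta) * gamma_dot / cos(gamma)

The ratio s / theta recovers metric distance from the ambiguous retinal
size; g normalizes the elevation-angle rate into time units.  For a ball
on a gravity-only collision course with the eye the prediction is exact up
to the small-angle approximation s / theta ~ D.

The module also provides the rate-of-change navigation signal (deviations
of the predicted-TTC slope from -1 indicate whether the landing point lies
beyond or short of the observer) and inverse-variance maximum-likelihood
fusion of two TTC cues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .optics import OpticalStream

__all__ = [
    "PriorSpec",
    "TTCSeries",
    "distance_from_size",
    "approach_speed_from_size",
    "ttc_gs",
    "ttc_gs_series",
    "navigation_signal",
    "combine_mle",
    "TAU_WEBER_FRACTION",
]

#: Mean Weber fraction of the tau cue (mid-point of the 7-13% psychophysical range).
TAU_WEBER_FRACTION = 0.10


@dataclass(frozen=True)
class PriorSpec:
    """Internalized constants: assumed gravity (m/s^2) and ball diameter (m)."""

    gravity: float = 9.807
    size: float = 0.074

    def __post_init__(self) -> None:
        if self.gravity <= 0 or self.size <= 0:
            raise ValueError("priors must be positive")


def distance_from_size(prior_size: float, theta) -> np.ndarray | float:
    """Distance estimate d = s / theta from known size and retinal size."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta[np.isfinite(theta)] <= 0):
        raise ValueError("theta must be positive")
    out = prior_size / theta
    return float(out) if out.ndim == 0 else out


def approach_speed_from_size(prior_size: float, theta, theta_dot) -> np.ndarray | float:
    """Approach-speed estimate V_z = s * theta_dot / theta^2.

    Negative when the image contracts (ball receding), by the same sign
    convention as ``theta_dot``.
    """
    theta = np.asarray(theta, dtype=float)
    theta_dot = np.asarray(theta_dot, dtype=float)
    if np.any(theta[np.isfinite(theta)] <= 0):
        raise ValueError("theta must be positive")
    out = prior_size * theta_dot / theta**2
    return float(out) if out.ndim == 0 else out


def ttc_gs(theta, gamma, gamma_dot, priors: PriorSpec = PriorSpec()) -> np.ndarray | float:
    """Predicted remaining TTC: (2/g) (s/theta) gamma_dot / cos(gamma)."""
    theta = np.asarray(theta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    gamma_dot = np.asarray(gamma_dot, dtype=float)
    if np.any(theta[np.isfinite(theta)] <= 0):
        raise ValueError("theta must be positive")
    out = (2.0 / priors.gravity) * (priors.size / theta) * gamma_dot / np.cos(gamma)
    return float(out) if out.ndim == 0 else out


@dataclass
class TTCSeries:
    """Predicted vs. true remaining TTC over a flight.

    ``error`` is predicted - true remaining; ``slope`` is the local
    rate of change of the prediction (OLS over a trailing window), which
    equals -1 for an exact predictor.
    """

    times: np.ndarray
    predicted: np.ndarray
    true_remaining: np.ndarray
    error: np.ndarray
    slope: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "predicted": self.predicted,
                "true_remaining": self.true_remaining,
                "error": self.error,
                "slope": self.slope,
            }
        )


def _trailing_slope(times: np.ndarray, values: np.ndarray, window: float) -> np.ndarray:
    """OLS slope of ``values`` over a trailing time window, NaN until full."""
    n = times.size
    dt = float(np.median(np.diff(times)))
    k = max(2, int(round(window / dt)))
    slope = np.full(n, np.nan)
    for i in range(k - 1, n):
        t = times[i - k + 1 : i + 1]
        y = values[i - k + 1 : i + 1]
        ok = np.isfinite(y)
        if ok.sum() < 2:
            continue
        tc = t[ok] - t[ok].mean()
        denom = np.dot(tc, tc)
        if denom > 0:
            slope[i] = np.dot(tc, y[ok] - y[ok].mean()) / denom
    return slope


def ttc_gs_series(
    stream: OpticalStream,
    priors: PriorSpec = PriorSpec(),
    flight_time: float | None = None,
    slope_window: float = 0.2,
) -> TTCSeries:
    """Apply the estimator to every sample of an optical stream.

    ``flight_time`` defaults to the last sample time (the landing event).
    """
    if stream.times.size == 0:
        raise ValueError("empty optical stream")
    if flight_time is None:
        flight_time = float(stream.times[-1])
    predicted = np.asarray(
        ttc_gs(stream.theta, stream.gamma, stream.gamma_dot, priors), dtype=float
    )
    true_remaining = flight_time - stream.times
    error = predicted - true_remaining
    slope = _trailing_slope(stream.times, predicted, slope_window)
    return TTCSeries(
        times=stream.times.copy(),
        predicted=predicted,
        true_remaining=true_remaining,
        error=error,
        slope=slope,
    )


#: Navigation actions emitted per sample.
MOVE_FORWARD = "move_forward"  # toward the launch point: ball lands short
MOVE_BACKWARD = "move_backward"  # away from the launch point: ball lands beyond
HOLD = "hold"


def navigation_signal(
    series: TTCSeries, window: float | None = None, tol: float = 0.05
) -> np.ndarray:
    """Classify each sample by the deviation of the TTC slope from -1.

    A slope above -1 + tol means the prediction decays too slowly: the
    ball will land beyond the observer, who should move away from the
    launch point (``move_backward``).  A slope below -1 - tol signals a
    landing short of the observer (``move_forward``).  Within the band, or
    where the slope is undefined (window not yet full), the signal is
    ``hold``.
    """
    slope = series.slope
    if window is not None:
        slope = _trailing_slope(series.times, series.predicted, window)
    out = np.full(series.times.shape, HOLD, dtype=object)
    defined = np.isfinite(slope)
    out[defined & (slope > -1.0 + tol)] = MOVE_BACKWARD
    out[defined & (slope < -1.0 - tol)] = MOVE_FORWARD
    return out


def combine_mle(ttc_a, wf_a: float, ttc_b, wf_b: float) -> tuple:
    """Fuse two TTC cues by inverse-variance (maximum-likelihood) weighting.

    Each cue's standard deviation is its Weber fraction times its estimate,
    sigma_i = wf_i * ttc_i.  NaN estimates (an undefined cue, e.g. tau
    while the ball recedes) fall back to the other cue.  Returns the fused
    estimate and its effective Weber fraction; the latter never exceeds
    the smaller input Weber fraction.
    """
    ttc_a = np.asarray(ttc_a, dtype=float)
    ttc_b = np.asarray(ttc_b, dtype=float)
    if wf_a <= 0 and wf_b <= 0:
        raise ValueError("at least one cue must have a positive Weber fraction")

    var_a = (wf_a * ttc_a) ** 2
    var_b = (wf_b * ttc_b) ** 2
    a_ok = np.isfinite(ttc_a) & (var_a > 0)
    b_ok = np.isfinite(ttc_b) & (var_b > 0)
    if not np.any(a_ok | b_ok):
        raise ValueError("both cues undefined")

    with np.errstate(divide="ignore", invalid="ignore"):
        w_a = np.where(a_ok, 1.0 / np.where(a_ok, var_a, 1.0), 0.0)
        w_b = np.where(b_ok, 1.0 / np.where(b_ok, var_b, 1.0), 0.0)
        w_sum = w_a + w_b
        fused = (w_a * np.where(a_ok, ttc_a, 0.0) + w_b * np.where(b_ok, ttc_b, 0.0)) / w_sum
        sigma = np.sqrt(1.0 / w_sum)
        wf = np.where(fused != 0, sigma / np.abs(fused), np.nan)
    fused = np.where(w_sum > 0, fused, np.nan)
    if fused.ndim == 0:
        return float(fused), float(wf)
    return fused, wf
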