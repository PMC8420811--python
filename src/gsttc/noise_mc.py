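"""Weber-fraction noise injection and Monte-Carlo precision analysis.

Sensory noise on each optical variable x in {theta, gamma, gamma_dot} is
modelled as additive Gaussian noise scaled by the variable's own magnitude
(a Weber fraction k): x_noisy = x + N(0, |x| k), drawn independently
across time samples, variables and simulations.  The precision of the TTC
estimator is then summarized timewise as WF(t) = SD / mean of the
predicted TTC across simulations — the same Weber-fraction currency used
for the inputs, so input noise and output precision are directly
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gs_model import TAU_WEBER_FRACTION, PriorSpec, ttc_gs
from .optics import OpticalStream

__all__ = ["WeberConfig", "noisify", "wf_timewise", "wf_combined"]


@dataclass(frozen=True)
class WeberConfig:
    """Weber fractions of the noisy inputs and Monte-Carlo settings."""

    k_theta: float = 0.05
    k_gamma: float = 0.05
    k_gamma_dot: float = 0.05
    k_tau: float = TAU_WEBER_FRACTION
    n_sims: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.k_theta, self.k_gamma, self.k_gamma_dot, self.k_tau) < 0:
            raise ValueError("Weber fractions must be non-negative")
        if self.n_sims < 1:
            raise ValueError("n_sims must be at least 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _noisify_array(
    x: np.ndarray, k: float, rng: np.random.Generator, n: int, positive: bool = False
) -> np.ndarray:
    """n independent noisy copies of x, shape (n, len(x)).

    With ``positive`` set, non-positive draws are redrawn (used for theta,
    which is physically positive; at 5% noise a violation has essentially
    zero probability, so this guard does not bias the distribution
    measurably).
    """
    if k == 0:
        return np.broadcast_to(x, (n, x.size)).copy()
    out = x[None, :] + rng.normal(0.0, 1.0, size=(n, x.size)) * np.abs(x)[None, :] * k
    if positive:
        bad = np.isfinite(out) & (out <= 0) & (x[None, :] > 0)
        while bad.any():
            idx = np.nonzero(bad)
            out[idx] = x[idx[1]] + rng.normal(0.0, 1.0, size=idx[0].size) * np.abs(x[idx[1]]) * k
            bad = np.isfinite(out) & (out <= 0) & (x[None, :] > 0)
    return out


def noisify(
    stream: OpticalStream, cfg: WeberConfig = WeberConfig(), rng: np.random.Generator | None = None
) -> OpticalStream:
    """One noisy realization of an optical stream.

    Applies Weber-scaled Gaussian noise to theta, gamma and gamma_dot;
    the remaining series are passed through unchanged.
    """
    if rng is None:
        rng = cfg.rng()
    theta = _noisify_array(stream.theta, cfg.k_theta, rng, 1, positive=True)[0]
    gamma = _noisify_array(stream.gamma, cfg.k_gamma, rng, 1)[0]
    gamma_dot = _noisify_array(stream.gamma_dot, cfg.k_gamma_dot, rng, 1)[0]
    return OpticalStream(
        times=stream.times.copy(),
        distance=stream.distance.copy(),
        theta=theta,
        gamma=gamma,
        gamma_dot=gamma_dot,
        theta_dot=stream.theta_dot.copy(),
        radial_speed=stream.radial_speed.copy(),
    )


def _predicted_ensemble(
    stream: OpticalStream, priors: PriorSpec, cfg: WeberConfig, rng: np.random.Generator
) -> np.ndarray:
    """Matrix (n_sims, n_times) of noisified TTC predictions."""
    theta = _noisify_array(stream.theta, cfg.k_theta, rng, cfg.n_sims, positive=True)
    gamma = _noisify_array(stream.gamma, cfg.k_gamma, rng, cfg.n_sims)
    gamma_dot = _noisify_array(stream.gamma_dot, cfg.k_gamma_dot, rng, cfg.n_sims)
    return np.asarray(ttc_gs(theta, gamma, gamma_dot, priors))


def wf_timewise(
    stream: OpticalStream,
    priors: PriorSpec = PriorSpec(),
    cfg: WeberConfig = WeberConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Timewise precision of the TTC estimator under sensory noise.

    Runs ``cfg.n_sims`` noisified predictions and returns
    (times, WF(t) = SD / mean of the predicted TTC at each sample).
    The landing sample (true remaining time zero, degenerate geometry)
    is reported as NaN.
    """
    if rng is None:
        rng = cfg.rng()
    pred = _predicted_ensemble(stream, priors, cfg, rng)
    wf = np.full(stream.times.shape, np.nan)
    valid = np.isfinite(stream.theta)
    mean = pred[:, valid].mean(axis=0)
    sd = pred[:, valid].std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        wf[valid] = np.where(np.abs(mean) > 0, sd / np.abs(mean), np.nan)
    return stream.times.copy(), wf


def wf_combined(
    stream: OpticalStream,
    priors: PriorSpec = PriorSpec(),
    cfg: WeberConfig = WeberConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Precision of the estimator alone and fused with the tau cue.

    Tau carries a fixed Weber fraction (``cfg.k_tau``) and is defined only
    while the image expands (theta_dot > 0); elsewhere the fused output
    falls back to the estimator alone.  With both cues available the fused
    Weber fraction is the inverse-variance combination
    1 / sqrt(wf_gs^-2 + k_tau^-2), which never exceeds either input.

    Returns (times, wf_gs, wf_tau, wf_combined); wf_tau is NaN where tau
    is undefined.
    """
    times, wf_gs = wf_timewise(stream, priors, cfg, rng)
    wf_tau = np.where(stream.theta_dot > 0, cfg.k_tau, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        fused = 1.0 / np.sqrt(1.0 / wf_gs**2 + 1.0 / wf_tau**2)
    combined = np.where(np.isfinite(wf_tau) & np.isfinite(wf_gs), fused, wf_gs)
    combined = np.where(np.isfinite(combined), combined, wf_tau)
    return times, wf_gs, wf_tau, combined
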