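"""Closed-form mathematics of the variance-preserving Gaussian diffusion process.

The forward process takes an image (or latent) ``x`` and defines a family of
increasingly noisy latents ``z_t`` for continuous time ``t`` in [0, 1],

    q(z_t | x) = N(alpha_t * x, sigma_t^2 * I),

parameterized through a scalar log-signal-to-noise schedule ``gamma(t)``:

    sigma_t^2 = logistic(gamma(t)),   alpha_t^2 = 1 - sigma_t^2,

so that the signal-to-noise ratio SNR(t) = alpha_t^2 / sigma_t^2 = exp(-gamma(t))
is strictly decreasing whenever gamma is increasing.  The variance-preserving
identity alpha_t^2 + sigma_t^2 = 1 holds exactly by construction.

All transition and posterior distributions of the process are Gaussian with
coefficients given in closed form below; nothing in this module involves a
neural network, so every function is oracle-testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import expit

__all__ = [
    "GammaSchedule",
    "MarginalParams",
    "TransitionParams",
    "PosteriorParams",
    "gamma_linear",
    "marginal_params",
    "snr",
    "forward_sample",
    "transition_params",
    "posterior_params",
]


def _check_time(t, name: str = "t") -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t < 0.0) or np.any(t > 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {t!r}")
    return t


@dataclass(frozen=True)
class GammaSchedule:
    """Noise schedule gamma(t): [0, 1] -> [gamma_min, gamma_max].

    ``kind="linear"`` interpolates exactly between the endpoints; the default
    range 0.1 to 1.0 with a 50-step / 1000-substep evaluation grid matches the
    model's stated hyperparameters.  ``kind="learned"`` delegates to an
    externally supplied monotone callable ``fn`` (see
    :func:`medvdm.nets.make_learned_schedule`).
    """

    gamma_min: float = 0.1
    gamma_max: float = 1.0
    n_grid: int = 50
    n_substeps: int = 1000
    kind: str = "linear"
    fn: Optional[Callable[[np.ndarray], np.ndarray]] = field(default=None, repr=False)

    def __post_init__(self):
        if not self.gamma_max > self.gamma_min:
            raise ValueError("gamma_max must exceed gamma_min")
        if self.n_grid < 2 or self.n_substeps < 1:
            raise ValueError("need n_grid >= 2 and n_substeps >= 1")
        if self.kind not in ("linear", "learned"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.kind == "learned" and self.fn is None:
            raise ValueError("learned schedule requires fn")

    def gamma(self, t):
        """Evaluate gamma(t) for t (scalar or array) in [0, 1]."""
        t = _check_time(t)
        if self.kind == "linear":
            return gamma_linear(t, self)
        return np.asarray(self.fn(t), dtype=float)

    def gamma_prime(self, t):
        """d gamma / d t.  Exact for the linear schedule, central finite
        difference (h = 1e-4, one-sided at the endpoints) for learned ones."""
        t = _check_time(t)
        if self.kind == "linear":
            return np.broadcast_to(self.gamma_max - self.gamma_min, t.shape).astype(float) \
            if t.ndim else float(self.gamma_max - self.gamma_min)
        h = 1e-4
        lo = np.clip(t - h, 0.0, 1.0)
        hi = np.clip(t + h, 0.0, 1.0)
        return (self.gamma(hi) - self.gamma(lo)) / (hi - lo)

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Tabulate the schedule on its evaluation grid of
        (n_grid - 1) * n_substeps + 1 linearly spaced times."""
        t = np.linspace(0.0, 1.0, (self.n_grid - 1) * self.n_substeps + 1)
        return t, self.gamma(t)


@dataclass(frozen=True)
class MarginalParams:
    """Coefficients of q(z_t | x) = N(alpha_t x, sigma_t^2 I)."""

    alpha: np.ndarray
    sigma: np.ndarray


@dataclass(frozen=True)
class TransitionParams:
    """Coefficients of q(z_t | z_s) = N(alpha_ts z_s, sigma2_ts I), s <= t."""

    alpha_ts: np.ndarray
    sigma2_ts: np.ndarray


@dataclass(frozen=True)
class PosteriorParams:
    """Mean and (scalar) variance of q(z_s | z_t, x), 0 <= s < t <= 1."""

    mean: np.ndarray
    variance: float


def gamma_linear(t, schedule: GammaSchedule):
    """Linear schedule gamma(t) = gamma_min + t (gamma_max - gamma_min)."""
    if schedule.kind != "linear":
        raise ValueError("gamma_linear requires a linear schedule")
    t = _check_time(t)
    return schedule.gamma_min + t * (schedule.gamma_max - schedule.gamma_min)


def marginal_params(gamma) -> MarginalParams:
    """Map a log-SNR level gamma to (alpha_t, sigma_t) with alpha^2 + sigma^2 = 1.

    sigma_t^2 = logistic(gamma) and alpha_t^2 = logistic(-gamma); the identity
    logistic(g) + logistic(-g) = 1 makes variance preservation exact.
    """
    gamma = np.asarray(gamma, dtype=float)
    if not np.all(np.isfinite(gamma)):
        raise ValueError("gamma must be finite")
    sigma = np.sqrt(expit(gamma))
    alpha = np.sqrt(expit(-gamma))
    return MarginalParams(alpha=alpha, sigma=sigma)


def snr(gamma):
    """Signal-to-noise ratio alpha^2 / sigma^2 = exp(-gamma)."""
    gamma = np.asarray(gamma, dtype=float)
    if not np.all(np.isfinite(gamma)):
        raise ValueError("gamma must be finite")
    return np.exp(-gamma)


def forward_sample(x, t, noise, schedule: GammaSchedule):
    """Draw z_t = alpha_t x + sigma_t noise from q(z_t | x).

    ``noise`` must be a standard-normal draw of the same shape as ``x``; it is
    supplied explicitly so sampling stays deterministic and reparameterized.
    """
    x = np.asarray(x, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if noise.shape != x.shape:
        raise ValueError(f"noise shape {noise.shape} != x shape {x.shape}")
    mp = marginal_params(schedule.gamma(t))
    return mp.alpha * x + mp.sigma * noise


def transition_params(s, t, schedule: GammaSchedule) -> TransitionParams:
    """Coefficients of the Markov transition q(z_t | z_s) for s <= t.

    alpha_ts = alpha_t / alpha_s and sigma2_ts = sigma_t^2 - alpha_ts^2 sigma_s^2,
    the unique Gaussian coefficients for which q(z_t|z_s) composed over
    q(z_s|x) reproduces the marginal q(z_t|x).
    """
    s_arr = _check_time(s, "s")
    t_arr = _check_time(t, "t")
    if np.any(s_arr > t_arr):
        raise ValueError("transition requires s <= t")
    mp_s = marginal_params(schedule.gamma(s_arr))
    mp_t = marginal_params(schedule.gamma(t_arr))
    alpha_ts = mp_t.alpha / mp_s.alpha
    sigma2_ts = mp_t.sigma**2 - alpha_ts**2 * mp_s.sigma**2
    sigma2_ts = np.maximum(sigma2_ts, 0.0)  # guard float cancellation at s ~ t
    return TransitionParams(alpha_ts=alpha_ts, sigma2_ts=sigma2_ts)


def posterior_params(z_t, x, s, t, schedule: GammaSchedule) -> PosteriorParams:
    """Bayes posterior q(z_s | z_t, x) of the forward process, 0 <= s < t <= 1.

    variance = sigma2_ts sigma_s^2 / sigma_t^2
    mean     = (alpha_ts sigma_s^2 / sigma_t^2) z_t + (alpha_s sigma2_ts / sigma_t^2) x
    """
    s_arr = _check_time(s, "s")
    t_arr = _check_time(t, "t")
    if not np.all(s_arr < t_arr):
        raise ValueError("posterior requires s < t")
    z_t = np.asarray(z_t, dtype=float)
    x = np.asarray(x, dtype=float)
    mp_s = marginal_params(schedule.gamma(s_arr))
    mp_t = marginal_params(schedule.gamma(t_arr))
    tr = transition_params(s_arr, t_arr, schedule)
    sigma_t2 = mp_t.sigma**2
    variance = tr.sigma2_ts * mp_s.sigma**2 / sigma_t2
    mean = (tr.alpha_ts * mp_s.sigma**2 / sigma_t2) * z_t + (mp_s.alpha * tr.sigma2_ts / sigma_t2) * x
    return PosteriorParams(mean=mean, variance=float(variance) if np.ndim(variance) == 0 else variance)
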