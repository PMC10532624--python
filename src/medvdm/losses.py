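"""Training objective: the variational lower bound plus an edge-matching term.

The VLB of the model factorizes into three nonnegative pieces,

* reconstruction — negative log-likelihood of the image under the decoder's
  mean-field Bernoulli model, given a latent drawn from q(z_0 | x);
* diffusion — the schedule-weighted expected squared error between the true
  and predicted noise, equal to the KL divergence between the forward and
  reverse joint distributions (discrete-time) or its continuous-time limit;
* latent — KL between the fully noised marginal q(z_1 | x) and the standard
  normal prior;

and the objective adds a fourth, non-variational *differential* term, the
mean squared difference of finite-difference image gradients between the
input and the decoded mean image, which penalizes edge disagreement.

Losses are reported in nats per image (summed over pixels/dimensions,
averaged over the batch).  Monte-Carlo time points use antithetic
(stratified) sampling by default: one point per interval [i/n, (i+1)/n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from . import autodiff as ad
from .diffusion import GammaSchedule, marginal_params
from .nets import ModelConfig, decode, encode, scorenet

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "reconstruction_loss",
    "latent_loss",
    "diffusion_loss_discrete",
    "diffusion_loss_continuous",
    "differential_loss",
    "antithetic_times",
    "total_loss",
    "loss_terms",
]


@dataclass(frozen=True)
class LossWeights:
    """Nonnegative weights of the four loss terms in the total objective."""

    reconstruction: float = 1.0
    diffusion: float = 1.0
    latent: float = 1.0
    differential: float = 1.0

    def __post_init__(self):
        w = (self.reconstruction, self.diffusion, self.latent, self.differential)
        if any(x < 0 for x in w):
            raise ValueError("loss weights must be nonnegative")


@dataclass(frozen=True)
class LossBreakdown:
    """Per-term losses (nats per image) and their weighted total."""

    reconstruction: float
    diffusion: float
    latent: float
    differential: float
    total: float
    weights: LossWeights

    def as_dict(self) -> dict:
        return {
            "reconstruction": self.reconstruction,
            "diffusion": self.diffusion,
            "latent": self.latent,
            "differential": self.differential,
            "total": self.total,
        }


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _per_image(term, batch_first: bool):
    """Sum a per-element loss over all dims, averaging over a leading batch axis."""
    v = ad.value(term)
    if batch_first and v.ndim >= 1:
        axes = tuple(range(1, v.ndim))
        per = ad.reduce_sum(term, axis=axes) if axes else term
        return ad.reduce_mean(per)
    return ad.reduce_sum(term)


def reconstruction_loss(x, logits):
    """Negative Bernoulli log-likelihood, summed over pixels, batch-averaged.

    Uses the numerically stable logit form softplus(l) - x*l.  ``x`` must lie
    in [0, 1]; a (B, H, W) input is treated as a batch, lower-rank input as a
    single image.
    """
    xv = np.asarray(ad.value(x), dtype=float)
    if np.any(xv < 0.0) or np.any(xv > 1.0):
        raise ValueError("pixel intensities must lie in [0, 1]")
    lv = ad.value(logits)
    if lv.shape != xv.shape:
        raise ValueError(f"logits shape {lv.shape} != image shape {xv.shape}")
    bce = ad.sub(ad.softplus(logits), ad.mul(xv, logits))
    return _per_image(bce, batch_first=xv.ndim >= 3)


def latent_loss(x, schedule: GammaSchedule):
    """KL( q(z_1|x) || N(0, I) ) = 1/2 sum_i (alpha_1^2 x_i^2 + sigma_1^2 - 1 - ln sigma_1^2).

    A 2-D ``x`` is treated as a batch of vectors (batch-averaged); lower rank
    as a single item.
    """
    g1 = float(schedule.gamma(1.0))
    s2 = float(expit(g1))
    a2 = float(expit(-g1))
    if s2 <= 0.0:
        raise ValueError("sigma_1^2 must be positive (KL would be infinite)")
    per_dim = ad.mul(0.5, ad.add(ad.mul(a2, ad.square(x)), s2 - 1.0 - np.log(s2)))
    xv = ad.value(x)
    return _per_image(per_dim, batch_first=np.ndim(xv) >= 2)


def antithetic_times(n: int, u0: float) -> np.ndarray:
    """Stratified times t_i = frac(u0 + i/n): exactly one per interval [i/n, (i+1)/n)."""
    if n < 1:
        raise ValueError("need n >= 1")
    if not 0.0 <= u0 < 1.0:
        raise ValueError("u0 must lie in [0, 1)")
    # computed as (bin index + common offset) / n so the one-sample-per-bin
    # property survives floating-point rounding at bin boundaries
    off = u0 * n
    k0 = np.floor(off)
    frac = off - k0
    bins = (np.arange(n) + int(k0)) % n
    return (bins + frac) / n


def _row_coeff(arr: np.ndarray, ndim: int) -> np.ndarray:
    """Reshape a per-row coefficient (B,) for broadcasting against (B, ...)."""
    return arr.reshape(arr.shape + (1,) * (ndim - 1))


def _sq_err_per_row(eps: np.ndarray, eps_hat):
    err = ad.sub(eps, eps_hat)
    axes = tuple(range(1, eps.ndim))
    return ad.reduce_sum(ad.square(err), axis=axes) if axes else ad.square(err)


def diffusion_loss_discrete(x, noise_predictor, T: int, schedule: GammaSchedule,
                            seed=0, antithetic: bool = True):
    """Discrete-time diffusion loss with T reverse steps.

    (T/2) * E_{i, eps} [ (exp(gamma(t_i) - gamma(s_i)) - 1) * ||eps - eps_hat||^2 ]
    with s_i = (i-1)/T, t_i = i/T, i uniform on {1..T}.  One (i, eps) draw per
    batch row; step indices are stratified over the batch when ``antithetic``.
    ``noise_predictor(z_t, gamma_t)`` must return an array shaped like ``z_t``.
    """
    if T < 1:
        raise ValueError("need T >= 1")
    rng = _rng(seed)
    xv = ad.value(x)
    B = xv.shape[0]
    u = antithetic_times(B, rng.uniform()) if antithetic else rng.uniform(size=B)
    i = np.floor(u * T).astype(int) + 1
    s, t = (i - 1) / T, i / T
    g_s, g_t = schedule.gamma(s), schedule.gamma(t)
    mp_t = marginal_params(g_t)
    eps = rng.standard_normal(xv.shape)
    z_t = ad.add(ad.mul(_row_coeff(mp_t.alpha, xv.ndim), x),
                 _row_coeff(mp_t.sigma, xv.ndim) * eps)
    eps_hat = noise_predictor(z_t, g_t)
    weight = np.expm1(g_t - g_s)
    sq = _sq_err_per_row(eps, eps_hat)
    return ad.mul(T / 2.0, ad.reduce_mean(ad.mul(weight, sq)))


def diffusion_loss_continuous(x, noise_predictor, schedule: GammaSchedule,
                              seed=0, n_times: int | None = None,
                              antithetic: bool = True):
    """Continuous-time diffusion loss 1/2 * E_{t, eps}[ gamma'(t) ||eps - eps_hat||^2 ].

    One time point per batch row (stratified when ``antithetic``).  When
    ``n_times`` differs from the batch size, rows of a plain-array ``x`` are
    recycled to give ``n_times`` Monte-Carlo draws.
    """
    xv = ad.value(x)
    B = xv.shape[0]
    n = B if n_times is None else int(n_times)
    if n < 1:
        raise ValueError("need n_times >= 1")
    if n != B:
        if isinstance(x, ad.Var):
            raise ValueError("n_times must equal the batch size for traced inputs")
        x = xv = xv[np.resize(np.arange(B), n)]
    rng = _rng(seed)
    t = antithetic_times(n, rng.uniform()) if antithetic else rng.uniform(size=n)
    g_t = schedule.gamma(t)
    gp = schedule.gamma_prime(t)
    mp = marginal_params(g_t)
    eps = rng.standard_normal(ad.value(x).shape)
    nd = ad.value(x).ndim
    z_t = ad.add(ad.mul(_row_coeff(mp.alpha, nd), x), _row_coeff(mp.sigma, nd) * eps)
    eps_hat = noise_predictor(z_t, g_t)
    sq = _sq_err_per_row(eps, eps_hat)
    return ad.mul(0.5, ad.reduce_mean(ad.mul(np.asarray(gp, float), sq)))


def differential_loss(x, x_hat):
    """Mean squared disagreement of forward finite-difference gradients.

    Horizontal and vertical differences are taken on the common
    (H-1) x (W-1) grid (last row and column excluded); constants shift out.
    """
    xv = np.asarray(ad.value(x), dtype=float)
    hv = ad.value(x_hat)
    if hv.shape != xv.shape:
        raise ValueError(f"shape mismatch {hv.shape} vs {xv.shape}")
    if xv.ndim < 2 or xv.shape[-1] < 2 or xv.shape[-2] < 2:
        raise ValueError("images must be at least 2x2")
    crop = (Ellipsis, slice(None, -1), slice(None, -1))
    right = (Ellipsis, slice(None, -1), slice(1, None))
    down = (Ellipsis, slice(1, None), slice(None, -1))

    def grads(a):
        return (ad.sub(ad.getitem(a, right), ad.getitem(a, crop)),
                ad.sub(ad.getitem(a, down), ad.getitem(a, crop)))

    dhx, dvx = grads(x)
    dhh, dvh = grads(x_hat)
    err = ad.add(ad.square(ad.sub(dhx, dhh)), ad.square(ad.sub(dvx, dvh)))
    return ad.reduce_mean(err)


def loss_terms(x, params: dict, config: ModelConfig, schedule: GammaSchedule,
               weights: LossWeights, rng_recon: np.random.Generator,
               rng_diff: np.random.Generator, antithetic: bool = True) -> dict:
    """All four loss terms plus the weighted total, as autodiff scalars.

    This is the traced core shared by :func:`total_loss` and the trainer;
    ``params`` may hold arrays (inference) or Var leaves (training).
    """
    xv = np.asarray(ad.value(x), dtype=float)
    B = xv.shape[0]
    f = encode(x, config, params)
    latent = latent_loss(f, schedule)

    mp0 = marginal_params(schedule.gamma(0.0))
    eps0 = rng_recon.standard_normal(ad.value(f).shape)
    z0 = ad.add(ad.mul(float(mp0.alpha), f), float(mp0.sigma) * eps0)
    logits = decode(z0, config, params)
    recon = reconstruction_loss(xv, logits)

    cond = np.zeros((B, config.n_classes)) if config.n_classes > 0 else None
    predictor = lambda z, g: scorenet(z, g, cond, config, params)
    diff = diffusion_loss_continuous(f, predictor, schedule, seed=rng_diff,
                                     antithetic=antithetic)

    x_hat = ad.sigmoid(logits)
    dloss = differential_loss(xv, x_hat)

    total = ad.add(
        ad.add(ad.mul(weights.reconstruction, recon), ad.mul(weights.diffusion, diff)),
        ad.add(ad.mul(weights.latent, latent), ad.mul(weights.differential, dloss)),
    )
    return {"reconstruction": recon, "diffusion": diff, "latent": latent,
            "differential": dloss, "total": total}


def total_loss(x, params: dict, config: ModelConfig, schedule: GammaSchedule,
               weights: LossWeights | None = None, seed: int = 0,
               antithetic: bool = True) -> LossBreakdown:
    """Evaluate the full objective on an image batch; returns a LossBreakdown.

    Randomness is split deterministically from ``seed`` into two child
    streams (reconstruction-noise, then diffusion time/noise), so each term
    is individually reproducible by calling its operation with the matching
    child generator.
    """
    weights = weights or LossWeights()
    children = np.random.SeedSequence(seed).spawn(2)
    rng_recon = np.random.default_rng(children[0])
    rng_diff = np.random.default_rng(children[1])
    terms = loss_terms(x, params, config, schedule, weights, rng_recon, rng_diff,
                       antithetic=antithetic)
    return LossBreakdown(
        reconstruction=float(ad.value(terms["reconstruction"])),
        diffusion=float(ad.value(terms["diffusion"])),
        latent=float(ad.value(terms["latent"])),
        differential=float(ad.value(terms["differential"])),
        total=float(ad.value(terms["total"])),
        weights=weights,
    )
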