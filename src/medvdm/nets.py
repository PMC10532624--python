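"""Learnable components: encoder / decoder ResNets, FiLM-conditioned ScoreNet,
sinusoidal time embedding, and the monotone noise-schedule network.

All networks are pure functions of ``(inputs, params)``.  Parameters live in
nested dicts of numpy arrays ("pytrees"); passing :class:`~medvdm.autodiff.Var`
leaves instead of arrays traces the computation for reverse-mode autodiff.
Stochasticity never lives inside a network — noise is always an explicit
argument of the caller.

Architecture summary
--------------------
* encoder: dense stem -> ``encoder_blocks`` residual blocks -> dense head to a
  ``latent_dim``-dimensional code (default 64).
* decoder: dense stem -> ``decoder_blocks`` residual blocks -> dense head to
  per-pixel Bernoulli logits (mean-field observational model: the likelihood
  factorizes over pixels).
* ScoreNet: the noisy latent is dense-projected to ``score_embedding_dim``
  (default 128), passed through ``score_layers`` (default 10) residual blocks
  conditioned FiLM-style on a vector built from the time embedding of the
  noise level gamma_t (optionally concatenated with a class-conditioning
  vector) via two swish-activated dense layers, and the result is added to a
  dense projection of the input — the network predicts the injected noise
  (epsilon-prediction).
* monotone gamma net: a one-hidden-layer network whose weights are passed
  through softplus, giving an output nondecreasing in t for *every* parameter
  setting, affinely rescaled to hit [gamma_min, gamma_max] at the endpoints.

Residual blocks are two dense layers with swish and an additive skip; the last
layer of every residual branch is zero-initialized so a freshly initialized
network starts close to its skip path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from . import autodiff as ad
from .diffusion import GammaSchedule

__all__ = [
    "ModelConfig",
    "time_embedding",
    "init_params",
    "encode",
    "decode",
    "scorenet",
    "init_gamma_net_params",
    "monotonic_gamma_net",
    "make_learned_schedule",
    "count_params",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters with the model's published defaults."""

    latent_dim: int = 64
    encoder_blocks: int = 6
    decoder_blocks: int = 6
    score_embedding_dim: int = 128
    score_layers: int = 10
    image_size: int = 256
    hidden_dim: int = 128          # width of encoder/decoder trunks
    n_classes: int = 0             # length of optional conditioning vector
    encoder_time_conditioning: bool = False

    def __post_init__(self):
        counts = (self.latent_dim, self.encoder_blocks, self.decoder_blocks,
                  self.score_embedding_dim, self.score_layers, self.image_size,
                  self.hidden_dim)
        if any(int(c) != c or c <= 0 for c in counts):
            raise ValueError("all architecture counts must be positive integers")
        if self.image_size % 2 != 0:
            raise ValueError("image_size must be even")
        if self.score_embedding_dim % 2 != 0:
            raise ValueError("score_embedding_dim must be even (sin/cos halves)")
        if self.n_classes < 0:
            raise ValueError("n_classes must be nonnegative")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def _dense_init(rng: np.random.Generator, n_in: int, n_out: int, scale: float | None = None):
    if scale is None:
        scale = np.sqrt(2.0 / n_in)
    return {"W": rng.normal(0.0, scale, size=(n_in, n_out)), "b": np.zeros(n_out)}


def _dense(p, x):
    return ad.add(ad.matmul(x, p["W"]), p["b"])


def _block_init(rng, width: int, film: bool = False, cond_dim: int = 0):
    p = {
        "d1": _dense_init(rng, width, width),
        "d2": {"W": np.zeros((width, width)), "b": np.zeros(width)},  # zero-init branch end
    }
    if film:
        p["film"] = _dense_init(rng, cond_dim, 2 * width, scale=np.sqrt(1.0 / cond_dim))
    return p


def _block(p, h, cond=None):
    h1 = ad.swish(_dense(p["d1"], h))
    if cond is not None:
        film = _dense(p["film"], cond)
        width = ad.value(h1).shape[-1]
        scale = ad.getitem(film, (slice(None), slice(0, width)))
        shift = ad.getitem(film, (slice(None), slice(width, 2 * width)))
        h1 = ad.add(ad.mul(h1, ad.add(1.0, scale)), shift)
    return ad.add(h, _dense(p["d2"], h1))


def time_embedding(t, dim: int):
    """Sinusoidal embedding of a scalar (or batch of) time/noise levels.

    Frequencies are geometrically spaced from 10^0 to 10^4; the first half of
    the vector is sin(w_k t), the second half cos(w_k t).  A scalar ``t``
    yields a vector of length ``dim``; a batch of shape (B,) yields (B, dim).
    """
    if dim % 2 != 0:
        raise ValueError("embedding dim must be even")
    half = dim // 2
    freqs = 10.0 ** np.linspace(0.0, 4.0, half)
    scalar = np.ndim(ad.value(t)) == 0
    tcol = ad.reshape(t, (-1, 1))
    args = ad.mul(tcol, freqs[None, :])
    emb = ad.concat([ad.sin(args), ad.cos(args)], axis=-1)
    if scalar and not isinstance(emb, ad.Var):
        return emb[0]
    return ad.reshape(emb, (dim,)) if scalar else emb


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def init_params(config: ModelConfig, rng: np.random.Generator) -> dict:
    """Initialize all network parameters for ``config``; returns a pytree."""
    d = config.image_size * config.image_size
    h = config.hidden_dim
    e = config.score_embedding_dim
    L = config.latent_dim
    cond_dim = e
    params = {
        "encoder": {
            "stem": _dense_init(rng, d, h),
            "blocks": [_block_init(rng, h) for _ in range(config.encoder_blocks)],
            "head": _dense_init(rng, h, L),
        },
        "decoder": {
            "stem": _dense_init(rng, L, h),
            "blocks": [_block_init(rng, h) for _ in range(config.decoder_blocks)],
            "head": _dense_init(rng, h, d),
        },
        "scorenet": {
            "cond1": _dense_init(rng, e + config.n_classes, e),
            "cond2": _dense_init(rng, e, e),
            "cond3": _dense_init(rng, e, cond_dim),
            "stem": _dense_init(rng, L, e),
            "blocks": [_block_init(rng, e, film=True, cond_dim=cond_dim)
                       for _ in range(config.score_layers)],
            "head": _dense_init(rng, e, L),
            "skip": _dense_init(rng, L, L, scale=np.sqrt(1.0 / L)),
        },
    }
    if config.encoder_time_conditioning:
        params["encoder"]["temb_proj"] = _dense_init(rng, e, h, scale=np.sqrt(1.0 / e))
    return params


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------


def encode(x, config: ModelConfig, params: dict, t=None):
    """Map an image batch (B, S, S) in [0, 1] to latent codes (B, latent_dim).

    ``t`` conditions the encoder on time only when the config enables it;
    the default encoder is time-independent.
    """
    p = params["encoder"]
    xv = ad.value(x)
    if xv.ndim != 3 or xv.shape[1] != config.image_size or xv.shape[2] != config.image_size:
        raise ValueError(
            f"expected images of shape (B, {config.image_size}, {config.image_size}), got {xv.shape}")
    flat = ad.reshape(x, (xv.shape[0], -1))
    h = ad.swish(_dense(p["stem"], flat))
    if config.encoder_time_conditioning and t is not None:
        temb = time_embedding(np.broadcast_to(np.asarray(t, float), (xv.shape[0],)),
                              config.score_embedding_dim)
        h = ad.add(h, _dense(p["temb_proj"], temb))
    for bp in p["blocks"]:
        h = _block(bp, h)
    return _dense(p["head"], h)


def decode(z, config: ModelConfig, params: dict):
    """Map latent codes (B, latent_dim) to per-pixel Bernoulli logits (B, S, S)."""
    p = params["decoder"]
    zv = ad.value(z)
    if zv.ndim != 2 or zv.shape[1] != config.latent_dim:
        raise ValueError(f"expected latents of shape (B, {config.latent_dim}), got {zv.shape}")
    h = ad.swish(_dense(p["stem"], z))
    for bp in p["blocks"]:
        h = _block(bp, h)
    logits = _dense(p["head"], h)
    return ad.reshape(logits, (zv.shape[0], config.image_size, config.image_size))


def scorenet(z, gt, conditioning, config: ModelConfig, params: dict):
    """Predict the standard-normal noise in ``z`` at log-SNR level ``gt``.

    ``gt`` is a scalar or (B,) array of gamma values; ``conditioning`` is a
    (B, n_classes) array (ignored when n_classes = 0).  Output has the shape
    of ``z``.
    """
    p = params["scorenet"]
    zv = ad.value(z)
    if zv.ndim != 2 or zv.shape[1] != config.latent_dim:
        raise ValueError(f"expected latents of shape (B, {config.latent_dim}), got {zv.shape}")
    B = zv.shape[0]
    gt_b = np.broadcast_to(np.asarray(ad.value(gt), dtype=float).reshape(-1), (B,)) \
        if np.ndim(ad.value(gt)) == 0 or ad.value(gt).size == 1 else gt
    temb = time_embedding(gt_b, config.score_embedding_dim)
    if config.n_classes > 0:
        cv = ad.value(conditioning)
        if cv.ndim != 2 or cv.shape != (B, config.n_classes):
            raise ValueError(
                f"conditioning must have shape ({B}, {config.n_classes}), got {cv.shape}")
        cond_in = ad.concat([temb, conditioning], axis=-1)
    else:
        cond_in = temb
    cond = ad.swish(_dense(p["cond1"], cond_in))
    cond = ad.swish(_dense(p["cond2"], cond))
    cond = _dense(p["cond3"], cond)
    h = ad.swish(_dense(p["stem"], z))
    for bp in p["blocks"]:
        h = _block(bp, h, cond=cond)
    resnet_out = _dense(p["head"], h)
    return ad.add(resnet_out, _dense(p["skip"], z))


# ---------------------------------------------------------------------------
# monotone noise-schedule network
# ---------------------------------------------------------------------------


def init_gamma_net_params(rng: np.random.Generator, hidden: int = 16) -> dict:
    """Raw (unconstrained) parameters of the monotone schedule network."""
    return {
        "w1_raw": rng.normal(0.0, 1.0, size=(1, hidden)),
        "b1": rng.normal(0.0, 1.0, size=hidden),
        "w2_raw": rng.normal(0.0, 1.0, size=hidden),
    }


def _gamma_net_raw(t: np.ndarray, params: dict) -> np.ndarray:
    # softplus reparameterization keeps every effective weight nonnegative, so
    # g(t) = t + sum_k w2_k * sigmoid(w1_k t + b1_k) is nondecreasing for any params
    w1 = np.logaddexp(0.0, params["w1_raw"])
    w2 = np.logaddexp(0.0, params["w2_raw"])
    hid = expit(t[:, None] * w1 + params["b1"])
    return t + hid @ w2


def monotonic_gamma_net(t, params: dict, gamma_min: float = 0.1, gamma_max: float = 1.0):
    """Structurally monotone gamma(t), rescaled to the endpoints.

    gamma(t) = gamma_min + (gamma_max - gamma_min) * (g(t) - g(0)) / (g(1) - g(0))
    where g is nondecreasing for every admissible parameter setting.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t_flat = np.atleast_1d(t)
    if np.any(t_flat < 0.0) or np.any(t_flat > 1.0) or not np.all(np.isfinite(t_flat)):
        raise ValueError("t must lie in [0, 1]")
    ends = _gamma_net_raw(np.array([0.0, 1.0]), params)
    g = _gamma_net_raw(t_flat, params)
    out = gamma_min + (gamma_max - gamma_min) * (g - ends[0]) / (ends[1] - ends[0])
    return float(out[0]) if scalar else out.reshape(t.shape)


def make_learned_schedule(params: dict, gamma_min: float = 0.1, gamma_max: float = 1.0,
                          n_grid: int = 50, n_substeps: int = 1000) -> GammaSchedule:
    """Wrap monotone-network parameters as a learned :class:`GammaSchedule`."""
    fn = lambda t: monotonic_gamma_net(t, params, gamma_min, gamma_max)
    return GammaSchedule(gamma_min=gamma_min, gamma_max=gamma_max, n_grid=n_grid,
                         n_substeps=n_substeps, kind="learned", fn=fn)


def count_params(params: dict) -> int:
    """Total scalar parameter count of a pytree."""
    return int(sum(np.size(leaf) for leaf in ad.tree_leaves(params)))
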