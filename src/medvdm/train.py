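"""Optimization loop: AdamW with linear warmup and cosine decay.

The learning rate composes three published pieces multiplicatively:

    lr(step) = base_lr * warmup(step) * cosine(step)

where warmup rises linearly 0 -> 1 over ``warmup_steps`` and the cosine
factor decays 1 -> ``final_decay`` over ``total_steps``.  AdamW uses
decoupled weight decay, excluded from bias parameters as is standard.

Training is stateless-seeded: the per-epoch shuffle and the per-step loss
randomness are derived from (seed, epoch) and (seed, step) seed sequences,
so resuming from a checkpoint reproduces the uninterrupted run exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from . import autodiff as ad
from .diffusion import GammaSchedule
from .losses import LossBreakdown, LossWeights, loss_terms
from .nets import ModelConfig, init_params

__all__ = ["TrainConfig", "TrainResult", "lr_at", "adamw_step", "decay_mask",
           "loss_and_grad", "train", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer recipe with the published defaults."""

    base_lr: float = 8e-4
    warmup_steps: int = 250
    total_steps: int = 20_000
    final_decay: float = 1e-5
    b1: float = 0.9
    b2: float = 0.99
    eps: float = 1e-8
    weight_decay: float = 1e-4
    batch_size: int = 64
    seed: int = 0
    log_every: int = 10

    def __post_init__(self):
        if not (0 < self.b1 < 1 and 0 < self.b2 < 1):
            raise ValueError("moment coefficients must lie in (0, 1)")
        if self.warmup_steps > self.total_steps:
            raise ValueError("warmup_steps must not exceed total_steps")
        if self.base_lr <= 0 or self.final_decay <= 0 or self.eps <= 0:
            raise ValueError("rates must be positive")
        if self.batch_size < 1 or self.total_steps < 1:
            raise ValueError("counts must be positive")


@dataclass
class TrainResult:
    params: dict
    opt_state: dict
    history: list = field(default_factory=list)


def lr_at(step: int, cfg: TrainConfig) -> float:
    """Learning rate at an optimizer step (clamped beyond total_steps)."""
    if step < 0:
        raise ValueError("step must be nonnegative")
    step = min(step, cfg.total_steps)
    warm = min(1.0, step / cfg.warmup_steps) if cfg.warmup_steps > 0 else 1.0
    cosine = cfg.final_decay + (1.0 - cfg.final_decay) * 0.5 * (
        1.0 + np.cos(np.pi * step / cfg.total_steps))
    return cfg.base_lr * warm * cosine


def decay_mask(params: dict) -> dict:
    """1.0 for weight matrices, 0.0 for biases — the decoupled-decay mask."""
    flat = ad.tree_flatten(params)
    mask = {k: (0.0 if k.rsplit("/", 1)[-1].startswith("b") else 1.0) for k in flat}
    return ad.tree_unflatten({k: np.asarray(v) for k, v in mask.items()})


def init_opt_state(params: dict) -> dict:
    zeros = lambda p: np.zeros_like(p)
    return {"m": ad.tree_map(zeros, params), "v": ad.tree_map(zeros, params), "count": 0}


def adamw_step(params: dict, grads: dict, state: dict, lr: float,
               cfg: TrainConfig, mask: dict) -> tuple[dict, dict]:
    """One decoupled-weight-decay Adam update; returns (new_params, new_state)."""
    k = state["count"] + 1
    b1, b2 = cfg.b1, cfg.b2
    m = ad.tree_map(lambda m_, g: b1 * m_ + (1 - b1) * g, state["m"], grads)
    v = ad.tree_map(lambda v_, g: b2 * v_ + (1 - b2) * g * g, state["v"], grads)
    c1, c2 = 1 - b1**k, 1 - b2**k

    def update(p, m_, v_, msk):
        step_dir = (m_ / c1) / (np.sqrt(v_ / c2) + cfg.eps)
        return p - lr * (step_dir + cfg.weight_decay * msk * p)

    new_params = ad.tree_map(update, params, m, v, mask)
    return new_params, {"m": m, "v": v, "count": k}


def loss_and_grad(x, params: dict, config: ModelConfig, schedule: GammaSchedule,
                  weights: LossWeights, seed: int) -> tuple[LossBreakdown, dict]:
    """Loss breakdown and parameter gradients of the weighted total."""
    var_params = ad.tree_map(ad.Var, params)
    children = np.random.SeedSequence(seed).spawn(2)
    terms = loss_terms(x, var_params, config, schedule, weights,
                       np.random.default_rng(children[0]),
                       np.random.default_rng(children[1]))
    total = terms["total"]
    if not isinstance(total, ad.Var):
        raise RuntimeError("loss did not depend on parameters")
    ad.backward(total)
    grads = ad.tree_map(
        lambda v: v.grad if v.grad is not None else np.zeros_like(v.value), var_params)
    breakdown = LossBreakdown(
        reconstruction=float(ad.value(terms["reconstruction"])),
        diffusion=float(ad.value(terms["diffusion"])),
        latent=float(ad.value(terms["latent"])),
        differential=float(ad.value(terms["differential"])),
        total=float(ad.value(total)),
        weights=weights,
    )
    return breakdown, grads


def _step_seed(seed: int, step: int) -> int:
    return int(np.random.SeedSequence([seed, step]).generate_state(1)[0] % (2**31))


def _epoch_perm(seed: int, epoch: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([seed, epoch, 0xE70C]))
    return rng.permutation(n)


def train(dataset: np.ndarray, model_cfg: ModelConfig, train_cfg: TrainConfig,
          loss_weights: LossWeights | None = None,
          schedule: GammaSchedule | None = None,
          params: Optional[dict] = None, opt_state: Optional[dict] = None,
          start_step: int = 0, n_steps: Optional[int] = None) -> TrainResult:
    """Run (a segment of) the training loop.

    ``dataset`` is an (N, S, S) array of images in [0, 1].  With the default
    arguments the full ``train_cfg.total_steps`` updates are run from a fresh
    initialization; passing ``params``/``opt_state``/``start_step`` resumes a
    checkpointed run, reproducing the uninterrupted loss history exactly.
    """
    dataset = np.asarray(dataset, dtype=float)
    if dataset.ndim != 3 or dataset.shape[0] == 0:
        raise ValueError("dataset must be a nonempty (N, S, S) array")
    weights = loss_weights or LossWeights()
    schedule = schedule or GammaSchedule()
    if params is None:
        params = init_params(model_cfg, np.random.default_rng(
            np.random.SeedSequence([train_cfg.seed, 0x1217])))
    if opt_state is None:
        opt_state = init_opt_state(params)
    mask = decay_mask(params)

    N = dataset.shape[0]
    B = min(train_cfg.batch_size, N)
    steps_per_epoch = max(1, N // B)
    end_step = train_cfg.total_steps if n_steps is None else min(
        train_cfg.total_steps, start_step + n_steps)

    history: list[dict] = []
    for step in range(start_step, end_step):
        epoch, pos = divmod(step, steps_per_epoch)
        perm = _epoch_perm(train_cfg.seed, epoch, N)
        idx = perm[pos * B:(pos + 1) * B]
        batch = dataset[idx]
        breakdown, grads = loss_and_grad(batch, params, model_cfg, schedule,
                                         weights, _step_seed(train_cfg.seed, step))
        if not np.isfinite(breakdown.total):
            raise RuntimeError(
                f"non-finite loss at step {step}: {breakdown.as_dict()}")
        lr = lr_at(step, train_cfg)
        params, opt_state = adamw_step(params, grads, opt_state, lr, train_cfg, mask)
        if step % train_cfg.log_every == 0 or step == train_cfg.total_steps - 1:
            history.append({"step": step, **breakdown.as_dict()})
    return TrainResult(params=params, opt_state=opt_state, history=history)


# ---------------------------------------------------------------------------
# checkpointing: named-tensor archive + optimizer state + step + configs
# ---------------------------------------------------------------------------


def save_checkpoint(path, params: dict, opt_state: dict, step: int,
                    model_cfg: ModelConfig, train_cfg: TrainConfig,
                    extra: Optional[dict] = None) -> None:
    arrays = {f"params/{k}": v for k, v in ad.tree_flatten(params).items()}
    arrays.update({f"opt/m/{k}": v for k, v in ad.tree_flatten(opt_state["m"]).items()})
    arrays.update({f"opt/v/{k}": v for k, v in ad.tree_flatten(opt_state["v"]).items()})
    meta = {
        "step": int(step),
        "opt_count": int(opt_state["count"]),
        "model_cfg": asdict(model_cfg),
        "train_cfg": asdict(train_cfg),
        "extra": extra or {},
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> dict:
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads(bytes(arrays.pop("meta_json")).decode())
    params = ad.tree_unflatten(
        {k[len("params/"):]: v for k, v in arrays.items() if k.startswith("params/")})
    m = ad.tree_unflatten(
        {k[len("opt/m/"):]: v for k, v in arrays.items() if k.startswith("opt/m/")})
    v = ad.tree_unflatten(
        {k[len("opt/v/"):]: v for k, v in arrays.items() if k.startswith("opt/v/")})
    return {
        "params": params,
        "opt_state": {"m": m, "v": v, "count": meta["opt_count"]},
        "step": meta["step"],
        "model_cfg": ModelConfig(**meta["model_cfg"]),
        "train_cfg": TrainConfig(**meta["train_cfg"]),
        "extra": meta.get("extra", {}),
    }
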