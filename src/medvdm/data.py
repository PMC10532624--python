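"""Image I/O, preprocessing, and the synthetic chest-phantom generator.

Real inputs are folders of 8-bit grayscale PNGs, preprocessed by bilinear
resize to a square resolution and scaling to [0, 1]; no augmentation is
applied.  The phantom generator emulates the statistical shape of a
frontal chest radiograph — a smooth vertical background gradient, two
bright elliptical lung fields with seeded position/shape jitter, darker
periodic rib-like bands crossing the lungs, and additive Gaussian sensor
noise — so the whole pipeline can be exercised without any external
dataset.  Phantoms are synthetic stand-ins, not anatomically faithful
renderings.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.special import expit

__all__ = ["ImageBatch", "PhantomConfig", "load_images", "save_images",
           "generate_phantoms"]


@dataclass
class ImageBatch:
    """Grayscale images (B, H, W) in [0, 1] with per-image provenance tags."""

    intensities: np.ndarray
    source_tags: list

    def __post_init__(self):
        a = np.asarray(self.intensities, dtype=float)
        if a.ndim != 3:
            raise ValueError("intensities must be (B, H, W)")
        if a.size and (a.min() < 0.0 or a.max() > 1.0):
            raise ValueError("intensities must lie in [0, 1]")
        if len(self.source_tags) != a.shape[0]:
            raise ValueError("one source tag per image required")
        self.intensities = a

    def __len__(self):
        return self.intensities.shape[0]


@dataclass(frozen=True)
class PhantomConfig:
    """Chest-phantom generator settings.

    Defaults: 1341 images (matching the size of the training corpus the model
    targets), 7 rib bands, sensor noise sd 0.02 in intensity units, and ±10%
    jitter of lung position and ellipticity.
    """

    image_size: int = 256
    n_images: int = 1341
    seed: int = 0
    rib_count: int = 7
    noise_sd: float = 0.02
    lung_ellipticity: float = 0.1

    def __post_init__(self):
        if self.image_size < 2 or self.n_images < 1:
            raise ValueError("image_size and n_images must be positive")
        if self.noise_sd < 0 or self.lung_ellipticity < 0:
            raise ValueError("noise_sd and lung_ellipticity must be nonnegative")
        if self.rib_count < 0:
            raise ValueError("rib_count must be nonnegative")


def load_images(directory, image_size: int) -> ImageBatch:
    """Read every PNG in ``directory`` as grayscale, resize, scale to [0, 1].

    RGB inputs are converted by luminance weighting; resizing is bilinear;
    intensities are divided by 255.  No augmentation is applied.
    """
    directory = Path(directory)
    paths = sorted(directory.glob("*.png"))
    if not paths:
        raise ValueError(f"no PNG files found in {directory}")
    images, tags = [], []
    for p in paths:
        try:
            with Image.open(p) as im:
                im = im.convert("L").resize((image_size, image_size), Image.BILINEAR)
                images.append(np.asarray(im, dtype=float) / 255.0)
        except Exception as exc:
            raise OSError(f"could not read image {p}: {exc}") from exc
        tags.append(str(p.name))
    return ImageBatch(intensities=np.stack(images), source_tags=tags)


def save_images(batch: ImageBatch | np.ndarray, directory, prefix: str = "img",
                manifest: bool = True) -> list:
    """Write images as 8-bit grayscale PNGs plus a manifest CSV; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(batch, np.ndarray):
        batch = ImageBatch(batch, [f"{prefix}_{i:04d}" for i in range(batch.shape[0])])
    paths = []
    for i, img in enumerate(batch.intensities):
        arr = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
        p = directory / f"{prefix}_{i:04d}.png"
        Image.fromarray(arr, mode="L").save(p)
        paths.append(p)
    if manifest:
        with open(directory / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["filename", "source"])
            for p, tag in zip(paths, batch.source_tags):
                writer.writerow([p.name, tag])
    return paths


def _soft_ellipse(yy, xx, cy, cx, ry, rx, softness=0.06):
    """Smooth [0, 1] mask of an ellipse; logistic falloff at the boundary."""
    r2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    return expit((1.0 - r2) / softness)


def _one_phantom(size: int, cfg: PhantomConfig, rng: np.random.Generator):
    yy, xx = np.meshgrid(np.linspace(0, 1, size), np.linspace(0, 1, size),
                         indexing="ij")
    # smooth background: darker at the top, brighter toward the abdomen
    base = 0.22 + 0.16 * yy + 0.04 * np.sin(np.pi * xx)
    jit = lambda w: rng.uniform(-w, w)
    e = cfg.lung_ellipticity
    lungs = np.zeros_like(base)
    for cx0 in (0.33, 0.67):
        cy = 0.45 + jit(0.05)
        cx = cx0 + jit(0.04)
        ry = 0.28 * (1 + jit(e))
        rx = 0.14 * (1 + jit(e))
        lungs = np.maximum(lungs, _soft_ellipse(yy, xx, cy, cx, ry, rx))
    img = base + 0.45 * lungs
    if cfg.rib_count > 0:
        phase = rng.uniform(0, 2 * np.pi)
        bands = np.clip(np.sin(2 * np.pi * cfg.rib_count * yy + phase), 0.0, 1.0) ** 2
        img = img - 0.12 * bands * lungs
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    clipped = np.count_nonzero((img < 0.0) | (img > 1.0))
    return np.clip(img, 0.0, 1.0), lungs > 0.5, clipped


def generate_phantoms(cfg: PhantomConfig, with_masks: bool = False):
    """Seeded batch of synthetic chest phantoms.

    Returns an :class:`ImageBatch`; with ``with_masks`` also returns the
    boolean lung-field masks used during composition (useful for checks of
    lung/background contrast).  Bit-identical for a fixed config.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC4E57]))
    images, masks, n_clipped = [], [], 0
    for i in range(cfg.n_images):
        img, mask, clipped = _one_phantom(cfg.image_size, cfg, rng)
        images.append(img)
        masks.append(mask)
        n_clipped += clipped
    batch = ImageBatch(intensities=np.stack(images),
                       source_tags=[f"phantom:{cfg.seed}:{i}" for i in range(cfg.n_images)])
    if with_masks:
        return batch, np.stack(masks)
    return batch
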