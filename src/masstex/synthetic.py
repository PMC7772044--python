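"""Synthetic grayscale texture patches with class-dependent oriented micro-texture.

Mammographic mass patches arrive at arbitrary imaging angles, so a texture
representation for them must be insensitive to global rotation while staying
sensitive to the micro-texture statistics that separate benign-looking from
malignant-looking tissue.  This generator produces the minimal stimulus with
exactly that structure: each patch is the sum of

* an oriented sinusoidal grating whose frequency and contrast are class
  parameters (the oriented component whose *orientation* is nuisance),
* a Poisson-random scatter of small Gaussian blobs whose density is a class
  parameter, and
* i.i.d. Gaussian pixel noise,

clipped to ``[0, 1]``, then presented at a random global rotation according to
the configured rotation policy.  The "malignant-like" class (label 1) has
higher stripe contrast and higher blob density than the "benign-like" class
(label 0) under the default parameters.

No attempt is made to render anatomically realistic masses (spiculation,
margins, breast background); the point is a controllable oriented texture whose
rotation the downstream representation must absorb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .errors import ConfigurationError
from .preprocess import GrayImage

__all__ = [
    "ClassTexture",
    "SynthConfig",
    "BENIGN_LIKE",
    "MALIGNANT_LIKE",
    "generate_dataset",
    "write_dataset",
]

ROTATION_POLICIES = ("none", "multiples_of_90", "uniform_0_360")


@dataclass(frozen=True)
class ClassTexture:
    """Texture descriptor for one class.

    stripe_freq
        Dominant grating frequency, cycles/pixel.
    stripe_contrast
        Peak-to-midline grating amplitude relative to full scale, in [0, 1].
    blob_density
        Expected number of Gaussian blobs per 10^4 pixels.
    noise_std
        Standard deviation of additive Gaussian pixel noise (intensity units).
    """

    stripe_freq: float
    stripe_contrast: float
    blob_density: float
    noise_std: float


#: Default class conditions: the label-1 class has both higher stripe contrast
#: and higher blob density, i.e. a "busier" oriented micro-texture.
BENIGN_LIKE = ClassTexture(stripe_freq=0.12, stripe_contrast=0.22,
                           blob_density=1.0, noise_std=0.04)
MALIGNANT_LIKE = ClassTexture(stripe_freq=0.18, stripe_contrast=0.45,
                              blob_density=3.5, noise_std=0.04)


@dataclass(frozen=True)
class SynthConfig:
    """Full description of a synthetic dataset draw (seeded, reproducible)."""

    n_per_class: int
    patch_size: int = 300
    class_params: tuple[ClassTexture, ClassTexture] = (BENIGN_LIKE, MALIGNANT_LIKE)
    rotation_policy: str = "uniform_0_360"
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise ConfigurationError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if self.patch_size < 32:
            raise ConfigurationError(f"patch_size must be >= 32, got {self.patch_size}")
        if self.rotation_policy not in ROTATION_POLICIES:
            raise ConfigurationError(
                f"rotation_policy must be one of {ROTATION_POLICIES}, "
                f"got {self.rotation_policy!r}"
            )
        if len(self.class_params) != 2:
            raise ConfigurationError("class_params must hold exactly two descriptors")


def _render_base(rng: np.random.Generator, size: int, p: ClassTexture) -> np.ndarray:
    """Unrotated texture on a size x size canvas (not yet clipped)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    img = 0.5 + 0.5 * p.stripe_contrast * np.sin(2.0 * np.pi * p.stripe_freq * xx + phase)

    n_blobs = rng.poisson(p.blob_density * size * size / 1.0e4)
    for _ in range(n_blobs):
        cy = rng.uniform(0, size)
        cx = rng.uniform(0, size)
        sigma = rng.uniform(2.0, 4.0)
        amp = rng.uniform(0.15, 0.35)
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        img += amp * np.exp(-r2 / (2.0 * sigma * sigma))

    img += rng.normal(0.0, p.noise_std, size=(size, size))
    return img


def _draw_angle(rng: np.random.Generator, policy: str) -> float:
    if policy == "none":
        return 0.0
    if policy == "multiples_of_90":
        return float(90 * rng.integers(0, 4))
    return float(rng.uniform(0.0, 360.0))


def _make_patch(rng: np.random.Generator, size: int, p: ClassTexture,
                angle: float) -> np.ndarray:
    if angle == 0.0:
        img = _render_base(rng, size, p)
    elif angle % 90.0 == 0.0:
        # exact grid rotation: no resampling artifacts
        img = np.rot90(_render_base(rng, size, p), k=int(angle // 90) % 4)
    else:
        # render on an enlarged canvas, rotate by bilinear resampling with
        # reflect padding, then crop centrally so no border artifact leaks
        # rotation information into the patch
        canvas = int(math.ceil(size * math.sqrt(2.0))) + 4
        big = _render_base(rng, canvas, p)
        rot = ndimage.rotate(big, angle, reshape=False, order=1, mode="reflect")
        lo = (canvas - size) // 2
        img = rot[lo:lo + size, lo:lo + size]
    return np.clip(img, 0.0, 1.0)


def generate_dataset(cfg: SynthConfig) -> tuple[list[GrayImage], np.ndarray]:
    """Generate ``2 * n_per_class`` labeled patches (class 0 first, then class 1).

    Deterministic: an identical :class:`SynthConfig` (including seed) produces
    byte-identical pixel arrays, labels and rotation metadata.  Each image's
    ``meta`` records its label, applied ``rotation_deg``, dataset seed and index.
    """
    cfg.validate()
    streams = np.random.SeedSequence(cfg.seed).spawn(2 * cfg.n_per_class)
    images: list[GrayImage] = []
    labels = np.repeat([0, 1], cfg.n_per_class)
    for idx, label in enumerate(labels):
        rng = np.random.default_rng(streams[idx])
        angle = _draw_angle(rng, cfg.rotation_policy)
        pixels = _make_patch(rng, cfg.patch_size, cfg.class_params[label], angle)
        images.append(GrayImage(
            pixels=pixels,
            meta={"label": int(label), "rotation_deg": angle,
                  "seed": cfg.seed, "index": idx,
                  "source_id": f"synth_{cfg.seed}_{idx}"},
        ))
    return images, labels


def write_dataset(images: list[GrayImage], labels: np.ndarray,
                  outdir: str | Path) -> Path:
    """Write patches as 16-bit PNGs plus a CSV manifest; returns the manifest path.

    Manifest columns: ``path,label,rotation_deg,seed,source_id``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, label) in enumerate(zip(images, labels)):
        path = outdir / f"patch_{i:05d}.png"
        arr = np.round(img.pixels * 65535.0).astype(np.uint16)
        Image.fromarray(arr).save(path)
        rows.append({
            "path": str(path),
            "label": int(label),
            "rotation_deg": img.meta.get("rotation_deg", 0.0),
            "seed": img.meta.get("seed", -1),
            "source_id": img.meta.get("source_id", f"img_{i}"),
        })
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
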