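"""Patch loading, contrast equalization, augmentation and split handling.

Mass patches are assumed pre-extracted and centered (no detection here).  The
stages mirror standard mammography-patch preprocessing: rescale intensities to
[0, 1], contrast-limited adaptive histogram equalization (CLAHE), dihedral
augmentation (the four 90-degree rotations, optionally each mirrored), and a
stratified, group-aware 60/10/30 train/validation/test split in which all
augmented copies of one source patch land in the same partition, so augmented
near-duplicates can never leak across the split boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import exposure

from .errors import ConfigurationError, SizeError

__all__ = [
    "GrayImage",
    "SplitSpec",
    "load_patch",
    "equalize",
    "augment",
    "split_dataset",
]


@dataclass
class GrayImage:
    """A 2-D grayscale intensity patch in [0, 1] with free-form metadata."""

    pixels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise SizeError(f"GrayImage requires a 2-D array, got shape {self.pixels.shape}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class SplitSpec:
    """Proportions and policy for a train/val/test split."""

    train_frac: float = 0.6
    val_frac: float = 0.1
    test_frac: float = 0.3
    stratified: bool = True
    seed: int = 0

    def validate(self) -> None:
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"split fractions must sum to 1, got {total}")
        if min(self.train_frac, self.val_frac, self.test_frac) < 0:
            raise ConfigurationError("split fractions must be nonnegative")


def load_patch(path: str | Path, target_size: int) -> GrayImage:
    """Load an image file as a [0, 1] grayscale patch of ``target_size`` square.

    Multi-channel inputs are collapsed by the unweighted channel mean (any
    color in a mammography patch is replication).  Integer images are scaled
    by their dtype's full range.  Larger images are center-cropped to
    ``target_size``; smaller ones are rejected with :class:`SizeError`.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            src = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc

    arr = src.astype(np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise SizeError(f"patch {path}: expected 2-D or RGB image, got shape {src.shape}")
    # scale by the container dtype's range; float inputs are clipped
    if np.issubdtype(src.dtype, np.integer):
        arr = arr / float(np.iinfo(src.dtype).max)
    arr = np.clip(arr, 0.0, 1.0)

    h, w = arr.shape
    if h < target_size or w < target_size:
        raise SizeError(
            f"patch {path} is {h}x{w}, smaller than target {target_size}"
        )
    top = (h - target_size) // 2
    left = (w - target_size) // 2
    arr = arr[top:top + target_size, left:left + target_size]
    return GrayImage(pixels=arr, meta={"path": str(path)})


def equalize(img: GrayImage, clip_limit: float = 0.02,
             tile_grid: tuple[int, int] = (8, 8)) -> GrayImage:
    """Contrast-limited adaptive histogram equalization (CLAHE), output in [0, 1].

    A constant image is returned unchanged (its histogram is degenerate; there
    is no contrast to equalize).
    """
    if clip_limit <= 0:
        raise ConfigurationError(f"clip_limit must be positive, got {clip_limit}")
    px = img.pixels
    if np.ptp(px) == 0.0:
        return GrayImage(pixels=px.copy(), meta=dict(img.meta))
    kernel = (max(1, px.shape[0] // tile_grid[0]), max(1, px.shape[1] // tile_grid[1]))
    out = exposure.equalize_adapthist(np.clip(px, 0, 1), kernel_size=kernel,
                                      clip_limit=clip_limit)
    return GrayImage(pixels=np.clip(out, 0.0, 1.0), meta=dict(img.meta))


_ROT_TAGS = ("rot0", "rot90", "rot180", "rot270")


def augment(img: GrayImage, mode: str = "rot4_flip") -> list[GrayImage]:
    """Dihedral augmentation of a square patch.

    ``rot4``: the four 90-degree rotations (4 images).  ``rot4_flip``: those
    four, then each flipped left-right (8 images).  Every output carries a
    distinct ``augmentation`` tag and inherits the source's metadata.
    """
    if mode not in ("rot4", "rot4_flip"):
        raise ConfigurationError(f"unknown augmentation mode {mode!r}")
    if img.height != img.width:
        raise SizeError(f"augmentation requires a square image, got {img.height}x{img.width}")
    out: list[GrayImage] = []
    rots = [np.rot90(img.pixels, k) for k in range(4)]
    for tag, px in zip(_ROT_TAGS, rots):
        out.append(GrayImage(pixels=px.copy(), meta={**img.meta, "augmentation": tag}))
    if mode == "rot4_flip":
        for tag, px in zip(_ROT_TAGS, rots):
            out.append(GrayImage(pixels=np.fliplr(px).copy(),
                                 meta={**img.meta, "augmentation": tag + "_flip"}))
    return out


def _allocate(n: int, fracs: tuple[float, float, float]) -> list[int]:
    """Integer partition of n by largest-remainder so counts sum exactly to n."""
    raw = [f * n for f in fracs]
    base = [int(np.floor(r)) for r in raw]
    rem = n - sum(base)
    order = np.argsort([-(r - b) for r, b in zip(raw, base)], kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    return base


def split_dataset(manifest: pd.DataFrame, spec: SplitSpec
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Group-aware stratified train/val/test split of a labeled manifest.

    The manifest needs ``label`` and (optionally) ``source_id`` columns; rows
    sharing a ``source_id`` (augmented copies of one patch) are assigned to a
    single partition.  Stratification operates on sources within each class.
    Deterministic given ``spec.seed``.
    """
    spec.validate()
    if len(manifest) < 10:
        raise ConfigurationError("manifest must contain at least 10 rows")
    if "label" not in manifest.columns:
        raise ConfigurationError("manifest must have a 'label' column")
    df = manifest.copy()
    if "source_id" not in df.columns:
        df = df.assign(source_id=[f"row_{i}" for i in range(len(df))])
    classes = df["label"].unique()
    if len(classes) < 2:
        raise ConfigurationError("manifest must contain two classes")

    rng = np.random.default_rng(spec.seed)
    fracs = (spec.train_frac, spec.val_frac, spec.test_frac)
    assignment: dict[str, int] = {}

    sources = df.drop_duplicates("source_id")[["source_id", "label"]]
    if spec.stratified:
        groups = [sources[sources["label"] == c] for c in sorted(classes)]
    else:
        groups = [sources]
    for grp in groups:
        ids = grp["source_id"].to_numpy()
        ids = ids[rng.permutation(len(ids))]
        counts = _allocate(len(ids), fracs)
        bounds = np.cumsum([0] + counts)
        for part in range(3):
            for sid in ids[bounds[part]:bounds[part + 1]]:
                assignment[sid] = part

    part_col = df["source_id"].map(assignment)
    return tuple(df[part_col == p].reset_index(drop=True) for p in range(3))
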