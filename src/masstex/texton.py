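"""Rotation-invariant uniform LBP histograms of MR8 responses: the texton block.

For each pixel of a response map, the local binary pattern samples P points on
a circle of radius R (bilinear interpolation, angle origin at the positive
x-axis, counter-clockwise) and thresholds them against the center:
s(x) = 1 if x >= 0 else 0 applied to (neighbor - center).  If the circular
bit string has at most 2 bitwise 0<->1 transitions (a "uniform" pattern) the
code is its number of set bits, in {0..P}; all other patterns share the single
non-uniform code P+1.  Because a rotation of the neighborhood only rotates the
bit string, and uniform codes depend solely on the bit count, the riu2 code —
and therefore its histogram over a map — is rotation-invariant.

With the default two rings (P=8, R=1) and (P=24, R=3), each response map
yields a (8+2) + (24+2) = 36-bin histogram, and concatenating the 8 MR8
channels gives the 288-dimensional texton feature vector per image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .block import FeatureBlock
from .errors import SizeError
from .mr8 import FilterBank, Mr8ResponseStack, apply_mr8
from .preprocess import GrayImage

__all__ = [
    "LbpConfig",
    "lbp_riu2_code",
    "lbp_code_map",
    "lbp_histogram",
    "texton_features",
    "extract_texton_block",
]


@dataclass(frozen=True)
class LbpConfig:
    """Sampling rings (P neighbors at radius R) and the riu2 uniformity cutoff."""

    rings: tuple[tuple[int, float], ...] = ((8, 1.0), (24, 3.0))
    uniformity_threshold: int = 2

    @property
    def histogram_length(self) -> int:
        """Total bins per response map: sum of P+2 over rings (36 by default)."""
        return sum(p + 2 for p, _ in self.rings)

    @property
    def max_radius(self) -> float:
        return max(r for _, r in self.rings)


def lbp_riu2_code(neighbors, center: float, uniformity_threshold: int = 2) -> int:
    """riu2 code of one sampled neighborhood (total function; see module doc)."""
    s = (np.asarray(neighbors, dtype=np.float64) >= center).astype(np.int64)
    u = int(np.sum(s != np.roll(s, 1)))
    p = s.size
    return int(s.sum()) if u <= uniformity_threshold else p + 1


def _ring_offsets(p: int, r: float) -> tuple[np.ndarray, np.ndarray]:
    # image convention: row offset -R*sin(angle), column offset R*cos(angle)
    angles = 2.0 * np.pi * np.arange(p) / p
    return -r * np.sin(angles), r * np.cos(angles)


def lbp_code_map(response_map: np.ndarray, p: int, r: float,
                 uniformity_threshold: int = 2) -> np.ndarray:
    """riu2 code at every pixel of a map (vectorized over the image).

    Codes at pixels closer than ceil(r) to the border rely on clamped samples
    and should be excluded by the caller (``lbp_histogram`` does).  The
    neighbor-vs-center comparison allows a tiny negative slack so that exact
    ties keep s(0) = 1 despite bilinear-interpolation rounding (a constant
    map codes as the all-ones pattern on every ring).
    """
    arr = np.asarray(response_map, dtype=np.float64)
    h, w = arr.shape
    need = 2 * int(np.ceil(r)) + 1
    if h <= need or w <= need:
        raise SizeError(f"map {arr.shape} too small for LBP radius {r}")
    dr, dc = _ring_offsets(p, r)
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    coords = np.stack([
        (rows[None] + dr[:, None, None]).ravel(),
        (cols[None] + dc[:, None, None]).ravel(),
    ])
    neigh = ndimage.map_coordinates(arr, coords, order=1, mode="nearest")
    eps = 1e-9 * np.ptp(arr) + 1e-12
    s = neigh.reshape(p, h, w) >= arr[None] - eps
    u = (s != np.roll(s, 1, axis=0)).sum(axis=0)
    return np.where(u <= uniformity_threshold, s.sum(axis=0), p + 1)


def lbp_histogram(response_map: np.ndarray, cfg: LbpConfig | None = None) -> np.ndarray:
    """Normalized riu2 histogram of one response map (length 36 by default).

    Pixels within ``max_radius`` of any edge are excluded from every ring, so
    all rings are counted over the same interior region; the concatenated
    histogram is normalized to sum to 1.
    """
    cfg = cfg or LbpConfig()
    margin = int(np.ceil(cfg.max_radius))
    parts = []
    for p, r in cfg.rings:
        codes = lbp_code_map(response_map, p, r, cfg.uniformity_threshold)
        interior = codes[margin:-margin, margin:-margin]
        parts.append(np.bincount(interior.ravel(), minlength=p + 2).astype(np.float64))
    hist = np.concatenate(parts)
    return hist / hist.sum()


def _column_names(cfg: LbpConfig, channel_names: tuple[str, ...]) -> list[str]:
    names = []
    for c, _ in enumerate(channel_names):
        b = 0
        for p, _r in cfg.rings:
            for _ in range(p + 2):
                names.append(f"mr8_c{c}_b{b}")
                b += 1
    return names


def texton_features(img: GrayImage | np.ndarray, bank: FilterBank,
                    cfg: LbpConfig | None = None, *,
                    stack: Mr8ResponseStack | None = None) -> np.ndarray:
    """The texton vector of one image: concatenated per-channel LBP histograms.

    288-dimensional under the default bank (8 channels) and rings (36 bins).
    A precomputed response ``stack`` may be passed to avoid re-filtering.
    """
    cfg = cfg or LbpConfig()
    if stack is None:
        stack = apply_mr8(img, bank)
    return np.concatenate([lbp_histogram(ch, cfg) for ch in stack.responses])


def extract_texton_block(imgs: list[GrayImage], bank: FilterBank,
                         cfg: LbpConfig | None = None) -> FeatureBlock:
    """Texton vectors for a list of images as a named FeatureBlock."""
    cfg = cfg or LbpConfig()
    vectors = [texton_features(img, bank, cfg) for img in imgs]
    n_channels = 2 * bank.oriented.shape[1] + 2
    names = _column_names(cfg, tuple(f"c{i}" for i in range(n_channels)))
    return FeatureBlock(name="texton", values=np.vstack(vectors), columns=names)
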