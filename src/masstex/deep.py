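"""Deep-representation feature block behind a pluggable extractor contract.

The pipeline only requires that some extractor turn each grayscale patch into
a fixed-length vector (1024-dimensional by default, matching the penultimate
global-pooling layer of common ImageNet backbones).  Users with a pretrained
network plug it in via :func:`register_backend` (a callable) or the
external-command protocol (a program that reads a manifest CSV and writes a
feature CSV with ``deep_0..deep_{D-1}`` columns).

The built-in ``default_light`` backend is a small fixed random-convolution
network: grayscale replicated to 3 channels, three conv(3x3)+ReLU+avgpool
stages with frozen He-scaled random weights, global average pooling, and a
frozen random linear projection to ``output_dim``.  It trains nothing, needs
no download, and is fully deterministic, yet produces a realistic
high-dimensional, weakly informative feature block for exercising the fusion
and selection machinery.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .block import FeatureBlock
from .errors import ConfigurationError, ContractViolationError
from .preprocess import GrayImage

__all__ = [
    "DeepExtractorSpec",
    "extract_deep",
    "register_backend",
    "run_external_extractor",
]

# Frozen weight seed for the default backend: features are reproducible across
# processes and runs by construction, independent of any experiment seed.
_WEIGHT_SEED = 731_261_993

_STAGE_WIDTHS = (3, 8, 16, 32)

_REGISTRY: dict[str, object] = {}


@dataclass(frozen=True)
class DeepExtractorSpec:
    """Identity and contract of a deep extractor.

    ``output_dim`` is fixed for the life of a run; every image must map to a
    vector of exactly that length.  Grayscale inputs are replicated across 3
    channels (``channel_policy``) and resized to ``input_size`` square.
    """

    name: str = "default_light"
    output_dim: int = 1024
    input_size: int = 64
    channel_policy: str = "replicate-grayscale-to-3"
    backend: str = "default_light"

    def validate(self) -> None:
        if self.output_dim < 1:
            raise ConfigurationError("output_dim must be >= 1")
        if self.input_size < 8:
            raise ConfigurationError("input_size must be >= 8")


def register_backend(name: str, fn) -> None:
    """Register a callable backend: fn(images_3chw: list[np.ndarray], spec) -> (n, D) array."""
    _REGISTRY[name] = fn


@lru_cache(maxsize=4)
def _light_weights(input_size: int, output_dim: int):
    rng = np.random.default_rng(_WEIGHT_SEED)
    stages = []
    for cin, cout in zip(_STAGE_WIDTHS[:-1], _STAGE_WIDTHS[1:]):
        w = rng.normal(0.0, np.sqrt(2.0 / (cin * 9)), size=(cout, cin, 3, 3))
        b = rng.normal(0.0, 0.01, size=cout)
        stages.append((w, b))
    proj = rng.normal(0.0, 1.0 / np.sqrt(_STAGE_WIDTHS[-1]),
                      size=(_STAGE_WIDTHS[-1], output_dim))
    proj_b = rng.normal(0.0, 0.01, size=output_dim)
    return stages, proj, proj_b


def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """3x3 'same' convolution, reflect padded: x (C,H,W), w (O,C,3,3) -> (O,H,W)."""
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)), mode="reflect")
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (C,H,W,3,3)
    return np.einsum("chwij,ocij->ohw", win, w, optimize=True)


def _avgpool2(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    return x[:, : h // 2 * 2, : w // 2 * 2].reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))


def _light_forward(img3: np.ndarray, spec: DeepExtractorSpec) -> np.ndarray:
    stages, proj, proj_b = _light_weights(spec.input_size, spec.output_dim)
    x = img3
    for w, b in stages:
        x = np.maximum(_conv_same(x, w) + b[:, None, None], 0.0)
        x = _avgpool2(x)
    pooled = x.mean(axis=(1, 2))  # global average pooling
    return pooled @ proj + proj_b


def _prepare(img: GrayImage | np.ndarray, spec: DeepExtractorSpec) -> np.ndarray:
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=np.float64)
    if px.shape != (spec.input_size, spec.input_size):
        px = resize(px, (spec.input_size, spec.input_size),
                    order=1, anti_aliasing=True)
    return np.stack([px, px, px])  # replicate grayscale across 3 channels


def extract_deep(imgs: list[GrayImage], spec: DeepExtractorSpec | None = None
                 ) -> FeatureBlock:
    """One ``output_dim`` vector per image, as a FeatureBlock named 'deep'.

    Deterministic given the spec and inputs; a registered backend returning
    the wrong shape raises :class:`ContractViolationError`.
    """
    spec = spec or DeepExtractorSpec()
    spec.validate()
    prepared = [_prepare(img, spec) for img in imgs]
    if spec.backend == "default_light":
        values = np.vstack([_light_forward(x, spec) for x in prepared])
    elif spec.backend in _REGISTRY:
        values = np.asarray(_REGISTRY[spec.backend](prepared, spec), dtype=np.float64)
    else:
        raise ConfigurationError(
            f"unknown deep backend {spec.backend!r}; register it first")
    if values.shape != (len(imgs), spec.output_dim):
        raise ContractViolationError(
            f"backend {spec.backend!r} returned shape {values.shape}, "
            f"expected {(len(imgs), spec.output_dim)}")
    return FeatureBlock(name="deep", values=values,
                        columns=[f"deep_{i}" for i in range(spec.output_dim)])


def run_external_extractor(command: list[str], manifest_csv: str | Path,
                           out_csv: str | Path, output_dim: int) -> FeatureBlock:
    """External-command backend: run ``command MANIFEST OUT`` and load the result.

    The command must write a CSV with columns ``deep_0..deep_{D-1}`` and one
    row per manifest row.
    """
    subprocess.run([*command, str(manifest_csv), str(out_csv)], check=True)
    frame = pd.read_csv(out_csv)
    expected = [f"deep_{i}" for i in range(output_dim)]
    if list(frame.columns) != expected:
        raise ContractViolationError(
            f"external extractor wrote columns {list(frame.columns)[:4]}..., "
            f"expected deep_0..deep_{output_dim - 1}")
    return FeatureBlock(name="deep", values=frame.to_numpy(dtype=np.float64),
                        columns=expected)
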