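"""Maximum-response (MR8) filter bank: 38 filters collapsed to 8 response maps.

The bank holds 36 anisotropic kernels — an edge (first-derivative-of-Gaussian)
and a bar (second-derivative-of-Gaussian) filter, each at 3 scales and 6
orientations — plus 2 isotropic kernels, a Gaussian and a Laplacian of
Gaussian (LOG).  For a Gaussian kernel G the oriented filters at angle theta
are the directional derivatives

    G'  = G_x cos(theta) + G_y sin(theta)
    G'' = G_xx cos^2(theta) + G_yy sin^2(theta) - 2 G_xy cos(theta) sin(theta)

and the LOG is the rotation-invariant ``G_xx + G_yy``.  Convolving an image
with all 38 kernels and keeping, per oriented filter type and scale, only the
maximum response over the 6 orientations collapses the 38 responses to 8.
Recording *which* orientation won is discarded, which is exactly what makes
the representation rotation-invariant: rotating the image permutes the
orientation responses but leaves their pointwise maximum (on the interior)
unchanged.

Default geometry follows the standard maximum-response bank construction:
anisotropic scales (sigma_across, sigma_along) in {(1,3), (2,6), (4,12)}
pixels, 49x49 support, isotropic sigma 10.  All kernels are zero-mean and
L1-normalized except the Gaussian, which keeps unit sum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import fft as sfft

from .errors import ConfigurationError, SizeError
from .preprocess import GrayImage

__all__ = [
    "FilterBankConfig",
    "FilterBank",
    "Mr8ResponseStack",
    "build_mr8_bank",
    "apply_mr8",
    "save_bank",
    "load_bank",
]

CHANNEL_NAMES = (
    "edge_s1", "edge_s2", "edge_s3",
    "bar_s1", "bar_s2", "bar_s3",
    "gauss", "log",
)


@dataclass(frozen=True)
class FilterBankConfig:
    """Geometry of the bank.

    ``scales`` are (sigma_across, sigma_along) pairs for the oriented kernels:
    the derivative is taken across the short axis, elongation is along the
    long axis.  ``support`` is the odd kernel side length in pixels.
    """

    scales: tuple[tuple[float, float], ...] = ((1.0, 3.0), (2.0, 6.0), (4.0, 12.0))
    n_orientations: int = 6
    support: int = 49
    gaussian_sigma: float = 10.0
    log_sigma: float = 10.0

    def validate(self) -> None:
        if self.support % 2 == 0 or self.support < 7:
            raise ConfigurationError(
                f"support must be odd and >= 7, got {self.support}")
        if self.n_orientations < 1:
            raise ConfigurationError("n_orientations must be >= 1")
        if not self.scales:
            raise ConfigurationError("at least one scale is required")

    @property
    def orientations(self) -> np.ndarray:
        """Filter angles in radians: k * pi / n_orientations, k = 0..n-1."""
        return np.arange(self.n_orientations) * np.pi / self.n_orientations


@dataclass
class FilterBank:
    """The realized kernels.

    ``oriented`` has shape ``(2, n_scales, n_orientations, support, support)``
    with index 0 = edge (first derivative), 1 = bar (second derivative).
    """

    oriented: np.ndarray
    gaussian: np.ndarray
    log: np.ndarray
    config: FilterBankConfig = field(default_factory=FilterBankConfig)

    @property
    def n_anisotropic(self) -> int:
        return int(np.prod(self.oriented.shape[:3]))

    @property
    def n_kernels(self) -> int:
        return self.n_anisotropic + 2

    @property
    def support(self) -> int:
        return self.oriented.shape[-1]

    def all_kernels(self) -> list[np.ndarray]:
        """Every kernel in a flat, deterministic order (oriented first)."""
        flat = [self.oriented[d, s, o]
                for d in range(self.oriented.shape[0])
                for s in range(self.oriented.shape[1])
                for o in range(self.oriented.shape[2])]
        return flat + [self.gaussian, self.log]


@dataclass
class Mr8ResponseStack:
    """The 8 per-pixel maximum-response maps of one image.

    Channel order: edge at scales 1..3, bar at scales 1..3, Gaussian, LOG.
    For a non-default number of scales the pattern generalizes and
    ``channel_names`` records the semantics.
    """

    responses: np.ndarray  # (n_channels, H, W)
    channel_names: tuple[str, ...]

    @property
    def n_channels(self) -> int:
        return self.responses.shape[0]


def _grid(support: int) -> tuple[np.ndarray, np.ndarray]:
    half = support // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float64)
    return y, x


def _normalize(kernel: np.ndarray) -> np.ndarray:
    kernel = kernel - kernel.mean()
    scale = np.abs(kernel).sum()
    return kernel / scale if scale > 0 else kernel


def oriented_kernel(order: int, sigma_across: float, sigma_along: float,
                    theta: float, support: int) -> np.ndarray:
    """Edge (order=1) or bar (order=2) kernel at angle ``theta``.

    Built analytically in rotated coordinates, so the kernel at theta is the
    exact theta-rotation of the base (theta=0) kernel; for 90-degree steps the
    sampled grids coincide to floating-point precision.
    """
    y, x = _grid(support)
    # u: along the elongated axis; v: across it (derivative direction)
    u = x * np.cos(theta) + y * np.sin(theta)
    v = -x * np.sin(theta) + y * np.cos(theta)
    g_along = np.exp(-u ** 2 / (2.0 * sigma_along ** 2))
    e = np.exp(-v ** 2 / (2.0 * sigma_across ** 2))
    if order == 1:
        g_across = -(v / sigma_across ** 2) * e
    elif order == 2:
        g_across = (v ** 2 / sigma_across ** 4 - 1.0 / sigma_across ** 2) * e
    else:
        raise ConfigurationError(f"derivative order must be 1 or 2, got {order}")
    return _normalize(g_along * g_across)


def isotropic_kernels(gaussian_sigma: float, log_sigma: float,
                      support: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit-sum Gaussian and zero-mean L1-normalized LOG kernels."""
    y, x = _grid(support)
    r2 = x ** 2 + y ** 2
    gauss = np.exp(-r2 / (2.0 * gaussian_sigma ** 2))
    gauss = gauss / gauss.sum()
    s2 = log_sigma ** 2
    log = (r2 / (s2 * s2) - 2.0 / s2) * np.exp(-r2 / (2.0 * s2))
    return gauss, _normalize(log)


def build_mr8_bank(cfg: FilterBankConfig | None = None) -> FilterBank:
    """Construct the bank; default config yields 2*3*6 + 2 = 38 kernels."""
    cfg = cfg or FilterBankConfig()
    cfg.validate()
    thetas = cfg.orientations
    oriented = np.empty((2, len(cfg.scales), cfg.n_orientations,
                         cfg.support, cfg.support))
    for d, order in enumerate((1, 2)):
        for s, (sx, sy) in enumerate(cfg.scales):
            for o, theta in enumerate(thetas):
                oriented[d, s, o] = oriented_kernel(order, sx, sy, theta, cfg.support)
    gauss, log = isotropic_kernels(cfg.gaussian_sigma, cfg.log_sigma, cfg.support)
    return FilterBank(oriented=oriented, gaussian=gauss, log=log, config=cfg)


def _correlate_bank(image: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Correlate one reflect-padded image with a stack of kernels via FFT.

    ``kernels`` has shape (..., sup, sup); returns responses of the original
    (unpadded) image size per kernel.  Correlation (not convolution) so the
    kernel's orientation semantics are preserved as constructed.
    """
    sup = kernels.shape[-1]
    pad = sup // 2
    padded = np.pad(image, pad, mode="reflect")
    fshape = [sfft.next_fast_len(padded.shape[0] + sup - 1),
              sfft.next_fast_len(padded.shape[1] + sup - 1)]
    fimg = sfft.rfftn(padded, fshape)
    flipped = kernels[..., ::-1, ::-1]
    out = np.empty(kernels.shape[:-2] + image.shape)
    start = sup - 1
    for idx in np.ndindex(kernels.shape[:-2]):
        fker = sfft.rfftn(flipped[idx], fshape)
        full = sfft.irfftn(fimg * fker, fshape)
        out[idx] = full[start:start + image.shape[0], start:start + image.shape[1]]
    return out


def contrast_normalize(responses: np.ndarray, scale: float = 0.03) -> np.ndarray:
    """Weber-law contrast normalization of a response stack, per pixel.

    Each pixel's channel vector r is rescaled by
    ``log(1 + L/scale) / (L/scale)`` with ``L = ||r||_2``, the normalization
    the standard maximum-response texton construction applies.  It compresses
    the overall response magnitude (which varies with how well the discrete
    orientation sampling aligns with the local texture) while preserving the
    ratios between channels at each pixel.
    """
    l2 = np.sqrt(np.sum(responses ** 2, axis=0, keepdims=True))
    t = l2 / scale
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = np.where(t > 0, np.log1p(t) / t, 1.0)
    return responses * factor


def apply_mr8(img: GrayImage | np.ndarray, bank: FilterBank, *,
              standardize: bool = True, edge_rectify: str = "abs",
              bar_rectify: str = "signed",
              normalize_contrast: bool = True) -> Mr8ResponseStack:
    """Compute the 8 maximum-response maps of an image.

    The image is standardized to zero mean / unit variance first (responses
    then compare across patches of different brightness).  Each oriented
    channel is the pointwise maximum over orientations; the antisymmetric edge
    filter is rectified by absolute value before the maximum by default (so an
    edge's response does not flip sign under contrast inversion), the
    symmetric bar filter is taken signed.  Both behaviors are switchable via
    ``edge_rectify`` / ``bar_rectify`` in {"abs", "signed"}.  The collapsed
    stack is Weber contrast-normalized per pixel (``normalize_contrast``),
    following the standard maximum-response construction.

    Output spatial size equals the input (reflect-padded correlation).
    """
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=np.float64)
    sup = bank.support
    if px.shape[0] < sup or px.shape[1] < sup:
        raise SizeError(
            f"image {px.shape} smaller than kernel support {sup}x{sup}")
    for name, mode in (("edge_rectify", edge_rectify), ("bar_rectify", bar_rectify)):
        if mode not in ("abs", "signed"):
            raise ConfigurationError(f"{name} must be 'abs' or 'signed', got {mode!r}")
    if standardize:
        std = px.std()
        # constant (or numerically constant) images: center only
        px = (px - px.mean()) / (std if std > 1e-12 else 1.0)

    n_scales = bank.oriented.shape[1]
    raw = _correlate_bank(px, bank.oriented)  # (2, S, O, H, W)
    channels = []
    names = []
    for d, mode, tag in ((0, edge_rectify, "edge"), (1, bar_rectify, "bar")):
        resp = np.abs(raw[d]) if mode == "abs" else raw[d]
        for s in range(n_scales):
            channels.append(resp[s].max(axis=0))
            names.append(f"{tag}_s{s + 1}")
    iso = _correlate_bank(px, np.stack([bank.gaussian, bank.log]))
    channels.extend([iso[0], iso[1]])
    names.extend(["gauss", "log"])
    stacked = np.stack(channels)
    if normalize_contrast:
        stacked = contrast_normalize(stacked)
    return Mr8ResponseStack(responses=stacked, channel_names=tuple(names))


def save_bank(bank: FilterBank, path: str | Path) -> None:
    """Serialize to an .npz with a JSON sidecar describing channel order."""
    path = Path(path)
    np.savez(path, oriented=bank.oriented, gaussian=bank.gaussian, log=bank.log)
    sidecar = {
        "scales": [list(s) for s in bank.config.scales],
        "n_orientations": bank.config.n_orientations,
        "support": bank.config.support,
        "gaussian_sigma": bank.config.gaussian_sigma,
        "log_sigma": bank.config.log_sigma,
        "oriented_index": "(derivative_order-1, scale, orientation)",
        "channel_order": list(CHANNEL_NAMES[:2 * len(bank.config.scales)])
        + ["gauss", "log"],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_bank(path: str | Path) -> FilterBank:
    path = Path(path)
    data = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = FilterBankConfig(
        scales=tuple(tuple(s) for s in meta["scales"]),
        n_orientations=meta["n_orientations"],
        support=meta["support"],
        gaussian_sigma=meta["gaussian_sigma"],
        log_sigma=meta["log_sigma"],
    )
    return FilterBank(oriented=data["oriented"], gaussian=data["gaussian"],
                      log=data["log"], config=cfg)
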