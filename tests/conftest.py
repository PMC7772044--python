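import numpy as np
import pytest
from hypothesis import settings

import masstex as mt

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bank():
    """Default 38-kernel MR8 bank, shared across tests (construction is cheap,
    but sharing keeps intent clear: every test sees the same defaults)."""
    return mt.build_mr8_bank()


@pytest.fixture(scope="session")
def textured_patch():
    """One 96x96 patch from the generator's malignant-like class, unrotated."""
    imgs, _ = mt.generate_dataset(
        mt.SynthConfig(n_per_class=1, patch_size=96, rotation_policy="none", seed=5))
    return imgs[1].pixels


def oriented_noisy_grating(angle_deg: float, size: int = 160, freq: float = 0.18,
                           contrast: float = 0.45, noise: float = 0.04,
                           seed: int = 0) -> np.ndarray:
    """Analytically rotated noisy grating: rotation with no resampling artifacts."""
    th = np.deg2rad(angle_deg)
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    phase = rng.uniform(0, 2 * np.pi)
    img = 0.5 + 0.5 * contrast * np.sin(
        2 * np.pi * freq * (xx * np.cos(th) + yy * np.sin(th)) + phase)
    img += rng.normal(0, noise, img.shape)
    return np.clip(img, 0, 1)
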