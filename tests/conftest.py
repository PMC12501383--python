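"""Shared fixtures: small synthetic volumes and phantom pairs."""

import numpy as np
import pytest

from emip import Band, DetectionConfig, PhantomSpec, ScanPair, Volume3D, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    return Volume3D(rng.uniform(0, 10, size=(5, 4, 6)).astype(np.float32), Band.LF)


@pytest.fixture(scope="session")
def tilted_phantom():
    """Noiseless tilted-plane phantom (surface z = 120 + 0.3 x), no hairs."""
    spec = PhantomSpec(
        surface_coefficients={(0, 0): 120.0, (1, 0): 0.3},
        n_hairs=0,
        n_vessels=6,
        noise_sd=0.0,
        seed=7,
    )
    pair, gt = generate_phantom(spec)
    return spec, pair, gt


@pytest.fixture(scope="session")
def hairy_phantom():
    """Noiseless tilted phantom with two hairs above the surface."""
    spec = PhantomSpec(
        surface_coefficients={(0, 0): 150.0, (1, 0): 0.2},
        n_hairs=2,
        n_vessels=4,
        noise_sd=0.0,
        seed=11,
    )
    pair, gt = generate_phantom(spec)
    return spec, pair, gt


@pytest.fixture(scope="session")
def detected_tilted(tilted_phantom):
    """Surface detection result on the tilted phantom (default config)."""
    import emip

    spec, pair, gt = tilted_phantom
    sfit, report = emip.detect_surface(pair, DetectionConfig(random_seed=1))
    return spec, pair, gt, sfit, report


def flat_pair(n_x=24, n_y=16, n_z=80, level=40, intensity=100.0):
    """Tiny analytic pair: a flat melanin sheet at a known depth, no randomness."""
    lf = np.zeros((n_x, n_y, n_z), dtype=np.float32)
    lf[:, :, level - 1 : level + 2] = intensity
    hf = lf.copy()
    return ScanPair(lfr=Volume3D(lf, Band.LF), hfr=Volume3D(hf, Band.HF))
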