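import numpy as np
import pytest

from rimradiomics.core import ImageVolume, RoiMask
from rimradiomics.synthetic_data import PhantomSpec, generate_phantom


def digital_sphere(radius_mm: float, spacing: float = 1.0,
                   margin: float = 3.0) -> RoiMask:
    n = int(np.ceil(2 * (radius_mm + margin) / spacing)) + 1
    c = (n - 1) / 2.0 * spacing
    ax = np.arange(n) * spacing - c
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = zz**2 + yy**2 + xx**2 <= radius_mm**2
    return RoiMask(inside.astype(np.uint8), (spacing,) * 3)


@pytest.fixture(scope="session")
def sphere_r15() -> RoiMask:
    return digital_sphere(15.0)


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic phantom (image, mask) with moderate texture."""
    return generate_phantom(PhantomSpec(seed=11), z=0.4)


@pytest.fixture(scope="session")
def small_roi_rng():
    return np.random.default_rng(42)


def toy_survival(n: int, seed: int, frac_censored: float = 0.3):
    """Simple uncorrelated survival toy data."""
    rng = np.random.default_rng(seed)
    time = rng.exponential(20.0, size=n) + 0.1
    event = (rng.uniform(size=n) > frac_censored).astype(int)
    return time, event
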