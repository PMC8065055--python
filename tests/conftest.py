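"""Shared fixtures: deterministic RNGs and small rendered phantom volumes."""

import numpy as np
import pytest

from navfuse.phantom import PhantomSpec, render_volume
from navfuse.volume import LabelMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def us_phantom(phantom_spec):
    """US-like prostate render at 1.25 mm, reused across registration tests."""
    return render_volume(phantom_spec, "us", spacing_mm=1.25, seed=100, frame="USpre")


@pytest.fixture(scope="session")
def mr_phantom(phantom_spec):
    return render_volume(phantom_spec, "mr", spacing_mm=1.0, seed=7, frame="MR")


def make_sphere_mask(center, radius, spacing, extent_mm, frame="a"):
    """Binary sphere mask on a unit-direction grid starting at the origin."""
    n = int(round(extent_mm / spacing))
    x = (np.arange(n) + 0.5) * spacing
    xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
    c = np.asarray(center, dtype=float)
    vox = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2 <= radius**2
    return LabelMask(
        voxels=vox, spacing=[spacing] * 3, origin=[spacing / 2] * 3, frame=frame
    )


@pytest.fixture(scope="session")
def offset_spheres():
    """Equal 5 mm spheres with centers 2 mm apart on a 0.2 mm grid."""
    a = make_sphere_mask((11.0, 12.0, 12.0), 5.0, 0.2, 24.0)
    b = make_sphere_mask((13.0, 12.0, 12.0), 5.0, 0.2, 24.0)
    return a, b


@pytest.fixture
def sphere_mask():
    """Factory fixture so tests need no cross-module helper imports."""
    return make_sphere_mask
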