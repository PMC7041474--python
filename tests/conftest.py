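import numpy as np
import pytest

from tgvtomo import GeometryConfig, RadonTransform


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_geo():
    """24x24x3 grid with 12 angles; cheap but not degenerate."""
    return GeometryConfig(nx=24, nz=3, n_angles=12)


@pytest.fixture(scope="session")
def small_radon(small_geo):
    return RadonTransform(small_geo)


@pytest.fixture(scope="session")
def tiny_geo():
    """Single-slice 8x8 grid with 6 angles for dense-oracle comparisons."""
    return GeometryConfig(nx=8, nz=1, n_angles=6, ns=16)


@pytest.fixture(scope="session")
def tiny_radon(tiny_geo):
    return RadonTransform(tiny_geo)
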