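import numpy as np
import pytest

from shardrecon import (
    GradientTable,
    SliceProfile,
    build_layout,
    combined_kernel,
)
from shardrecon.simulate import PhantomSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_phantom():
    """16^3 three-shell phantom shared by forward-model tests."""
    spec = PhantomSpec(
        shape=(16, 16, 16), shells=((0.0, 3), (1000.0, 10), (2600.0, 16))
    )
    dmri, grad, mask = make_phantom(spec, seed=0)
    affine = np.diag([1.5, 1.5, 1.5, 1.0])
    return dmri, grad, mask, affine, spec


@pytest.fixture(scope="session")
def small_layout(small_phantom):
    _, grad, _, _, _ = small_phantom
    return build_layout(16, 2, 2, 1, grad)


@pytest.fixture(scope="session")
def gauss_kernel():
    """Combined through-plane kernel for a 3 mm FWHM SSP on a 1.5 mm grid."""
    return combined_kernel(SliceProfile.gaussian(3.0), 1.5)


@pytest.fixture
def uniform_grad(rng):
    """Single-shell table with 24 near-uniform directions at b=1000."""
    from shardrecon.simulate import uniform_directions

    dirs = uniform_directions(24)
    return GradientTable(np.full(24, 1000.0), dirs)
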