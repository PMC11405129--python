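import numpy as np
import pytest

from mfdl.basis import make_bspline_system
from mfdl.functional import OmicsVariantFunction, build_variant_function
from mfdl.simdata import GenotypeModel, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genotypes():
    """A small genotype modality (50 samples x 30 markers) with common variants."""
    return simulate_genotypes(
        GenotypeModel(n_samples=50, n_markers=30, ld_rho=0.5, fixed_maf=0.3), seed=2)


@pytest.fixture
def quintic_basis():
    return make_bspline_system(5, 7)


def random_ovf(rng, n=5, p=8):
    """A random small variant function with values in {0,1,2}."""
    vals = rng.integers(0, 3, size=(n, p)).astype(float)
    pos = np.sort(rng.choice(10_000, size=p, replace=False))
    return build_variant_function(vals, pos)
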