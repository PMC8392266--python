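import numpy as np
import pytest

from gkradiomics.synthgen import PhantomSpec, make_phantom_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 6-patient cohort for cheap structural tests."""
    return make_phantom_cohort(PhantomSpec(n_patients=6, seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def ellipsoid_mask():
    """A small non-spherical mask centered in a 16^3 grid."""
    g = np.indices((16, 16, 16))
    c = np.array([8, 8, 8])[:, None, None, None]
    radii = np.array([5.0, 3.5, 2.5])[:, None, None, None]
    return (((g - c) / radii) ** 2).sum(axis=0) <= 1.0
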