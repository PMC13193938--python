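import numpy as np
import pytest

from habitatpipe.imaging import CTVolume, RegionMask
from habitatpipe.synthetic import SyntheticCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Eight default-condition patients shared across module tests."""
    return generate_cohort(SyntheticCohortSpec(n_patients=8, seed=3))


@pytest.fixture(scope="session")
def sphere_mask():
    """Digital sphere of radius 10 mm centered in a 40 mm isotropic grid."""
    zz, yy, xx = np.ogrid[:40, :40, :40]
    mask = ((zz - 19.5) ** 2 + (yy - 19.5) ** 2 + (xx - 19.5) ** 2) <= 10.0 ** 2
    return RegionMask(mask)


@pytest.fixture(scope="session")
def noise_volume():
    rng = np.random.default_rng(42)
    return CTVolume(np.clip(rng.normal(0.5, 0.1, (40, 40, 40)), 0.0, 1.0))
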