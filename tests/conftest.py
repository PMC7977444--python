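import numpy as np
import pytest

from psmaquant import EllipsoidSpec, PhantomSpec, SUVImage, generate_phantom, reference_cohort


@pytest.fixture(scope="session")
def fixture_cohort():
    """The packaged 17-patient cohort plus its published reference calls."""
    records, refs = reference_cohort()
    return records, refs


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def two_cube_image():
    """Two disjoint 3x3x3 SUV-6 cubes on an SUV-1 background, 2 mm voxels."""
    values = np.ones((20, 20, 20))
    values[2:5, 2:5, 2:5] = 6.0
    values[12:15, 12:15, 12:15] = 6.0
    return SUVImage(values=values, spacing=(2.0, 2.0, 2.0), frame_id="cubes")


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    """Noise-free phantom with one ~20 mL ellipsoid at SUV 8 on SUV-1 background."""
    # radii chosen so 4/3 pi abc = 20 mL: (20, 15, 15.9155) mm
    lesion = EllipsoidSpec(name="target", center_mm=(63, 63, 95),
                           radii_mm=(20.0, 15.0, 15.9155), suv=8.0)
    spec = PhantomSpec(shape=(64, 64, 96), spacing=(2.0, 2.0, 2.0),
                       background_suv=1.0, lesions=(lesion,), noise_sd=0.0, seed=7)
    return spec, generate_phantom(spec)
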