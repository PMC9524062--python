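import numpy as np
import pytest

from dwifilters import LesionROI, LesionSpec, PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noisefree_mass_phantom():
    """Anisotropic mass lesion, no noise: ground truth is exact."""
    spec = PhantomSpec(grid_shape=(10, 48, 48), noise_sigma=0.0, seed=11)
    lesion = LesionSpec(
        center=(5, 24, 24),
        morphology="mass",
        pathology="malignant",
        mean_adc_target=1.0e-3,
        anisotropy=0.3,
        extent=(6.0, 12.0, 10.0),
        lesion_id="mass0",
    )
    return generate_phantom(spec, [lesion]), spec, lesion


@pytest.fixture
def small_roi():
    """Three-slice ROI on a 6x12x12 grid, largest mask on slice 3."""
    m2 = np.zeros((12, 12), bool)
    m2[4:7, 4:7] = True
    m3 = np.zeros((12, 12), bool)
    m3[3:8, 3:8] = True
    m4 = np.zeros((12, 12), bool)
    m4[5:7, 5:7] = True
    return LesionROI(masks={2: m2, 3: m3, 4: m4}, pixel_area=1.5625)
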