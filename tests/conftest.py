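import numpy as np
import pytest

from aitie import ImagingConfig, SourceSpec
from aitie.benchmark import star_study, wotf_optimization_summary


@pytest.fixture(scope="session")
def cfg128():
    return ImagingConfig(na_obj=0.8, wavelength_um=0.55, pixel_pitch_um=0.13,
                         grid_size=128)


@pytest.fixture(scope="session")
def annulus():
    return SourceSpec.matched_annulus(0.1)


@pytest.fixture(scope="session")
def aperture_summary():
    """Radial WOTF comparison of annular vs circular apertures (shared)."""
    return wotf_optimization_summary()


@pytest.fixture(scope="session")
def star_results():
    """Full-size noisy Siemens-star simulation study (shared; minutes)."""
    return star_study(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
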