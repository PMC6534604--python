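import numpy as np
import pytest

from acuitysim.psf import GridSpec
from acuitysim.wavefront import SubjectRecord


@pytest.fixture(scope="session")
def small_grid():
    """Quarter-resolution grid for fast pipeline tests (same pixel pitch,
    24 arcmin field; pupils up to ~5 mm fit the sampled pupil plane)."""
    return GridSpec(n=256, dx_arcsec=5.724)


@pytest.fixture(scope="session")
def mid_grid():
    return GridSpec(n=512, dx_arcsec=5.724)


@pytest.fixture(scope="session")
def diffraction_limited_subject():
    return SubjectRecord("diff", 0.0, 0.0, 5.0, 5.0, {})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230555)
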