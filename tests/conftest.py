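import numpy as np
import pytest

from prrtdose.dose_engine import build_kernel


@pytest.fixture(scope="session")
def kernel():
    """Packaged ¹⁷⁷Lu water kernel (loaded once per session)."""
    return build_kernel()


@pytest.fixture(scope="session")
def sphere_dose(kernel):
    """Per-decay dose map of the 24.1 mm³ uniform reference sphere at 20 μm
    pitch, shared by the S-value and DVH acceptance checks."""
    from prrtdose.dose_engine import convolve_dose, sphere_phantom

    grid, activity = sphere_phantom(24.1, 20.0)
    dose = convolve_dose(activity, kernel)
    return grid, dose


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
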