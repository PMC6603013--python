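import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nirassign.synthetic import (default_synthetic_grid,
                                 make_methylbenzene_family, simulate_spectrum)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def synthetic_grid() -> np.ndarray:
    return default_synthetic_grid()


@pytest.fixture(scope="session")
def family_spectra(synthetic_grid):
    """Noiseless 1 mol/L spectra of the synthetic methylbenzene family."""
    family = make_methylbenzene_family()
    spectra = {c.name: simulate_spectrum(c, 1.0, synthetic_grid)
               for c in family}
    return family, spectra
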