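import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from hidyce import (
    AlleleSpec,
    InstrumentConfig,
    SamplePlan,
    make_dye_spectra,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def quiet_config():
    """Small, noise-free instrument for exact analytic checks."""
    return InstrumentConfig(
        scan_count=200,
        background_noise_sd=0.0,
        readout_noise_sd=0.0,
    )


@pytest.fixture
def default_spectra():
    return make_dye_spectra()


@pytest.fixture
def single_allele_plan():
    """One allele, VAF 1.0, well inside a 200-scan trace."""
    allele = AlleleSpec(
        name="A-MT",
        dye_channel=1,
        peak_position=100,
        peak_sigma=3.0,
        amplitude_per_unit_vaf=5000.0,
    )
    return SamplePlan(alleles=((allele, 1.0),), capillary=0, seed=1)


def gaussian(t, pos, sigma):
    return np.exp(-((np.asarray(t, float) - pos) ** 2) / (2 * sigma**2))
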