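import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pedinirs.core_io import InstrumentConfig
from pedinirs.forward_model import MediumGeometry
from pedinirs.synthetic_data import DEFAULT_SYNTH_INSTRUMENT, generate_irf

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def instrument() -> InstrumentConfig:
    """1024-channel synthetic instrument (9.7 ps/ch, 686/830 nm, rho 2.5 cm)."""
    return DEFAULT_SYNTH_INSTRUMENT


@pytest.fixture(scope="session")
def geom(instrument) -> MediumGeometry:
    return MediumGeometry(
        rho=instrument.rho, refractive_index_tissue=instrument.refractive_index
    )


@pytest.fixture(scope="session")
def irf60(instrument):
    """A 60 ps FWHM Gaussian IRF on the instrument grid."""
    return generate_irf(60.0, instrument, seed=7)


@pytest.fixture(scope="session")
def t_grid(instrument) -> np.ndarray:
    return np.arange(instrument.n_channels) * instrument.channel_width
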