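import numpy as np
import pytest

from nanocage.architecture import build_default_architecture, default_species_table
from nanocage.signals import SignalFactors


@pytest.fixture(scope="session")
def architecture():
    return build_default_architecture()


@pytest.fixture(scope="session")
def simplified_table():
    return default_species_table("simplified")


@pytest.fixture(scope="session")
def inclusive_table():
    return default_species_table("inclusive")


@pytest.fixture()
def unit_factors():
    """Adjustment factor 1 (no scattering correction), 50 uM reference."""
    return SignalFactors(f_a280=1.0)


@pytest.fixture()
def i53_40_factors():
    return SignalFactors(f_a280=0.89, f_a280_sd=0.06)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
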