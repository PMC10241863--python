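import numpy as np
import pytest

from vitellometrics import MembraneDropParams

# bench-standard yolk: ~17 mL at 1.035 g/cm^3
YOLK_DENSITY = 1035.0  # kg/m^3
YOLK_VOLUME = 17e-6  # m^3
GRAVITY = 9.8


def params_at_bond(bo, volume=YOLK_VOLUME, density=YOLK_DENSITY):
    """MembraneDropParams with the tension chosen to hit Bond number ``bo``."""
    gamma = density * GRAVITY * volume ** (2.0 / 3.0) / bo
    return MembraneDropParams(gamma, density, volume, GRAVITY)


@pytest.fixture(scope="session")
def yolk_params():
    return dict(volume=YOLK_VOLUME, density=YOLK_DENSITY)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230615)
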