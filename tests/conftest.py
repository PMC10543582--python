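import numpy as np
import pytest

from alpscombat import SimulationConfig, generate_cohort
from alpscombat.simulate import ScannerEffect


@pytest.fixture
def recovery_config():
    """Three scanners with strong location/scale effects, 200 per cell."""
    return SimulationConfig(
        n_per_cell=200,
        scanners=(
            ScannerEffect("A", gamma=-0.3, delta=0.7),
            ScannerEffect("B", gamma=0.0, delta=1.0),
            ScannerEffect("C", gamma=0.3, delta=1.5),
        ),
        sigma=0.2,
        seed=20240901,
    )


@pytest.fixture
def recovery_cohort(recovery_config):
    return generate_cohort(recovery_config).table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
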