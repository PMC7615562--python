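import numpy as np
import pytest

import momnet as mn


@pytest.fixture(scope="session")
def connectome30():
    """30-area modular synthetic connectome, unit-mean normalized."""
    return mn.normalize_to_unit_mean(mn.generate_synthetic_connectome(30, 3, 0.6, seed=42))


@pytest.fixture(scope="session")
def connectome12():
    return mn.normalize_to_unit_mean(mn.generate_synthetic_connectome(12, 2, 0.7, seed=3))


@pytest.fixture(scope="session")
def run_synchronized(connectome30):
    """High-synchrony delayed run: K=20, <tau>=0.5 ms, 21 s."""
    params = mn.SimulationParams(K=20.0, mean_delay_s=0.5e-3, duration=21.0, seed=11)
    return mn.integrate(connectome30, params)


@pytest.fixture(scope="session")
def run_zero_delay(connectome30):
    """Zero-delay strong-coupling run used as a MOM baseline, 16 s."""
    params = mn.SimulationParams(K=10.0, speed_mps=np.inf, duration=16.0, seed=21)
    return mn.integrate(connectome30, params)
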