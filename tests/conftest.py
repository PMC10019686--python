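import numpy as np
import pytest

import photodyn as P


@pytest.fixture(scope="session")
def params() -> P.ModelParameters:
    return P.ModelParameters.default()


@pytest.fixture(scope="session")
def step_trace() -> P.EnvironmentTrace:
    """Irradiance step 100 -> 600 -> 100 under otherwise constant drivers."""
    t = np.arange(0.0, 9000.0, 2.0)
    I = np.where((t >= 1000) & (t < 4000), 600.0, 100.0)
    return P.EnvironmentTrace(
        t=t, I=I, Tl=np.full_like(t, 296.0), ca=np.full_like(t, 400.0)
    )


@pytest.fixture(scope="session")
def chamber_dataset(params) -> P.GasExchangeDataset:
    """One hour of 50/500 chamber light switching with channel noise."""
    spec = P.IrradianceProfileSpec(mode="chamber_fluctuating", duration=3600, seed=5)
    trace = P.generate_environment(spec)
    return P.generate_gas_exchange(trace, params, P.NoiseSpec(seed=6))


@pytest.fixture(scope="session")
def chamber_dataset_clean(params) -> P.GasExchangeDataset:
    """Noise-free version of the chamber dataset (same trace seed)."""
    spec = P.IrradianceProfileSpec(mode="chamber_fluctuating", duration=3600, seed=5)
    trace = P.generate_environment(spec)
    return P.generate_gas_exchange(trace, params)


@pytest.fixture(scope="session")
def greenhouse_trace(params) -> P.EnvironmentTrace:
    """Two-hour greenhouse-style trace (fluctuating baseline + one peak)."""
    spec = P.IrradianceProfileSpec(seed=3, duration=7200)
    return P.generate_environment(spec)
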