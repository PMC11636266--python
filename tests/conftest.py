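import numpy as np
import pandas as pd
import pytest

from molcomrx import (
    ChannelConfig,
    CircuitParams,
    RunConfig,
    Trajectory,
    build_model,
)
from molcomrx.period_finder import find_native_state


@pytest.fixture(scope="session")
def channel_a():
    return ChannelConfig()  # IPTG: d=200 um, r=1 um, D=600 um^2/s


@pytest.fixture(scope="session")
def channel_b():
    return ChannelConfig(diffusion_um2_per_s=870.0)  # aTc


@pytest.fixture(scope="session")
def default_params():
    return CircuitParams()


@pytest.fixture(scope="session")
def base_model(default_params):
    """Compiled no-input circuit model, shared across tests (compile once)."""
    model = build_model(default_params)
    model.compiled()
    return model


@pytest.fixture(scope="session")
def native_state(default_params):
    return find_native_state(default_params)


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


def make_trajectory(times, **species):
    """Synthetic Trajectory with the given species arrays (others zero)."""
    times = np.asarray(times, dtype=float)
    from molcomrx.circuit import SPECIES

    data = {name: np.zeros(len(times)) for name in SPECIES}
    for name, values in species.items():
        data[name] = np.asarray(values, dtype=float)
    return Trajectory(times_s=times, values=pd.DataFrame(data))
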