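import numpy as np
import pytest

from patchphys import (
    NeuronParams,
    ProtocolSpec,
    default_cc_protocol,
    default_vc_protocol,
    simulate_current_clamp,
    simulate_voltage_clamp,
)


@pytest.fixture(scope="session")
def passive_params():
    """Cell with all voltage-gated conductances off: pure RC."""
    return NeuronParams(g_na=0.0, g_kd=0.0, g_a=0.0, g_l=2.0, c_m=30.0,
                        noise_sd=0.0)


@pytest.fixture(scope="session")
def excitable_params():
    """Moderately excitable preset (week-7-mutant-like)."""
    return NeuronParams(c_m=28.0, g_l=1.2, g_na=95.0, g_kd=16.0, g_a=26.0,
                        noise_sd=0.0)


@pytest.fixture(scope="session")
def robust_spiker_params():
    """High-conductance cell whose spikes all overshoot 0 mV (for crossing
    -counter oracle checks)."""
    return NeuronParams(c_m=30.0, g_l=1.5, g_na=300.0, g_kd=60.0, g_a=30.0,
                        noise_sd=0.0)


@pytest.fixture(scope="session")
def cc_protocol():
    return default_cc_protocol()


@pytest.fixture(scope="session")
def vc_protocol():
    return default_vc_protocol()


@pytest.fixture(scope="session")
def excitable_cc(excitable_params, cc_protocol):
    return simulate_current_clamp(excitable_params, cc_protocol, seed=1)


@pytest.fixture(scope="session")
def excitable_vc(excitable_params, vc_protocol):
    return simulate_voltage_clamp(excitable_params, vc_protocol, seed=1)
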