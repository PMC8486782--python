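import numpy as np
import pytest
from dataclasses import replace

from ecochg import CochlearModel, DamageMap, preset


@pytest.fixture(scope="session")
def model():
    return CochlearModel()


@pytest.fixture(scope="session")
def quiet_model(model):
    """Default model with all channel noise disabled."""
    return replace(model, ecp_noise_pa=0.0, rw_noise_v=0.0, remote_noise_v=0.0)


@pytest.fixture(scope="session")
def healthy(model):
    return DamageMap.healthy(model)


@pytest.fixture(scope="session")
def battery_results():
    """One shared run of the headline-observable battery (noise-free)."""
    from ecochg.reproduce import run_battery
    return {r.target: r for r in run_battery(seed=1)}


@pytest.fixture(scope="session")
def notch_profiles(model):
    """Pre/post DP-grams and change profile for the 4-kHz notch preset."""
    from ecochg import dp_sweep, dp_change
    _, healthy_map = preset("healthy", model)
    _, notch = preset("notch_4khz", model)
    pre = dp_sweep(model, healthy_map, seed=101)
    post = dp_sweep(model, notch, seed=202)
    return pre, post, dp_change(pre, post)
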