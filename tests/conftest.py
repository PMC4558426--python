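import numpy as np
import pytest
from hypothesis import settings

from thermocode import Recording
from thermocode.synthetic import (
    STNeuronModel,
    TTNeuronModel,
    simulate_st_recording,
    simulate_tt_recordings,
)

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tt_model() -> TTNeuronModel:
    return TTNeuronModel()


@pytest.fixture(scope="session")
def st_model() -> STNeuronModel:
    return STNeuronModel()


@pytest.fixture(scope="session")
def tt_unit(tt_model) -> list[Recording]:
    """One flux-detector unit stimulated at three cooling ramp rates."""
    sims = simulate_tt_recordings(tt_model, seed=7)
    return [
        Recording(
            unit_id=f"tt_fix_r{j}",
            neuron_class="TT",
            trace=trace,
            train=train,
            protocol_onset=proto.onset,
        )
        for j, (proto, trace, train) in enumerate(sims)
    ]


@pytest.fixture(scope="session")
def st_unit(st_model) -> Recording:
    """One steady-temperature unit under a slow 23->37 degC ramp."""
    proto, trace, train = simulate_st_recording(st_model, seed=11)
    return Recording(
        unit_id="st_fix",
        neuron_class="ST",
        trace=trace,
        train=train,
        protocol_onset=proto.onset,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
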