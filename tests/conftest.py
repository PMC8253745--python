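import numpy as np
import pytest

import vestigait as vg
from vestigait import synthetic_gait as sg


@pytest.fixture(scope="session")
def normal_trial():
    """A 64-stride normal-walking trial shared across tests."""
    evs = vg.generate_evs(120.0, seed=3)
    config, kwargs = sg.condition_preset("normal")
    return sg.simulate_trial(evs, config, n_strides=64, seed=5, **kwargs)


@pytest.fixture(scope="session")
def narrow_trial():
    """A 64-stride narrow-base trial with cross-stepping."""
    evs = vg.generate_evs(120.0, seed=3)
    config, kwargs = sg.condition_preset("narrow")
    return sg.simulate_trial(evs, config, n_strides=64, seed=7, **kwargs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
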