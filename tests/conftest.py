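import numpy as np
import pytest

from ddmconf import ModelParams, StimulusSpec, ThresholdSpec


@pytest.fixture
def stim():
    """Stated-world stimulus: 40 Hz frames, moderate per-frame SNR."""
    return StimulusSpec(delta_mu=0.12, sigma_E=0.25, t_f=0.025)


@pytest.fixture
def params():
    """Stated-world observer with drift-rate variability and a flat unit threshold."""
    return ModelParams(
        sigma_acc=1.0, sigma_phi=0.5, sigma_m=0.3, pipeline_I=0.1,
        boundaries=(0.5, 1.0, 1.5), threshold=ThresholdSpec("constant", (1.0,)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
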