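import numpy as np
import pytest

from spikeramp import AnalysisWindows, TaskConfig
from spikeramp.synth import NeuronGroundTruth, simulate_population


@pytest.fixture
def config():
    return TaskConfig()


@pytest.fixture
def windows():
    return AnalysisWindows()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """One tonic increaser + one null neuron, one block per condition."""
    cfg = TaskConfig()
    gen = np.random.default_rng(777)
    neurons = [
        NeuronGroundTruth(
            0,
            baseline_rate=4.0,
            tonic_gain_increase=15.0,
            cs_phasic_gain=2.0,
            stop_phasic_gain=1.5,
            stop_phasic_offset=(-6.0, 0.0),
            burst_fraction=0.7,
        ),
        NeuronGroundTruth(1, baseline_rate=3.5),
    ]
    return simulate_population(cfg, {}, gen, n_blocks=1, neurons=neurons, with_licks=True)
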