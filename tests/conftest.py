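import numpy as np
import pytest

from bushycell import SpikeTrainSet, StimulusSpec


@pytest.fixture
def tone350():
    return StimulusSpec(kind="pure_tone", frequency=350.0, duration=200.0,
                        pause=200.0, n_reps=10, onset_latency=4.1)


@pytest.fixture
def tone3500():
    return StimulusSpec(kind="pure_tone", frequency=3500.0, duration=200.0,
                        pause=200.0, n_reps=10, onset_latency=2.4)


def manual_trains(spike_lists, duration=50.0, pause=10.0, onset=0.0):
    """Build a SpikeTrainSet from explicit per-fiber single-rep spike lists."""
    stim = StimulusSpec(duration=duration, pause=pause, n_reps=1,
                        onset_latency=onset)
    spikes = [[np.asarray(s, dtype=float)] for s in spike_lists]
    return SpikeTrainSet(spikes=spikes, stimulus=stim,
                         n_fibers=len(spike_lists))
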