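import numpy as np
import pytest

from vasopipe import synth
from vasopipe.behavior import segment_behavior


@pytest.fixture(scope="session")
def bout_trace():
    """Locomotion trace with three well-separated bouts."""
    return synth.make_locomotion_trace(
        [(20.0, 28.0), (50.0, 62.0), (85.0, 97.0)],
        duration=120.0, sample_rate=1000.0, noise_sd=0.1, seed=7,
    )


@pytest.fixture(scope="session")
def bout_segmentation(bout_trace):
    return segment_behavior(bout_trace)


@pytest.fixture(scope="session")
def pial_movie():
    """Constant 20 um pial vessel movie at moderate SNR."""
    return synth.make_pial_movie(np.full(16, 20.0), pixel_size=0.5,
                                 frame_rate=8.0, snr=10.0, seed=3)

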