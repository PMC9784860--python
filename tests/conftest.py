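import numpy as np
import pytest

from endoskill import from_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(20221216)


def make_stream(frames, fps=10.0):
    """Wrap a list of 2-D uint8 arrays as a FrameStream."""
    return from_arrays([np.asarray(f, dtype=np.uint8) for f in frames], fps=fps)


@pytest.fixture
def static_stream():
    """1.3 s of identical 32x32 frames at 10 fps (4 differencing pairs)."""
    frame = np.full((32, 32), 120, dtype=np.uint8)
    return make_stream([frame] * 13, fps=10.0)
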