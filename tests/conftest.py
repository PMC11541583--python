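import numpy as np
import pytest

from spheroquant.frames import ImageFrame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def frame_from(pixels, pixel_size=1.0, channel="grey", bit_depth=16):
    """Helper: wrap raw pixel data in a calibrated frame."""
    return ImageFrame(
        np.asarray(pixels), bit_depth=bit_depth, pixel_size=pixel_size, channel=channel
    )
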