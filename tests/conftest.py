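import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py

from titervision import ImageFrame


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def make_frame(pixels, channel="green", well="B2", **kw) -> ImageFrame:
    return ImageFrame(pixels=np.asarray(pixels, dtype=float), channel=channel, well=well, **kw)


@pytest.fixture
def frame_factory():
    return make_frame
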