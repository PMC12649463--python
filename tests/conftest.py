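import numpy as np
import pytest

from blinkpath import EyeLandmarkSet


@pytest.fixture
def rect_eye():
    """Factory for the symmetric-rectangle eye: A=2, B=2, C=4, EAR=0.5."""

    def make(scale: float = 1.0, closed: bool = False) -> EyeLandmarkSet:
        h = 0.0 if closed else 1.0
        pts = np.array(
            [[0, 0], [1, h], [3, h], [4, 0], [3, -h], [1, -h]], dtype=float
        )
        return EyeLandmarkSet(pts * scale)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
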