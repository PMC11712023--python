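import numpy as np
import pytest

from polartrack import RoiShape, TimeLapseStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stack(rng):
    """5-frame 16×16 random stack, 0.5 µm/px, 2 s/frame."""
    return TimeLapseStack(
        frames=rng.uniform(0, 100, size=(5, 16, 16)),
        pixel_size=0.5,
        frame_interval=2.0,
    )


@pytest.fixture
def circle_roi():
    """5-µm-diameter circle, the polarized-site ROI convention."""
    return RoiShape(kind="circle", center=(4.0, 4.0), radius=2.5)
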