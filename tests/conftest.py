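import numpy as np
import pytest

from bananavision.geometry import CameraIntrinsics
from bananavision.scenes import default_calibration


@pytest.fixture
def vga_intrinsics() -> CameraIntrinsics:
    return CameraIntrinsics(fx=500.0, fy=500.0, cx=320.0, cy=240.0, width=640, height=480)


@pytest.fixture
def calibration() -> dict:
    return default_calibration()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
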