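import numpy as np
import pytest

from scintidose import BeamModel, CalibrationSet, DetectorModel

# 80-20 quantile spread of a unit normal: penumbra of an erf edge = this * sigma
Z_8020 = 1.6832424671458288


@pytest.fixture
def detector():
    return DetectorModel()


@pytest.fixture
def cal(detector):
    return CalibrationSet(acr=detector.acr_true, cr=detector.cr_true)


@pytest.fixture
def beam3x3():
    """3 x 3 cm^2 field, untilted, default FFF-like depth dose."""
    return BeamModel(field_width_w=30.0)


@pytest.fixture
def tilted_small_beam():
    """0.5 x 0.5 cm^2 field with a 0.01 rad beam inclination."""
    return BeamModel(field_width_w=5.0, tilt_theta=0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
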