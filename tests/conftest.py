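import numpy as np
import pytest

from explantmech import ForceTrace, ProbeCalibration


@pytest.fixture
def calibration():
    return ProbeCalibration(spring_constant=0.02, magnification=0.5, probe_id="t")


@pytest.fixture
def flat_trace(calibration):
    """Ten samples over one hour, constant 100 px deflection, no drift."""
    t = np.arange(0, 60, 6.0)
    return ForceTrace(
        time_min=t,
        deflection_px=np.full_like(t, 100.0),
        calibration=calibration,
        pre_unstressed_px=0.0,
        post_unstressed_px=0.0,
    )
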