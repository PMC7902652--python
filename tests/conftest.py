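import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from sniffmodel.deposition import DEVICE_CHANNEL, DEVICE_CALIBRATION
from sniffmodel.womersley import AIR, Channel, SniffProtocol


@pytest.fixture
def device_channel() -> Channel:
    """The bench device's channel: 1 cm radius, 5 mm sensor."""
    return DEVICE_CHANNEL


@pytest.fixture
def air():
    return AIR


@pytest.fixture
def device_protocol() -> SniffProtocol:
    """Reference operating point: 0.3 Hz at the calibrated stroke."""
    return DEVICE_CALIBRATION.protocol(0.3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
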