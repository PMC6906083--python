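import numpy as np
import pytest

from alarmcast.io import VitalTrace


def grid_trace(signal, values, start=0.0, infant="I000"):
    """VitalTrace on an exact 1 Hz integer grid."""
    values = np.asarray(values, dtype=float)
    times = start + np.arange(values.size, dtype=float)
    return VitalTrace(infant, signal, times, values)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
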