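import numpy as np
import pytest

from edastress.device_model import ConductanceTrace


def make_trace(values, dt=2.0, source="synthetic"):
    values = np.asarray(values, dtype=float)
    return ConductanceTrace(np.arange(values.size) * dt, values, source=source)


@pytest.fixture
def triangle_trace():
    """Symmetric triangular bump on a 2 µS tonic level: linear rise of
    1 µS over 10 s starting at t=20, linear fall over the next 10 s."""
    t = np.arange(0.0, 60.0, 2.0)
    y = np.full(t.shape, 2.0)
    up = (t >= 20) & (t <= 30)
    y[up] = 2.0 + (t[up] - 20) / 10.0
    dn = (t > 30) & (t <= 40)
    y[dn] = 3.0 - (t[dn] - 30) / 10.0
    return ConductanceTrace(t, y, source="synthetic")
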