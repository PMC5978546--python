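import numpy as np
import pytest

from xpanderdose import make_port
from xpanderdose.volume import centered_grid


@pytest.fixture
def default_port():
    return make_port()


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def fine_grid():
    """0.25 mm grid tightly covering the default port."""
    return centered_grid((24.0, 24.0, 24.0), (0.25, 0.25, 0.25))


def dense_chord_oracle(port, origin, direction, step_mm=0.001, span_mm=80.0):
    """Independent chord estimate: step along the ray and sum the inside
    indicator (1 um steps by default)."""
    ts = np.arange(0.0, span_mm, step_mm)
    pts = np.asarray(origin)[None, :] + ts[:, None] * np.asarray(direction)[None, :]
    return port.contains(pts).sum() * step_mm
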