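import numpy as np
import pytest

from rp24.spectral import ExpressionProfile

N = 12
DT = 4.0
T = 48.0
TIMES = np.arange(N) * DT


@pytest.fixture
def times():
    return TIMES.copy()


def make_profile(values, tid="t", condition="young", times=None, duration=None):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(len(values)) * DT
    if duration is None:
        duration = len(values) * (times[1] - times[0])
    return ExpressionProfile(
        transcript_id=tid, times=times, values=values, duration=duration, condition=condition
    )


@pytest.fixture
def cosine24():
    """Unit-amplitude 24-h cosine on the 12-point / 48-h grid."""
    return make_profile(np.cos(2 * np.pi * TIMES / 24.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
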