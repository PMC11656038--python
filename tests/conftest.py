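import numpy as np
import pytest

from pupiltrend import CleanSeries, PupilRecording


def make_recording(
    duration_s: float = 10.0,
    rate: float = 1000.0,
    left=None,
    right=None,
    valid=None,
    participant_id: str = "p1",
) -> PupilRecording:
    n = int(round(duration_s * rate))
    t = np.arange(n) * (1000.0 / rate)
    if left is None:
        left = np.full(n, 3000.0)
    if right is None:
        right = left.copy()
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return PupilRecording(
        participant_id=participant_id,
        t=t,
        left=np.asarray(left, dtype=float),
        right=np.asarray(right, dtype=float),
        valid_left=np.asarray(valid, dtype=bool),
        valid_right=np.asarray(valid, dtype=bool),
        sample_rate=rate,
    )


def make_series(values, rate: float = 1000.0, interpolated=None) -> CleanSeries:
    values = np.asarray(values, dtype=float)
    n = values.size
    if interpolated is None:
        interpolated = np.zeros(n, dtype=bool)
    t = np.arange(n) * (1000.0 / rate)
    return CleanSeries(t=t, value=values, interpolated=interpolated, sample_rate=rate)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
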