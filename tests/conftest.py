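import numpy as np
import pytest

from eatseg.cad_io import Episode, EpisodeList, MotionRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_recording(rng):
    """A 10-minute random-walk recording (each channel nondegenerate)."""
    n = 10 * 60 * 15
    data = np.cumsum(rng.standard_normal((n, 6)), axis=0) * 0.01
    return MotionRecording(subject_id="walk0", data=data, sample_rate=15.0)


@pytest.fixture
def meal_list():
    return EpisodeList(
        episodes=[Episode(480.0, 900.0, "meal"), Episode(43200.0, 43900.0, "meal")]
    )


def make_recording(n, seed=0, rate=15.0, subject_id="r0"):
    data = np.random.default_rng(seed).standard_normal((n, 6))
    return MotionRecording(subject_id=subject_id, data=data, sample_rate=rate)
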