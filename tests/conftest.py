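import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from affectsense.io_formats import SignalRecord, Trial, TrialSet
from affectsense.synthetic import EcgConfig, gen_ecg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_channel_record(rng):
    return SignalRecord(
        channel_names=["ECG", "EDA"],
        data=rng.standard_normal((2, 1280)),
        rate_hz=128.0,
    )


@pytest.fixture
def small_trial_set(rng):
    trials = []
    for s in range(2):
        for t in range(3):
            trials.append(Trial(
                subject_id=f"S{s:02d}", trial_id=t,
                ecg=gen_ecg(EcgConfig(duration_s=6.0, seed=10 * s + t)),
                vad_raw=tuple(1.0 + 4.0 * rng.random(3)),
            ))
    return TrialSet(trials=trials)


@pytest.fixture
def ecg_segment():
    """One standard 640-sample (5 s @ 128 Hz) segment."""
    return gen_ecg(EcgConfig(duration_s=5.0, seed=7))
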