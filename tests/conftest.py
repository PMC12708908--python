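import numpy as np
import pytest

from dyadsync import pipeline, synth
from dyadsync.types import SignalInterval


@pytest.fixture(scope="session")
def small_records():
    """Two dyads at reduced rate/duration for pipeline-level tests."""
    config = synth.SynthConfig(n_dyads=2, sampling_rate=32, interval_duration=120,
                               seed=7)
    return synth.generate_cohort(config), config


@pytest.fixture(scope="session")
def extracted_table(small_records):
    records, _ = small_records
    return pipeline.extract_feature_table(records)


@pytest.fixture(scope="session")
def feature_cohort():
    """Feature-level synthetic cohort with label-driving features."""
    return synth.synthetic_feature_table(n_dyads=8, seed=5)


def make_interval(samples, fs=32.0, channel="ecg", dyad=0, participant=1,
                  interval=1):
    return SignalInterval(dyad_id=dyad, participant=participant,
                          interval_index=interval, channel=channel,
                          sampling_rate=fs, samples=np.asarray(samples, float))


def pulse_train(spacings_s, fs, duration_s, width_s=0.02, amplitude=1.0):
    """Synthetic ECG-like signal with pulses at cumulative spacings."""
    n = round(duration_s * fs)
    t = np.arange(n) / fs
    sig = np.zeros(n)
    beat_times = np.cumsum(spacings_s)
    beat_times = beat_times[beat_times < duration_s]
    for bt in beat_times:
        sig += amplitude * np.exp(-0.5 * ((t - bt) / width_s) ** 2)
    return sig, beat_times
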