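import numpy as np
import pytest

from cobci.preprocessing import Epoch
from cobci.synth import Recording, SyntheticConfig


def make_epoch(samples, sampling_rate=512.0, labels=None,
               true_frequency=10.0, participant="P00"):
    samples = np.atleast_2d(np.asarray(samples, dtype=np.float64))
    if labels is None:
        labels = tuple(f"C{i}" for i in range(samples.shape[0]))
    return Epoch(
        participant_id=participant, trial_index=0,
        epoch_index_within_trial=0, true_frequency=true_frequency,
        channel_labels=labels, sampling_rate=sampling_rate, samples=samples)


def tone_epoch(freq, n=512, fs=512.0, amplitude=1.0, n_channels=1,
               labels=None, phase=0.0):
    t = np.arange(n) / fs
    x = amplitude * np.sin(2 * np.pi * freq * t + phase)
    samples = np.tile(x, (n_channels, 1))
    return make_epoch(samples, sampling_rate=fs, labels=labels,
                      true_frequency=freq)


def make_recording(samples, fs=512.0, labels=None, annotations=None,
                   participant="P00"):
    samples = np.atleast_2d(np.asarray(samples))
    if labels is None:
        labels = tuple(f"C{i}" for i in range(samples.shape[0]))
    if annotations is None:
        annotations = [(0.0, samples.shape[1] / fs, "target:10")]
    return Recording(participant_id=participant, channel_labels=labels,
                     sampling_rate=fs, samples=samples,
                     annotations=annotations)


@pytest.fixture
def tiny_config():
    """Small, fast session config: 2 participants, 2 trials/target, 4-s
    trials, generated directly at 512 Hz."""
    return SyntheticConfig(
        seed=7, n_participants=2, trials_per_target=2, trial_duration=4.0,
        sampling_rate=512.0, noise_amplitude=1.0, coupling_gain=1.0)


@pytest.fixture
def noiseless_config():
    return SyntheticConfig(
        seed=0, n_participants=1, trials_per_target=1, trial_duration=2.0,
        sampling_rate=512.0, noise_amplitude=0.0, ssvep_amplitude=1.0)
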