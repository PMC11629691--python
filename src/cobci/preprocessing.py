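"""Preprocessing chain: resample to 512 Hz, band-pass 4-45 Hz, cut 1-s epochs.

The composition order is fixed (resample -> bandpass -> epoch) and every
operation preserves channel order and labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .errors import PipelineError
from .synth import Recording, parse_annotation_label

__all__ = [
    "Epoch", "resample", "bandpass", "epoch_segments",
    "DEFAULT_RATE", "DEFAULT_BAND", "DEFAULT_EPOCH_DURATION",
]

DEFAULT_RATE = 512.0
DEFAULT_BAND = (4.0, 45.0)
DEFAULT_EPOCH_DURATION = 1.0

#: Butterworth order per band edge; applied forward-backward (zero phase).
FILTER_ORDER = 4


@dataclass
class Epoch:
    """One fixed-duration segment of a trial.

    ``samples`` is channels x time; ``true_frequency`` is the trial's
    attended target in Hz.
    """

    participant_id: str
    trial_index: int
    epoch_index_within_trial: int
    true_frequency: float
    channel_labels: tuple
    sampling_rate: float
    samples: np.ndarray

    def __post_init__(self):
        self.channel_labels = tuple(self.channel_labels)
        self.samples = np.asarray(self.samples)
        if self.samples.shape[0] != len(self.channel_labels):
            raise PipelineError("epoch rows must match channel labels")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def resample(recording: Recording, target_rate: float) -> Recording:
    """Polyphase resampling with FIR anti-alias filtering.

    Output length follows the floor convention
    ``floor(n * target / source)``.  Annotations are carried over
    unchanged (they are stored in seconds).  Upsampling is rejected.
    """
    if target_rate <= 0:
        raise PipelineError("target_rate must be positive")
    if target_rate > recording.sampling_rate:
        raise PipelineError(
            f"refusing to upsample from {recording.sampling_rate} Hz to "
            f"{target_rate} Hz")
    if target_rate == recording.sampling_rate:
        return recording.copy()

    ratio = (Fraction(target_rate).limit_denominator(10 ** 6)
             / Fraction(recording.sampling_rate).limit_denominator(10 ** 6))
    up, down = ratio.numerator, ratio.denominator
    out = signal.resample_poly(
        recording.samples.astype(np.float64), up, down, axis=1)
    n_out = (recording.n_samples * up) // down
    out = out[:, :n_out]
    return Recording(
        participant_id=recording.participant_id,
        channel_labels=recording.channel_labels,
        sampling_rate=float(target_rate),
        samples=out.astype(np.float32),
        annotations=list(recording.annotations),
    )


def design_bandpass(low: float, high: float, sampling_rate: float):
    """Second-order sections of the band-pass filter (exposed for
    frequency-response inspection in tests)."""
    if not (0 < low < high < sampling_rate / 2):
        raise PipelineError(
            f"band edges must satisfy 0 < low < high < rate/2; got "
            f"({low}, {high}) at {sampling_rate} Hz")
    return signal.butter(FILTER_ORDER, [low, high], btype="bandpass",
                         fs=sampling_rate, output="sos")


def bandpass(recording: Recording, low: float = DEFAULT_BAND[0],
             high: float = DEFAULT_BAND[1]) -> Recording:
    """Zero-phase Butterworth band-pass applied per channel."""
    sos = design_bandpass(low, high, recording.sampling_rate)
    filtered = signal.sosfiltfilt(
        sos, recording.samples.astype(np.float64), axis=1)
    return Recording(
        participant_id=recording.participant_id,
        channel_labels=recording.channel_labels,
        sampling_rate=recording.sampling_rate,
        samples=filtered.astype(np.float32),
        annotations=list(recording.annotations),
    )


def epoch_segments(recording: Recording,
                   epoch_duration: float = DEFAULT_EPOCH_DURATION
                   ) -> list[Epoch]:
    """Cut each annotated trial into consecutive non-overlapping epochs.

    Epochs start exactly at trial onsets; a trailing remainder shorter
    than ``epoch_duration`` is discarded.  Each epoch inherits the
    trial's true target frequency from its annotation label.
    """
    if epoch_duration <= 0:
        raise PipelineError("epoch_duration must be positive")
    if not recording.annotations:
        raise PipelineError("recording has no trial annotations to epoch")

    fs = recording.sampling_rate
    n_epoch = int(round(epoch_duration * fs))
    epochs: list[Epoch] = []
    for trial_index, (onset, duration, label) in enumerate(
            recording.annotations):
        freq = parse_annotation_label(label)
        start = int(round(onset * fs))
        avail = min(int(round(duration * fs)), recording.n_samples - start)
        n_full = avail // n_epoch
        if n_full == 0:
            raise PipelineError(
                f"trial {trial_index} is shorter ({avail / fs:.3f}s) than "
                f"one epoch ({epoch_duration}s)")
        for k in range(n_full):
            s = start + k * n_epoch
            epochs.append(Epoch(
                participant_id=recording.participant_id,
                trial_index=trial_index,
                epoch_index_within_trial=k,
                true_frequency=freq,
                channel_labels=recording.channel_labels,
                sampling_rate=fs,
                samples=recording.samples[:, s:s + n_epoch],
            ))
    return epochs
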