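"""End-to-end composition of the analysis chain.

Processing is applied per trial (crop -> resample -> band-pass -> 1-s
epochs -> Welch PSD), exactly as a streaming server must apply it; the
offline entry points below and the session server call the same
functions on the same float32 samples, which is what makes online and
offline results bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import coupling, decoding, preprocessing, spectral
from .errors import PipelineError
from .preprocessing import Epoch
from .synth import Recording, generate_group_session, generate_recording, \
    parse_annotation_label

__all__ = [
    "AnalysisSettings", "crop_trial", "process_trial", "trial_psds",
    "recording_trial_psds", "decode_recording", "decode_recordings_collaborative",
    "generate_and_decode_individual", "decode_group_session",
    "coupling_from_recordings",
]


@dataclass(frozen=True)
class AnalysisSettings:
    """Knobs of the analysis chain with the published defaults."""

    rate: float = preprocessing.DEFAULT_RATE
    band: tuple = preprocessing.DEFAULT_BAND
    epoch_duration: float = preprocessing.DEFAULT_EPOCH_DURATION
    occipital_channels: tuple = decoding.OCCIPITAL_DEFAULT
    candidates: tuple = (8.0, 10.0, 13.0)

    def to_dict(self) -> dict:
        return {
            "rate": self.rate,
            "band": list(self.band),
            "epoch_duration": self.epoch_duration,
            "occipital_channels": list(self.occipital_channels),
            "candidates": list(self.candidates),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisSettings":
        return cls(rate=d["rate"], band=tuple(d["band"]),
                   epoch_duration=d["epoch_duration"],
                   occipital_channels=tuple(d["occipital_channels"]),
                   candidates=tuple(d["candidates"]))


def crop_trial(recording: Recording, trial_index: int) -> Recording:
    """A single-trial recording whose annotation starts at t=0."""
    onset, duration, label = recording.annotations[trial_index]
    fs = recording.sampling_rate
    start = int(round(onset * fs))
    stop = start + int(round(duration * fs))
    return Recording(
        participant_id=recording.participant_id,
        channel_labels=recording.channel_labels,
        sampling_rate=fs,
        samples=recording.samples[:, start:stop],
        annotations=[(0.0, duration, label)],
    )


def process_trial(trial: Recording,
                  settings: AnalysisSettings = AnalysisSettings()
                  ) -> list[Epoch]:
    """Resample -> band-pass -> epoch one trial."""
    rec = preprocessing.resample(trial, settings.rate)
    rec = preprocessing.bandpass(rec, *settings.band)
    return preprocessing.epoch_segments(rec, settings.epoch_duration)


def trial_psds(epochs: list[Epoch]) -> list[spectral.PSDMatrix]:
    return [spectral.welch_psd(e) for e in epochs]


def recording_trial_psds(recording: Recording,
                         settings: AnalysisSettings = AnalysisSettings()):
    """Per-trial list of ``(true_frequency, [epoch PSDs])``."""
    out = []
    for trial_index in range(len(recording.annotations)):
        trial = crop_trial(recording, trial_index)
        freq = parse_annotation_label(trial.annotations[0][2])
        out.append((freq, trial_psds(process_trial(trial, settings))))
    return out


def decode_recording(recording: Recording,
                     settings: AnalysisSettings = AnalysisSettings()
                     ) -> list[decoding.DecodingResult]:
    """Individual decoding of every 1-s epoch of every trial."""
    results = []
    for trial_index, (freq, psds) in enumerate(
            recording_trial_psds(recording, settings)):
        for k, psd in enumerate(psds):
            results.append(decoding.decode_individual(
                psd, settings.occipital_channels, settings.candidates,
                true_frequency=freq,
                epoch_id=f"{recording.participant_id}/t{trial_index}/e{k}"))
    return results


def decode_recordings_collaborative(recordings: list[Recording],
                                    settings: AnalysisSettings = AnalysisSettings()
                                    ) -> list[decoding.DecodingResult]:
    """Collaborative decoding across participants sharing a trial
    schedule: per epoch, pool band power over all participants."""
    if not recordings:
        raise PipelineError("need at least one recording")
    per_participant = [recording_trial_psds(r, settings) for r in recordings]
    n_trials = {len(p) for p in per_participant}
    if len(n_trials) != 1:
        raise PipelineError("participants have differing trial counts")
    results = []
    for trial_index in range(n_trials.pop()):
        freqs = {p[trial_index][0] for p in per_participant}
        if len(freqs) != 1:
            raise PipelineError(
                f"trial {trial_index}: participants disagree on the target")
        freq = freqs.pop()
        n_epochs = {len(p[trial_index][1]) for p in per_participant}
        if len(n_epochs) != 1:
            raise PipelineError(
                f"trial {trial_index}: differing epoch counts")
        for k in range(n_epochs.pop()):
            psds = [p[trial_index][1][k] for p in per_participant]
            results.append(decoding.decode_collaborative(
                psds, settings.occipital_channels, settings.candidates,
                true_frequency=freq,
                epoch_id=f"group/t{trial_index}/e{k}"))
    return results


def generate_and_decode_individual(config,
                                   occipital_channels=decoding.OCCIPITAL_DEFAULT,
                                   candidates=None):
    settings = AnalysisSettings(
        occipital_channels=tuple(occipital_channels),
        candidates=tuple(candidates or config.target_frequencies))
    rec = generate_recording(config, 0)
    return decode_recording(rec, settings)


def decode_group_session(config,
                         occipital_channels=decoding.OCCIPITAL_DEFAULT,
                         candidates=None):
    """Accuracy per participant (individual decoding) and the group's
    collaborative accuracy, from one simulated session."""
    settings = AnalysisSettings(
        occipital_channels=tuple(occipital_channels),
        candidates=tuple(candidates or config.target_frequencies))
    recordings = generate_group_session(config)
    ci = [decoding.recognition_accuracy(decode_recording(r, settings))
          for r in recordings]
    cc = decoding.recognition_accuracy(
        decode_recordings_collaborative(recordings, settings))
    return ci, cc


def coupling_from_recordings(rec_a: Recording, rec_b: Recording,
                             target_frequency: float,
                             settings: AnalysisSettings = AnalysisSettings(),
                             channel_subset=None,
                             trials: str = "matching") -> coupling.CouplingResult:
    """Coupling statistic between two recordings.

    ``trials="matching"`` restricts to trials whose annotated target
    equals ``target_frequency`` (falling back to all trials when no
    annotation matches); ``trials="all"`` uses every trial.
    """
    if trials not in ("matching", "all"):
        raise PipelineError("trials must be 'matching' or 'all'")
    a_trials = recording_trial_psds(rec_a, settings)
    b_trials = recording_trial_psds(rec_b, settings)
    if trials == "matching":
        sel_a = [p for f, p in a_trials if f == target_frequency]
        sel_b = [p for f, p in b_trials if f == target_frequency]
        if not sel_a or not sel_b:
            sel_a = [p for _f, p in a_trials]
            sel_b = [p for _f, p in b_trials]
    else:
        sel_a = [p for _f, p in a_trials]
        sel_b = [p for _f, p in b_trials]
    return coupling.coupling_analysis(
        sel_a, sel_b, target_frequency, channel_subset=channel_subset,
        participant_pair=(rec_a.participant_id, rec_b.participant_id))
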