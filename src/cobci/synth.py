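"""Synthetic multi-participant SSVEP EEG generation.

Replaces a VR + amplifier acquisition stack with a controllable signal
model: per-trial occipital sinusoids at the attended flicker frequency,
superposed on 1/f ("pink") plus white Gaussian background noise, with an
optional broadband component shared across participants that induces
inter-brain band-power coupling with a single tunable gain.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError

__all__ = [
    "DEFAULT_MONTAGE_32",
    "SyntheticConfig",
    "Recording",
    "occipital_gain_profile",
    "generate_recording",
    "generate_group_session",
    "write_session",
]

#: Standard 10-20 names for a 32-channel cap; occipital sites last.
DEFAULT_MONTAGE_32 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO3", "PO4", "PO7", "PO8",
    "O1", "Oz", "O2",
)

OCCIPITAL_CHANNELS = ("O1", "O2", "Oz")

ANNOTATION_PREFIX = "target:"

# Stream-key salts: keep participant, shared and schedule substreams disjoint.
_PARTICIPANT_SALT = 1001
_SHARED_SALT = 7919


def occipital_gain_profile(channel_labels) -> np.ndarray:
    """Per-channel gain of the evoked response: 1.0 occipital, 0.3
    parietal/parieto-occipital, 0.05 elsewhere."""
    gains = []
    for label in channel_labels:
        if label in OCCIPITAL_CHANNELS:
            gains.append(1.0)
        elif label.startswith(("P", "CP")):
            gains.append(0.3)
        else:
            gains.append(0.05)
    return np.asarray(gains, dtype=np.float64)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one simulated SSVEP session.

    The defaults mirror the experimental paradigm the pipeline targets:
    three flicker frequencies (8, 10, 13 Hz), ten 10-s trials per target,
    a 32-channel 10-20 montage containing O1/O2/Oz, and acquisition at
    1 kHz.
    """

    sampling_rate: float = 1000.0
    channel_labels: tuple = DEFAULT_MONTAGE_32
    target_frequencies: tuple = (8.0, 10.0, 13.0)
    trial_duration: float = 10.0
    trials_per_target: int = 10
    ssvep_amplitude: float = 1.0
    occipital_gains: tuple | None = None  # defaults to occipital_gain_profile
    noise_amplitude: float = 1.0
    white_noise_fraction: float = 0.3
    coupling_gain: float = 0.0
    n_participants: int = 1
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        object.__setattr__(
            self, "target_frequencies",
            tuple(float(f) for f in self.target_frequencies))
        if self.occipital_gains is not None:
            object.__setattr__(
                self, "occipital_gains", tuple(self.occipital_gains))
        self.validate()

    def validate(self) -> None:
        if not self.target_frequencies:
            raise ConfigError("target_frequencies must be non-empty")
        if any(f <= 0 for f in self.target_frequencies):
            raise ConfigError("target_frequencies must be positive")
        if len(set(self.target_frequencies)) != len(self.target_frequencies):
            raise ConfigError("target_frequencies must be unique")
        if self.sampling_rate <= 2 * max(self.target_frequencies):
            raise ConfigError(
                "sampling_rate must exceed twice the maximum target "
                "frequency (Nyquist)")
        missing = [c for c in OCCIPITAL_CHANNELS if c not in self.channel_labels]
        if missing:
            raise ConfigError(
                f"channel_labels must contain O1, O2 and Oz; missing {missing}")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ConfigError("channel_labels must be unique")
        if self.coupling_gain < 0:
            raise ConfigError("coupling_gain must be >= 0")
        if self.trials_per_target < 1:
            raise ConfigError("trials_per_target must be >= 1")
        if self.trial_duration <= 0:
            raise ConfigError("trial_duration must be positive")
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if self.noise_amplitude < 0 or self.ssvep_amplitude < 0:
            raise ConfigError("amplitudes must be non-negative")
        if self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")
        if self.occipital_gains is not None and (
                len(self.occipital_gains) != len(self.channel_labels)):
            raise ConfigError(
                "occipital_gains must have one entry per channel")

    def replace(self, **changes) -> "SyntheticConfig":
        return dataclasses.replace(self, **changes)

    @property
    def n_trials(self) -> int:
        return len(self.target_frequencies) * self.trials_per_target

    def trial_schedule(self) -> list[float]:
        """Round-robin target sequence shared by every participant."""
        return [self.target_frequencies[i % len(self.target_frequencies)]
                for i in range(self.n_trials)]

    def gain_profile(self) -> np.ndarray:
        if self.occipital_gains is not None:
            return np.asarray(self.occipital_gains, dtype=np.float64)
        return occipital_gain_profile(self.channel_labels)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channel_labels"] = list(self.channel_labels)
        d["target_frequencies"] = list(self.target_frequencies)
        if self.occipital_gains is not None:
            d["occipital_gains"] = list(self.occipital_gains)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        return cls(**d)


@dataclass
class Recording:
    """A multi-channel EEG recording with trial annotations.

    ``samples`` is a channels x time float32 matrix in microvolt-like
    units; ``annotations`` is a list of ``(onset_s, duration_s, label)``
    with labels of the form ``"target:<Hz>"``.
    """

    participant_id: str
    channel_labels: tuple
    sampling_rate: float
    samples: np.ndarray
    annotations: list = field(default_factory=list)

    def __post_init__(self):
        self.channel_labels = tuple(self.channel_labels)
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 2:
            raise ConfigError("samples must be a 2-D channels x time matrix")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ConfigError(
                "samples row count must equal the number of channel labels")
        dur = self.duration
        for onset, d, _label in self.annotations:
            if onset < 0 or onset + d > dur + 1e-9:
                raise ConfigError(
                    f"annotation at {onset}s (+{d}s) lies outside [0, {dur}]s")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy(self) -> "Recording":
        return Recording(
            participant_id=self.participant_id,
            channel_labels=self.channel_labels,
            sampling_rate=self.sampling_rate,
            samples=self.samples.copy(),
            annotations=list(self.annotations),
        )


def annotation_label(frequency: float) -> str:
    return f"{ANNOTATION_PREFIX}{frequency:g}"


def parse_annotation_label(label: str) -> float:
    if not label.startswith(ANNOTATION_PREFIX):
        raise ConfigError(f"annotation label {label!r} does not encode a target")
    return float(label[len(ANNOTATION_PREFIX):])


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                sampling_rate: float) -> np.ndarray:
    """Unit-variance 1/f-shaped Gaussian noise, one row per channel.

    Shaped in the frequency domain: amplitude proportional to f^(-1/2)
    (power exponent 1), zero DC, then normalized to unit standard
    deviation per channel.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** -0.5
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size)))
    spec *= shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x / std


def _trial_noise(rng: np.random.Generator, config: SyntheticConfig,
                 n_samples: int) -> np.ndarray:
    nch = len(config.channel_labels)
    pink = _pink_noise(rng, nch, n_samples, config.sampling_rate)
    white = rng.standard_normal((nch, n_samples))
    return config.noise_amplitude * (
        pink + config.white_noise_fraction * white)


def _shared_component(config: SyntheticConfig, shared_seed: int,
                      trial_index: int, n_samples: int) -> np.ndarray:
    """Broadband component identical across participants for one trial."""
    rng = np.random.default_rng([shared_seed, _SHARED_SALT, trial_index])
    nch = len(config.channel_labels)
    return config.coupling_gain * _pink_noise(
        rng, nch, n_samples, config.sampling_rate)


def generate_recording(config: SyntheticConfig, participant_index: int = 0,
                       shared_seed: int | None = None) -> Recording:
    """Simulate one participant's full session.

    Deterministic given ``(config.seed, participant_index)``; substreams
    are keyed per trial so adding participants or trials never perturbs
    existing ones.  ``shared_seed`` selects the shared-noise stream used
    when ``coupling_gain > 0`` (defaults to ``config.seed`` so that all
    participants generated from the same config are coupled).
    """
    config.validate()
    if participant_index < 0 or participant_index >= config.n_participants:
        raise ConfigError(
            f"participant_index {participant_index} out of range for "
            f"n_participants={config.n_participants}")
    if shared_seed is None:
        shared_seed = config.seed

    n_trial = int(round(config.trial_duration * config.sampling_rate))
    t = np.arange(n_trial) / config.sampling_rate
    gains = config.gain_profile()
    schedule = config.trial_schedule()

    chunks = []
    annotations = []
    for trial_index, freq in enumerate(schedule):
        rng = np.random.default_rng(
            [config.seed, _PARTICIPANT_SALT + participant_index, trial_index])
        phase = rng.uniform(0.0, 2.0 * np.pi)
        evoked = config.ssvep_amplitude * np.sin(
            2.0 * np.pi * freq * t + phase)
        trial = gains[:, None] * evoked[None, :]
        if config.noise_amplitude > 0:
            trial = trial + _trial_noise(rng, config, n_trial)
        if config.coupling_gain > 0:
            trial = trial + _shared_component(
                config, shared_seed, trial_index, n_trial)
        chunks.append(trial)
        annotations.append((trial_index * config.trial_duration,
                            config.trial_duration, annotation_label(freq)))

    samples = np.concatenate(chunks, axis=1).astype(np.float32)
    return Recording(
        participant_id=f"P{participant_index:02d}",
        channel_labels=config.channel_labels,
        sampling_rate=config.sampling_rate,
        samples=samples,
        annotations=annotations,
    )


def generate_group_session(config: SyntheticConfig) -> list[Recording]:
    """One recording per participant, sharing the trial schedule and the
    shared-noise stream (so ``coupling_gain`` acts identically across the
    group)."""
    return [generate_recording(config, i, shared_seed=config.seed)
            for i in range(config.n_participants)]


def write_session(recordings: list[Recording], config: SyntheticConfig,
                  out_dir) -> Path:
    """Write one EDF per participant plus a JSON session manifest."""
    from . import io_formats

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for rec in recordings:
        path = out / f"{rec.participant_id}.edf"
        io_formats.write_edf(rec, path)
        files[rec.participant_id] = path.name
    manifest = {
        "participants": [rec.participant_id for rec in recordings],
        "files": files,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
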