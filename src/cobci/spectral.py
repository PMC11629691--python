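"""Welch power spectral density estimation and band-power lookup."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ChannelMismatchError, PipelineError
from .preprocessing import Epoch

__all__ = ["PSDMatrix", "welch_psd", "band_power"]


@dataclass
class PSDMatrix:
    """Per-channel PSD on a shared uniform frequency grid.

    ``power`` is channels x frequencies, in power per Hz, non-negative.
    """

    channel_labels: tuple
    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        self.channel_labels = tuple(self.channel_labels)
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.power.shape != (len(self.channel_labels),
                                self.frequencies.size):
            raise PipelineError("power must be channels x frequencies")

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def same_grid(self, other: "PSDMatrix") -> bool:
        return (self.channel_labels == other.channel_labels
                and self.frequencies.shape == other.frequencies.shape
                and bool(np.array_equal(self.frequencies, other.frequencies)))


def welch_psd(epoch: Epoch, segment_length: int | None = None,
              overlap_fraction: float = 0.5,
              window: str = "hann") -> PSDMatrix:
    """Welch PSD of one epoch.

    With ``segment_length`` equal to the epoch length (the default) this
    degenerates to a single Hann-windowed, mean-detrended periodogram,
    which puts a 1-s/512-Hz epoch on a 1 Hz grid where 8/10/13 Hz are
    exact bins.  Scaling is one-sided power density, so
    ``sum(power) * df`` approximates the signal variance.
    """
    n = epoch.n_samples
    if segment_length is None:
        segment_length = n
    if segment_length > n:
        raise PipelineError(
            f"segment_length {segment_length} exceeds epoch length {n}")
    if segment_length < 2:
        raise PipelineError("segment_length must be >= 2")
    if not (0 <= overlap_fraction < 1):
        raise PipelineError("overlap_fraction must lie in [0, 1)")
    noverlap = int(overlap_fraction * segment_length)
    freqs, power = signal.welch(
        np.asarray(epoch.samples, dtype=np.float64),
        fs=epoch.sampling_rate, window=window, nperseg=segment_length,
        noverlap=noverlap, detrend="constant", scaling="density", axis=1)
    power = np.maximum(power, 0.0)  # guard against -0.0 / rounding
    return PSDMatrix(channel_labels=epoch.channel_labels,
                     frequencies=freqs, power=power)


def band_power(psd: PSDMatrix, frequency: float) -> np.ndarray:
    """PSD value per channel at the grid bin nearest ``frequency``.

    Ties between two equidistant bins resolve toward the lower
    frequency.  On the default 1 Hz grid the paradigm targets are exact
    bins, so ties cannot occur there.
    """
    fmax = float(psd.frequencies[-1])
    if not (0 <= frequency <= fmax):
        raise PipelineError(
            f"frequency {frequency} Hz outside PSD grid [0, {fmax}] Hz")
    idx = int(np.argmin(np.abs(psd.frequencies - frequency)))
    return psd.power[:, idx].copy()


def check_shared_grid(psds: list[PSDMatrix]) -> None:
    first = psds[0]
    for p in psds[1:]:
        if not first.same_grid(p):
            raise ChannelMismatchError(
                "PSD matrices do not share channel labels and frequency grid")
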