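"""Inter-brain coupling: per-trial correlation of two participants'
channel-wise band-power vectors, Fisher-Z aggregation, and a
normal-theory significance test.

The p-value model: under the null each per-trial z is approximately
normal with variance 1/(n_channels - 3), so the mean of m independent
trials has standard error 1/sqrt(m * (n_channels - 3)); the reported
p-value is the one-sided upper tail (synchrony greater than chance).
The construction is isolated in :func:`normal_theory_p_value` so
alternatives can be swapped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (ChannelMismatchError, DegenerateVarianceError,
                     PipelineError, TrialMismatchError)
from .spectral import PSDMatrix, band_power, check_shared_grid

__all__ = [
    "CouplingResult", "trial_band_power_vector", "pearson_r",
    "fisher_z", "inverse_fisher_z", "coupling_analysis",
    "normal_theory_p_value", "R_CLAMP",
]

#: |r| is clamped to this bound before atanh so z stays finite.
R_CLAMP = 1.0 - 1e-7

#: p-values are floored here so the (0, 1] invariant survives underflow.
P_FLOOR = 1e-300

MIN_CHANNELS = 4


@dataclass
class CouplingResult:
    participant_pair: tuple
    target_frequency: float
    per_trial_r: tuple
    per_trial_z: tuple
    mean_z: float
    mean_r: float
    p_value: float
    n_channels: int

    def to_dict(self) -> dict:
        return {
            "participant_pair": list(self.participant_pair),
            "target_frequency": self.target_frequency,
            "per_trial_r": list(self.per_trial_r),
            "per_trial_z": list(self.per_trial_z),
            "mean_z": self.mean_z,
            "mean_r": self.mean_r,
            "p_value": self.p_value,
            "n_channels": self.n_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CouplingResult":
        return cls(
            participant_pair=tuple(d["participant_pair"]),
            target_frequency=d["target_frequency"],
            per_trial_r=tuple(d["per_trial_r"]),
            per_trial_z=tuple(d["per_trial_z"]),
            mean_z=d["mean_z"],
            mean_r=d["mean_r"],
            p_value=d["p_value"],
            n_channels=d["n_channels"],
        )


def trial_band_power_vector(epoch_psds: list[PSDMatrix],
                            target_frequency: float) -> np.ndarray:
    """Band power at the target frequency, averaged over a trial's
    epochs, one value per channel."""
    if not epoch_psds:
        raise PipelineError("trial has no epoch PSDs")
    check_shared_grid(epoch_psds)
    vals = np.stack([band_power(p, target_frequency) for p in epoch_psds])
    return vals.mean(axis=0)


def pearson_r(x, y) -> float:
    """Standard product-moment correlation coefficient."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise PipelineError("pearson_r needs two 1-D vectors of equal length")
    if x.size < 3:
        raise PipelineError("pearson_r needs at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateVarianceError(
            "pearson_r is undefined for a constant vector")
    r = float(xc @ yc) / (sx * sy)
    return float(min(1.0, max(-1.0, r)))


def fisher_z(r: float) -> float:
    """z = atanh(r), with |r| clamped to 1 - 1e-7 so z stays finite."""
    if abs(r) > 1.0:
        raise PipelineError(f"|r| must be <= 1, got {r}")
    return math.atanh(max(-R_CLAMP, min(R_CLAMP, r)))


def inverse_fisher_z(z: float) -> float:
    return math.tanh(z)


def normal_theory_p_value(mean_z: float, n_trials: int,
                          n_channels: int) -> float:
    """One-sided upper-tail p for the mean Fisher Z of ``n_trials``
    correlations each over ``n_channels`` points."""
    se = 1.0 / math.sqrt(n_trials * (n_channels - 3))
    p = float(stats.norm.sf(mean_z / se))
    return max(p, P_FLOOR)


def coupling_analysis(participant_a_trials: list[list[PSDMatrix]],
                      participant_b_trials: list[list[PSDMatrix]],
                      target_frequency: float,
                      channel_subset=None,
                      participant_pair=("A", "B")) -> CouplingResult:
    """Full coupling statistic for one participant pair.

    Inputs are per-trial lists of 1-s epoch PSDs.  Per trial, both
    band-power vectors are built, correlated, and Fisher-transformed;
    the mean z over trials is converted to a one-sided normal-theory
    p-value.
    """
    if len(participant_a_trials) != len(participant_b_trials):
        raise TrialMismatchError(
            f"participants have {len(participant_a_trials)} vs "
            f"{len(participant_b_trials)} trials")
    m = len(participant_a_trials)
    if m < 2:
        raise TrialMismatchError("need at least 2 trials")
    all_psds = [p for trial in (participant_a_trials + participant_b_trials)
                for p in trial]
    check_shared_grid(all_psds)
    labels = all_psds[0].channel_labels
    if channel_subset is not None:
        missing = [c for c in channel_subset if c not in labels]
        if missing:
            raise ChannelMismatchError(
                f"channel subset entries not in PSDs: {missing}")
        rows = [labels.index(c) for c in channel_subset]
    else:
        rows = list(range(len(labels)))
    if len(rows) < MIN_CHANNELS:
        raise ChannelMismatchError(
            f"need at least {MIN_CHANNELS} channels, got {len(rows)}")

    rs, zs = [], []
    for trial_a, trial_b in zip(participant_a_trials, participant_b_trials):
        va = trial_band_power_vector(trial_a, target_frequency)[rows]
        vb = trial_band_power_vector(trial_b, target_frequency)[rows]
        r = pearson_r(va, vb)
        rs.append(r)
        zs.append(fisher_z(r))
    mean_z = float(np.mean(zs))
    return CouplingResult(
        participant_pair=tuple(participant_pair),
        target_frequency=float(target_frequency),
        per_trial_r=tuple(rs),
        per_trial_z=tuple(zs),
        mean_z=mean_z,
        mean_r=inverse_fisher_z(mean_z),
        p_value=normal_theory_p_value(mean_z, m, len(rows)),
        n_channels=len(rows),
    )
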