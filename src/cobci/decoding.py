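"""SSVEP target recognition, individual and collaborative, plus the
accuracy / effect-size benchmark across decoding regimes (II / CI / CC)."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ChannelMismatchError, DegenerateVarianceError, PipelineError
from .spectral import PSDMatrix, band_power, check_shared_grid

__all__ = [
    "DecodingResult", "EffectSize", "BenchmarkResult",
    "decode_individual", "decode_collaborative",
    "recognition_accuracy", "cohens_d", "run_benchmark",
    "OCCIPITAL_DEFAULT",
]

OCCIPITAL_DEFAULT = ("O1", "O2", "Oz")


@dataclass
class DecodingResult:
    epoch_id: str
    candidate_frequencies: tuple
    pooled_power: tuple
    predicted_frequency: float
    true_frequency: float | None
    mode: str  # "individual" | "collaborative"

    @property
    def correct(self) -> bool | None:
        if self.true_frequency is None:
            return None
        return self.predicted_frequency == self.true_frequency

    def to_dict(self) -> dict:
        return {
            "epoch_id": self.epoch_id,
            "candidate_frequencies": list(self.candidate_frequencies),
            "pooled_power": list(self.pooled_power),
            "predicted_frequency": self.predicted_frequency,
            "true_frequency": self.true_frequency,
            "correct": self.correct,
            "mode": self.mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecodingResult":
        return cls(
            epoch_id=d["epoch_id"],
            candidate_frequencies=tuple(d["candidate_frequencies"]),
            pooled_power=tuple(d["pooled_power"]),
            predicted_frequency=d["predicted_frequency"],
            true_frequency=d["true_frequency"],
            mode=d["mode"],
        )


@dataclass
class EffectSize:
    """Cohen's d with the conventional magnitude label (|d| > 0.2 small,
    > 0.5 medium, > 0.8 large)."""

    d: float
    magnitude_label: str = field(init=False)

    def __post_init__(self):
        a = abs(self.d)
        if a > 0.8:
            self.magnitude_label = "large"
        elif a > 0.5:
            self.magnitude_label = "medium"
        elif a > 0.2:
            self.magnitude_label = "small"
        else:
            self.magnitude_label = "none"


def _occipital_indices(psd: PSDMatrix, occipital_channels) -> list[int]:
    idx = []
    for label in occipital_channels:
        if label not in psd.channel_labels:
            raise ChannelMismatchError(
                f"channel {label!r} not present in PSD matrix")
        idx.append(psd.channel_labels.index(label))
    return idx


def _argmax_lowest_tie(candidates, pooled) -> float:
    """Candidate with maximal pooled power; ties go to the lowest
    frequency, independent of input order."""
    order = np.argsort(candidates, kind="stable")
    best = None
    best_power = -math.inf
    for i in order:
        if pooled[i] > best_power:
            best_power = pooled[i]
            best = candidates[i]
    return float(best)


def decode_individual(psd: PSDMatrix,
                      occipital_channels=OCCIPITAL_DEFAULT,
                      candidates=(8.0, 10.0, 13.0),
                      true_frequency: float | None = None,
                      epoch_id: str = "") -> DecodingResult:
    """Argmax over candidate frequencies of band power averaged across
    the occipital channels of one participant."""
    candidates = tuple(float(c) for c in candidates)
    if not candidates:
        raise PipelineError("candidate frequency list is empty")
    rows = _occipital_indices(psd, occipital_channels)
    pooled = [float(np.mean(band_power(psd, c)[rows])) for c in candidates]
    return DecodingResult(
        epoch_id=epoch_id,
        candidate_frequencies=candidates,
        pooled_power=tuple(pooled),
        predicted_frequency=_argmax_lowest_tie(candidates, pooled),
        true_frequency=true_frequency,
        mode="individual",
    )


def decode_collaborative(psds: list[PSDMatrix],
                         occipital_channels=OCCIPITAL_DEFAULT,
                         candidates=(8.0, 10.0, 13.0),
                         true_frequency: float | None = None,
                         epoch_id: str = "") -> DecodingResult:
    """Argmax of band power pooled over occipital channels of ALL
    participants (grand mean over channels x participants).

    With a single participant this reduces exactly to
    :func:`decode_individual`.
    """
    candidates = tuple(float(c) for c in candidates)
    if not candidates:
        raise PipelineError("candidate frequency list is empty")
    if not psds:
        raise PipelineError("need at least one participant PSD")
    check_shared_grid(psds)
    rows = _occipital_indices(psds[0], occipital_channels)
    pooled = []
    for c in candidates:
        vals = [band_power(p, c)[rows] for p in psds]
        pooled.append(float(np.mean(np.concatenate(vals))))
    return DecodingResult(
        epoch_id=epoch_id,
        candidate_frequencies=candidates,
        pooled_power=tuple(pooled),
        predicted_frequency=_argmax_lowest_tie(candidates, pooled),
        true_frequency=true_frequency,
        mode="collaborative" if len(psds) > 1 else "individual",
    )


def recognition_accuracy(results: list[DecodingResult]) -> float:
    """Fraction of correct predictions, in [0, 1]."""
    if not results:
        raise PipelineError("cannot compute accuracy of an empty result list")
    flags = [r.correct for r in results]
    if any(f is None for f in flags):
        raise PipelineError("results without a true frequency cannot be scored")
    return float(sum(flags)) / len(flags)


def cohens_d(group_a, group_b) -> EffectSize:
    """Standardized mean difference (mean_a - mean_b) / pooled SD with
    (n_a - 1, n_b - 1) weighting."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise PipelineError("each group needs at least 2 values")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    pooled = math.sqrt(((a.size - 1) * va + (b.size - 1) * vb)
                       / (a.size + b.size - 2))
    diff = float(a.mean() - b.mean())
    if pooled == 0.0:
        if diff == 0.0:
            return EffectSize(d=0.0)
        raise DegenerateVarianceError(
            "pooled standard deviation is zero with unequal means; "
            "Cohen's d is undefined")
    return EffectSize(d=diff / pooled)


@dataclass
class BenchmarkResult:
    """Per-regime accuracy samples from seeded replicates."""

    accuracies: dict  # regime -> list of floats
    effect_sizes: dict  # "CC_vs_CI" / "CI_vs_II" -> EffectSize | None
    degenerate: dict  # same keys -> reason string when effect size undefined

    def mean(self, regime: str) -> float:
        return float(np.mean(self.accuracies[regime]))

    def table(self) -> str:
        lines = [f"{'regime':8s}{'n':>5s}{'mean':>9s}{'sd':>9s}"]
        for regime, vals in self.accuracies.items():
            v = np.asarray(vals)
            sd = v.std(ddof=1) if v.size > 1 else 0.0
            lines.append(
                f"{regime:8s}{v.size:5d}{v.mean():9.3f}{sd:9.3f}")
        for key, es in self.effect_sizes.items():
            if es is None:
                lines.append(f"d({key}): {self.degenerate.get(key, 'n/a')}")
            else:
                lines.append(f"d({key}): {es.d:+.3f} ({es.magnitude_label})")
        return "\n".join(lines)


def run_benchmark(config, regimes=("II", "CI", "CC"), n_replicates: int = 20,
                  occipital_channels=OCCIPITAL_DEFAULT) -> BenchmarkResult:
    """Simulate seeded sessions and compare decoding regimes.

    II: single-participant sessions, individual decoding (one accuracy
    per participant per replicate).  CI: collaborative sessions,
    individual decoding per member.  CC: collaborative sessions,
    collaborative decoding (one accuracy per replicate).  Fully
    deterministic given ``config.seed``.
    """
    from . import pipeline  # local import; pipeline depends on this module

    unknown = set(regimes) - {"II", "CI", "CC"}
    if unknown:
        raise PipelineError(f"unknown regimes {sorted(unknown)}")
    if ({"CI", "CC"} & set(regimes)) and config.n_participants < 2:
        raise PipelineError("CI/CC regimes require n_participants >= 2")

    accuracies: dict[str, list[float]] = {r: [] for r in regimes}
    candidates = config.target_frequencies

    for rep in range(n_replicates):
        if "II" in regimes:
            for p in range(config.n_participants):
                solo = config.replace(
                    n_participants=1, coupling_gain=0.0,
                    seed=config.seed + 10_000 * (rep + 1) + 101 * p)
                rec = pipeline.generate_and_decode_individual(
                    solo, occipital_channels=occipital_channels,
                    candidates=candidates)
                accuracies["II"].append(recognition_accuracy(rec))
        if {"CI", "CC"} & set(regimes):
            group_cfg = config.replace(seed=config.seed + 10_000 * (rep + 1))
            ci_accs, cc_acc = pipeline.decode_group_session(
                group_cfg, occipital_channels=occipital_channels,
                candidates=candidates)
            if "CI" in regimes:
                accuracies["CI"].extend(ci_accs)
            if "CC" in regimes:
                accuracies["CC"].append(cc_acc)

    effect_sizes: dict[str, EffectSize | None] = {}
    degenerate: dict[str, str] = {}
    for key, (ga, gb) in (("CC_vs_CI", ("CC", "CI")),
                          ("CI_vs_II", ("CI", "II"))):
        if ga in accuracies and gb in accuracies:
            va = np.var(accuracies[ga], ddof=1)
            vb = np.var(accuracies[gb], ddof=1)
            if va == 0.0 and vb == 0.0:
                effect_sizes[key] = None
                degenerate[key] = "zero variance in both groups"
                continue
            try:
                effect_sizes[key] = cohens_d(accuracies[ga], accuracies[gb])
            except DegenerateVarianceError as exc:
                effect_sizes[key] = None
                degenerate[key] = str(exc)
    return BenchmarkResult(accuracies=accuracies, effect_sizes=effect_sizes,
                           degenerate=degenerate)
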