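import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cobci.decoding import (cohens_d, decode_collaborative, decode_individual,
                            recognition_accuracy, run_benchmark)
from cobci.errors import (ChannelMismatchError, DegenerateVarianceError,
                          PipelineError)
from cobci.spectral import PSDMatrix, welch_psd
from cobci.synth import SyntheticConfig

from conftest import make_epoch, tone_epoch

OCC = ("O1", "O2", "Oz")


def psd_from_rows(rows, labels=None, df=1.0):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    labels = labels or tuple(f"C{i}" for i in range(rows.shape[0]))
    freqs = np.arange(rows.shape[1]) * df
    return PSDMatrix(channel_labels=labels, frequencies=freqs, power=rows)


def fft_decode_oracle(epoch_samples_list, channel_rows, candidates, fs):
    """Brute-force reference: mean squared FFT magnitude at candidate
    bins over the stated channels of all participants, argmax with ties
    to the lowest frequency."""
    pooled = {}
    for c in candidates:
        vals = []
        for samples in epoch_samples_list:
            x = np.asarray(samples, dtype=np.float64)
            spec = np.abs(np.fft.rfft(x, axis=1)) ** 2
            k = int(round(c * x.shape[1] / fs))
            vals.extend(spec[channel_rows, k])
        pooled[c] = float(np.mean(vals))
    best = max(sorted(pooled), key=lambda c: pooled[c])
    for c in sorted(pooled):
        if pooled[c] == pooled[best]:
            return c
    return best


class TestDecodeIndividual:
    def test_noiseless_tone_decoded(self):
        epoch = tone_epoch(8.0, n_channels=3, labels=OCC)
        res = decode_individual(welch_psd(epoch), OCC, (8.0, 10.0, 13.0))
        assert res.predicted_frequency == 8.0
        assert res.mode == "individual"

    def test_tie_breaks_to_lowest(self):
        psd = psd_from_rows(np.ones((3, 20)), labels=OCC)
        res = decode_individual(psd, OCC, (13.0, 10.0, 8.0))
        assert res.predicted_frequency == 8.0

    def test_missing_channel_named(self):
        psd = psd_from_rows(np.ones((2, 20)), labels=("O1", "O2"))
        with pytest.raises(ChannelMismatchError, match="Oz"):
            decode_individual(psd, OCC, (8.0,))

    def test_empty_candidates_rejected(self):
        psd = psd_from_rows(np.ones((3, 20)), labels=OCC)
        with pytest.raises(PipelineError, match="empty"):
            decode_individual(psd, OCC, ())

    def test_only_occipital_rows_enter_pooling(self):
        power = np.zeros((4, 20))
        power[3, 13] = 100.0  # non-occipital channel screams at 13 Hz
        power[:3, 8] = 1.0
        psd = psd_from_rows(power, labels=OCC + ("Cz",))
        res = decode_individual(psd, OCC, (8.0, 13.0))
        assert res.predicted_frequency == 8.0

    def test_matches_fft_oracle_on_noisy_epochs(self):
        # boxcar periodogram route vs an independent raw-FFT oracle
        rng = np.random.default_rng(42)
        candidates = (8.0, 10.0, 13.0)
        for _ in range(100):
            x = rng.normal(size=(3, 512))
            f = candidates[rng.integers(3)]
            t = np.arange(512) / 512.0
            x += 0.5 * np.sin(2 * np.pi * f * t)
            psd = welch_psd(make_epoch(x, labels=OCC), window="boxcar")
            res = decode_individual(psd, OCC, candidates)
            assert res.predicted_frequency == fft_decode_oracle(
                [x], [0, 1, 2], candidates, 512.0)


class TestDecodeCollaborative:
    def test_single_participant_reduction(self):
        rng = np.random.default_rng(3)
        psd = psd_from_rows(rng.uniform(size=(3, 20)), labels=OCC)
        solo = decode_individual(psd, OCC, (8.0, 10.0, 13.0))
        collab = decode_collaborative([psd], OCC, (8.0, 10.0, 13.0))
        assert collab.pooled_power == solo.pooled_power
        assert collab.predicted_frequency == solo.predicted_frequency

    def test_identical_psds_same_prediction(self):
        epoch = tone_epoch(10.0, n_channels=3, labels=OCC)
        psd = welch_psd(epoch)
        collab = decode_collaborative([psd, psd], OCC, (8.0, 10.0, 13.0))
        assert collab.predicted_frequency == 10.0
        assert collab.mode == "collaborative"

    def test_shared_signal_dominates_grand_mean(self):
        # A's noise favors 10, B's favors 13, shared 8 Hz power wins;
        # verified against arithmetic on the raw rows.
        base = np.zeros((3, 20))
        base[:, 8] = 2.0
        a = base.copy(); a[:, 10] += 1.5
        b = base.copy(); b[:, 13] += 1.5
        pa, pb = psd_from_rows(a, labels=OCC), psd_from_rows(b, labels=OCC)
        res = decode_collaborative([pa, pb], OCC, (8.0, 10.0, 13.0))
        grand = {c: (a[:, int(c)].mean() + b[:, int(c)].mean()) / 2
                 for c in (8.0, 10.0, 13.0)}
        assert res.predicted_frequency == max(sorted(grand), key=grand.get)
        assert res.predicted_frequency == 8.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        psds = [psd_from_rows(rng.uniform(size=(3, 20)), labels=OCC)
                for _ in range(3)]
        a = decode_collaborative(psds, OCC, (8.0, 10.0, 13.0))
        b = decode_collaborative(psds[::-1], OCC, (8.0, 10.0, 13.0))
        assert a.predicted_frequency == b.predicted_frequency
        assert np.allclose(a.pooled_power, b.pooled_power)

    def test_mismatched_grids_rejected(self):
        pa = psd_from_rows(np.ones((3, 20)), labels=OCC)
        pb = psd_from_rows(np.ones((3, 30)), labels=OCC)
        with pytest.raises(ChannelMismatchError):
            decode_collaborative([pa, pb], OCC, (8.0,))

    def test_matches_fft_oracle_two_participants(self):
        rng = np.random.default_rng(7)
        candidates = (8.0, 10.0, 13.0)
        for _ in range(100):
            f = candidates[rng.integers(3)]
            t = np.arange(512) / 512.0
            xs = [rng.normal(size=(3, 512))
                  + 0.4 * np.sin(2 * np.pi * f * t) for _ in range(2)]
            psds = [welch_psd(make_epoch(x, labels=OCC), window="boxcar")
                    for x in xs]
            res = decode_collaborative(psds, OCC, candidates)
            assert res.predicted_frequency == fft_decode_oracle(
                xs, [0, 1, 2], candidates, 512.0)


class TestAccuracy:
    def _result(self, pred, true):
        from cobci.decoding import DecodingResult
        return DecodingResult("e", (8.0, 10.0), (1.0, 0.0), pred, true,
                              "individual")

    def test_all_correct(self):
        assert recognition_accuracy([self._result(8.0, 8.0)] * 4) == 1.0

    def test_none_correct(self):
        assert recognition_accuracy([self._result(8.0, 10.0)] * 4) == 0.0

    def test_three_of_four(self):
        rs = [self._result(8.0, 8.0)] * 3 + [self._result(8.0, 10.0)]
        assert recognition_accuracy(rs) == 0.75

    def test_empty_rejected(self):
        with pytest.raises(PipelineError):
            recognition_accuracy([])


class TestCohensD:
    def test_identical_groups_zero(self):
        es = cohens_d([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert es.d == 0.0
        assert es.magnitude_label == "none"

    def test_degenerate_variance_error(self):
        with pytest.raises(DegenerateVarianceError):
            cohens_d([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])

    def test_small_groups_rejected(self):
        with pytest.raises(PipelineError):
            cohens_d([1.0], [0.0, 0.5])

    def test_arithmetic_oracle(self):
        a, b = [0.8, 0.9], [0.6, 0.7]
        # independent pooled-SD computation
        ma, mb = sum(a) / 2, sum(b) / 2
        sa2 = sum((x - ma) ** 2 for x in a) / 1
        sb2 = sum((x - mb) ** 2 for x in b) / 1
        pooled = ((1 * sa2 + 1 * sb2) / 2) ** 0.5
        expected = (ma - mb) / pooled
        assert cohens_d(a, b).d == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("d,label", [
        (0.1, "none"), (0.2, "none"), (0.3, "small"), (0.6, "medium"),
        (-0.9, "large")])
    def test_magnitude_labels(self, d, label):
        from cobci.decoding import EffectSize
        assert EffectSize(d=d).magnitude_label == label

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=5)
        b = rng.normal(size=7)
        assert cohens_d(a, b).d == pytest.approx(-cohens_d(b, a).d)


class TestBenchmark:
    CFG = dict(trials_per_target=1, trial_duration=3.0, sampling_rate=512.0,
               n_participants=2)

    def test_noiseless_all_regimes_perfect(self):
        cfg = SyntheticConfig(seed=1, noise_amplitude=0.0, **self.CFG)
        res = run_benchmark(cfg, n_replicates=2)
        for regime in ("II", "CI", "CC"):
            assert res.mean(regime) == 1.0
        assert res.effect_sizes["CC_vs_CI"] is None
        assert "variance" in res.degenerate["CC_vs_CI"]

    def test_deterministic(self):
        cfg = SyntheticConfig(seed=2, noise_amplitude=5.0, **self.CFG)
        a = run_benchmark(cfg, n_replicates=2)
        b = run_benchmark(cfg, n_replicates=2)
        assert a.accuracies == b.accuracies

    def test_ci_cc_require_multiple_participants(self):
        cfg = SyntheticConfig(seed=1, trials_per_target=1, trial_duration=3.0,
                              sampling_rate=512.0, n_participants=1)
        with pytest.raises(PipelineError, match="participants"):
            run_benchmark(cfg)
        res = run_benchmark(cfg, regimes=("II",), n_replicates=2)
        assert set(res.accuracies) == {"II"}
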