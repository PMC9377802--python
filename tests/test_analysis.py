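"""Burst detection, activity classification and IBI scaling-law fitting."""

import numpy as np
import pytest

from slenet.analysis import (BurstTrain, classify_activity, detect_bursts,
                             detect_spikes, fit_ibi)


def make_burst_train(onsets_s, n_spikes=4, intra_isi=12.0):
    """Synthetic spike times (ms) for bursts at the given onsets (s)."""
    times = []
    for o in onsets_s:
        times.extend(o * 1e3 + intra_isi * np.arange(n_spikes))
    return np.array(times)


class TestDetectBursts:
    def test_recovers_constructed_onsets_exactly(self):
        onsets = np.arange(10) * 1.5 + 2.0
        train = detect_bursts(make_burst_train(onsets))
        assert len(train) == 10
        assert np.allclose(train.onsets, onsets * 1e3)
        assert np.all(train.sizes == 4)

    def test_tonic_spiking_yields_no_bursts(self):
        tonic = np.arange(0, 5000.0, 50.0)  # 20 Hz for 5 s
        assert len(detect_bursts(tonic)) == 0

    def test_empty_and_singleton_inputs(self):
        assert len(detect_bursts(np.empty(0))) == 0
        assert len(detect_bursts(np.array([100.0]))) == 0

    def test_ibi_strictly_positive_and_ordered(self, reference_traces):
        train = detect_bursts(reference_traces.spike_times[2])
        assert np.all(np.diff(train.onsets) > 0)
        assert np.all(train.ibi > 0)

    def test_spike_detection_invariant_to_scale_and_offset(self):
        t = np.arange(0, 1000.0, 0.25)
        v = np.full_like(t, -65.0)
        for spike_t in (100.0, 400.0, 700.0):
            mask = np.abs(t - spike_t) < 1.0
            v[mask] = 20.0
        base = detect_spikes(t, v)
        scaled = detect_spikes(t, 0.25 * (v + 65.0) - 65.0,
                               threshold=0.25 * (-10.0 + 65.0) - 65.0)
        assert np.array_equal(base, scaled)
        assert len(base) == 3


class TestClassifyActivity:
    def test_flat_trace_is_rest(self):
        lab = classify_activity(np.empty(0), (0.0, 5e3))
        assert lab.label == "rest" and lab.n_spikes == 0

    def test_regular_20hz_is_tonic(self):
        sp = np.arange(0, 5000.0, 50.0)
        assert classify_activity(sp, (2e3, 5e3)).label == "tonic"

    def test_slow_triplet_bursts_are_bursting(self):
        sp = make_burst_train(np.arange(5.0), n_spikes=3)
        assert classify_activity(sp, (0.0, 5e3)).label == "bursting"

    def test_labels_mutually_exclusive_over_fixtures(self):
        fixtures = [np.empty(0), np.arange(0, 5000.0, 50.0),
                    make_burst_train(np.arange(5.0), n_spikes=3)]
        labels = {classify_activity(f, (0.0, 5e3)).label for f in fixtures}
        assert labels == {"rest", "tonic", "bursting"}


#: distance-to-end horizon of the synthetic burst sequences, s
LAW_T_END = 60.0


def train_from_law(law, noise=0.0, rng=None):
    """Burst onsets whose IBIs follow one of the four scaling laws.

    The law parameters are chosen so that, noise-free, every wrong
    two-parameter law misfits the sequence by far more than the 5%
    multiplicative noise used in the recovery test.
    """
    onsets = [0.0]
    while len(onsets) < 200 and onsets[-1] < LAW_T_END:
        t = onsets[-1]
        lam = max(LAW_T_END - t + 1.0, 1.0)
        if law == "linear":
            ibi = 0.15 + 0.04 * t
        elif law == "exponential":
            ibi = 0.25 + 0.02 * np.exp(0.08 * t)
        elif law == "logarithmic":
            ibi = 2.2 - 0.5 * np.log(lam)
        else:
            ibi = 0.15 + 2.0 / np.sqrt(lam)
        if noise and rng is not None:
            ibi *= 1.0 + noise * rng.normal()
        onsets.append(t + max(ibi, 0.03))
    on = np.array(onsets) * 1e3
    return BurstTrain(on, on, np.full(len(on), 3))


class TestFitIBI:
    def test_exact_linear_data_wins_with_zero_rmse(self):
        fits = fit_ibi(train_from_law("linear"))
        assert fits["linear"].rmse < 1e-10
        assert fits["best"].model == "linear"

    def test_exponential_parameter_recovery(self):
        rng = np.random.default_rng(11)
        fits = fit_ibi(train_from_law("exponential", noise=0.01, rng=rng))
        assert fits["best"].model == "exponential"
        p = fits["exponential"].params
        assert p["C"] == pytest.approx(0.08, rel=0.10)
        assert p["B"] == pytest.approx(0.02, rel=0.25)

    def test_too_few_intervals_rejected(self):
        on = np.array([0.0, 1e3, 2e3, 3e3])
        with pytest.raises(ValueError, match="at least 4"):
            fit_ibi(BurstTrain(on, on, np.full(4, 2)))

    def test_four_law_confusion_matrix(self):
        """Noise-free generated sequences from each law must be won by that
        law; with 5% multiplicative noise at least 95% of 50 replicates per
        law are classified correctly.  Selection is parsimony-corrected
        (BIC), since the three-parameter exponential nests the linear law
        and raw RMSE could never return a linear verdict under noise."""
        for law in ("linear", "exponential", "logarithmic", "inverse_sqrt"):
            fits = fit_ibi(train_from_law(law), t_end=LAW_T_END + 1.0)
            assert fits["best_bic"].model == law, f"noise-free {law}"
        rng = np.random.default_rng(7)
        correct = total = 0
        for law in ("linear", "exponential", "logarithmic", "inverse_sqrt"):
            for _ in range(50):
                fits = fit_ibi(train_from_law(law, noise=0.05, rng=rng),
                               t_end=LAW_T_END + 1.0)
                correct += fits["best_bic"].model == law
                total += 1
        assert correct / total >= 0.95

    def test_lambda_predictor_positive(self):
        train = train_from_law("logarithmic")
        fits = fit_ibi(train)
        t = (train.onsets[:-1] - train.onsets[0]) / 1e3
        lam = fits["logarithmic"].params["t_end"] - t + 1.0
        assert np.all(lam >= 1.0 - 1e-9)
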