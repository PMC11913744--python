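import numpy as np
import pandas as pd
import pytest

from intersectinfo import decoding as dec
from intersectinfo.info import plugin_mi
from intersectinfo.synthetic import OUTCOME_MAP


def _trial_table(n_lick, n_nolick, n_correct=None, n_wrong=None, p_go=0.5,
                 seed=0):
    """Trial table with the requested choice counts; outcomes consistent."""
    rng = np.random.default_rng(seed)
    choice = np.array(["Lick"] * n_lick + ["No-lick"] * n_nolick)
    n = choice.size
    if n_correct is None:
        stim = np.where(rng.random(n) < p_go, "Go", "No-go")
    else:
        correct = np.zeros(n, dtype=bool)
        correct[:n_correct] = True
        stim = np.where(correct == (choice == "Lick"), "Go", "No-go")
        stim = np.where(correct, np.where(choice == "Lick", "Go", "No-go"),
                        np.where(choice == "Lick", "No-go", "Go"))
    outcome = [OUTCOME_MAP[(s, c)] for s, c in zip(stim, choice)]
    return pd.DataFrame({
        "trial_id": range(n), "stimulus": stim, "choice": choice,
        "outcome": outcome, "onset_frame": 45 + 150 * np.arange(n),
        "offset_frame": 67 + 150 * np.arange(n), "excluded": False})


def _separable(n=80, sigma=0.05, seed=0, n_feat=4):
    rng = np.random.default_rng(seed)
    y = np.array(["Go", "No-go"])[rng.integers(0, 2, n)]
    X = rng.normal(0, sigma, (n, n_feat))
    X[y == "Go"] += 1.0
    return X, y


class TestSessionFilter:
    def test_too_few_licks_excludes_choice_decoding(self):
        trials = _trial_table(5, 80)
        assert not dec.apply_session_filter(trials, task="choice",
                                            training_session=False)
        assert dec.apply_session_filter(trials, task="stimulus",
                                        training_session=False)

    def test_boundary_counts_are_inclusive(self):
        trials = _trial_table(6, 6, n_correct=6, n_wrong=6)
        assert dec.apply_session_filter(trials, task="choice")
        assert dec.apply_session_filter(trials, task="stimulus")

    def test_too_few_wrong_trials_excludes_training_decoding(self):
        trials = _trial_table(52, 53, n_correct=100, n_wrong=5)
        assert not dec.apply_session_filter(trials, task="stimulus")

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            dec.SessionFilter(min_lick=0)


class TestDecode:
    def test_separable_data_reaches_one_bit(self):
        X, y = _separable()
        res = dec.decode(X, y)
        assert res.dec_mi == pytest.approx(1.0, abs=0.05)
        assert res.balanced_accuracy > 0.95
        assert res.confusion.sum() == 80

    def test_shuffled_labels_carry_little_information(self, rng):
        X, y = _separable()
        res = dec.decode(X, y[rng.permutation(y.size)])
        assert res.dec_mi < 0.1

    def test_dec_mi_is_plugin_mi_of_the_confusion_table(self):
        X, y = _separable(sigma=1.5)
        res = dec.decode(X, y)
        assert res.dec_mi == pytest.approx(plugin_mi(res.confusion))
        # frozen hand-evaluated value for a reference confusion table
        assert plugin_mi(np.array([[40, 10], [10, 40]])) == pytest.approx(
            0.27807, abs=1e-5)

    def test_single_class_rejected(self):
        X, _ = _separable()
        with pytest.raises(ValueError):
            dec.decode(X, np.repeat("Go", 80))

    def test_three_dim_features_are_frame_concatenated(self):
        X, y = _separable(n_feat=6)
        feats = X.reshape(80, 2, 3).transpose(1, 0, 2)  # neurons,trials,frames
        res3 = dec.decode(feats, y)
        res2 = dec.decode(X, y)
        assert res3.dec_mi == pytest.approx(res2.dec_mi)


class TestDecoderNull:
    def test_null_size_and_fov_pooling(self, rng):
        X, y = _separable(n=40)
        nulls = [dec.decoder_null(X, y, n_shuffles=10, rng=rng)
                 for _ in range(8)]
        assert all(n.shape == (10,) for n in nulls)
        assert dec.fov_null(nulls).shape == (80,)

    def test_informative_neuron_beats_its_null(self, rng):
        X, y = _separable(n=60)
        true = dec.decode(X, y, rng=rng).dec_mi
        null = dec.decoder_null(X, y, n_shuffles=10, rng=rng)
        assert true > np.percentile(null, 95)
        assert dec.classify_discriminative(true, null)

    def test_below_median_is_not_discriminative(self):
        assert not dec.classify_discriminative(0.01, np.linspace(0.02, 0.4, 50))
        assert dec.classify_discriminative(0.5, np.linspace(0.02, 0.4, 50))
        with pytest.raises(ValueError):
            dec.classify_discriminative(0.5, np.array([]))


class TestCumulativeCurve:
    def test_grid_sizes(self, rng):
        feats = rng.standard_normal((6, 60, 3))
        y = np.array(["Go", "No-go"])[rng.integers(0, 2, 60)]
        mi = rng.random(6)
        g_full, v_full = dec.cumulative_curve(feats, y, mi,
                                              grid=dec.CURVE_GRID_FULL, rng=rng)
        g_nd, v_nd = dec.cumulative_curve(feats, y, mi,
                                          grid=dec.CURVE_GRID_NONDISC, rng=rng)
        assert g_full.size == 18 and v_full.size == 18
        assert g_nd.size == 11 and v_nd.size == 11

    def test_uninformative_pool_stays_flat_near_zero(self, rng):
        feats = rng.standard_normal((5, 120, 3)) * 0.1
        y = np.array(["Go", "No-go"])[rng.integers(0, 2, 120)]
        _, v = dec.cumulative_curve(feats, y, rng.random(5), rng=rng)
        assert np.abs(v).max() < 0.12

    def test_pool_too_small_rejected(self, rng):
        feats = rng.standard_normal((5, 30, 2))
        y = np.array(["Go", "No-go"])[rng.integers(0, 2, 30)]
        with pytest.raises(ValueError):
            dec.cumulative_curve(feats, y, rng.random(5),
                                 pool=np.array([1, 0, 0, 0, 0], bool), rng=rng)


class TestPairingGain:
    def test_redundant_pool_adds_nothing(self, rng):
        X, y = _separable(n=100, sigma=0.05, n_feat=2)
        neuron = X[:, :1][None]                 # (1, trials, 1)
        pool = np.repeat(neuron, 3, axis=0)  # copies of the same signal
        gain = dec.pairing_gain(neuron, pool, y, rng=rng)
        assert abs(gain) < 0.1

    def test_complementary_pool_helps(self, rng):
        n = 120
        stim = np.array(["Go", "No-go"])[rng.integers(0, 2, n)]
        weak = rng.normal(0, 1.0, (1, n, 1))
        weak[0, stim == "Go", 0] += 1.0
        strong_pool = rng.normal(0, 0.1, (3, n, 1))
        strong_pool[:, stim == "Go", 0] += 1.0
        gain = dec.pairing_gain(weak, strong_pool, stim, rng=rng)
        assert gain > 0.2

    def test_empty_pool_is_nan(self, rng):
        X, y = _separable(n=40, n_feat=1)
        assert np.isnan(dec.pairing_gain(X[None], np.empty((0, 40, 1)), y))


class TestNoiseCorrelationGain:
    def test_independent_noise_gain_is_near_zero(self, rng):
        n = 120
        y = np.array(["Go", "No-go"])[rng.integers(0, 2, n)]
        feats = rng.normal(0, 1, (4, n, 1))
        feats[:, y == "Go"] += 0.8
        gain, null = dec.noise_correlation_gain(feats, y, n_shuffles=60,
                                                rng=rng)
        assert null.shape == (60,)
        assert abs(gain) < 0.1

    def test_signflipped_pair_with_shared_noise_benefits(self, rng):
        """Opposite tuning + positive shared noise: the difference channel is
        cleaned by correlations, so shuffling them away hurts decoding."""
        n = 160
        y = np.array(["Go", "No-go"])[rng.integers(0, 2, n)]
        s = np.where(y == "Go", 1.0, -1.0)
        shared = rng.normal(0, 1.2, n)
        feats = np.empty((2, n, 1))
        feats[0, :, 0] = s + shared + rng.normal(0, 0.2, n)
        feats[1, :, 0] = -s + shared + rng.normal(0, 0.2, n)
        gain, _ = dec.noise_correlation_gain(feats, y, n_shuffles=60, rng=rng)
        assert gain > 0.1


class TestStimulusConditionedChoiceGain:
    def test_choice_driven_by_decoded_signal_gives_positive_gain(self, rng):
        n = 200
        stim = np.array(["Go", "No-go"])[rng.integers(0, 2, n)]
        feats = rng.normal(0, 1.0, (4, n, 1))
        feats[:, stim == "Go"] += 0.8
        # choice reads the same noisy neural signal the decoder sees
        readout = feats.mean(axis=(0, 2))
        choice = np.where(readout > np.median(readout), "Lick", "No-lick")
        gain = dec.stimulus_conditioned_choice_gain(feats, stim, choice,
                                                    rng=rng)
        assert gain > 10.0

    def test_choice_independent_of_activity_gives_no_gain(self, rng):
        n = 200
        stim = np.array(["Go", "No-go"])[rng.integers(0, 2, n)]
        feats = rng.normal(0, 1.0, (4, n, 1))
        feats[:, stim == "Go"] += 0.8
        choice = np.array(["Lick", "No-lick"])[rng.integers(0, 2, n)]
        gain = dec.stimulus_conditioned_choice_gain(feats, stim, choice,
                                                    rng=rng)
        assert abs(gain) < 12.0

    def test_perfect_stimulus_decoding_returns_nan(self, rng):
        n = 60
        stim = np.array(["Go", "No-go"])[rng.integers(0, 2, n)]
        feats = np.where(stim == "Go", 5.0, -5.0)[None, :, None]
        choice = np.where(stim == "Go", "Lick", "No-lick")
        assert np.isnan(dec.stimulus_conditioned_choice_gain(
            feats, stim, choice, rng=rng))
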