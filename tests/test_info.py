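import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from intersectinfo.info import (InfoResult, JointCounts, framewise_info,
                                framewise_mi, joint_counts, mi_significance,
                                permutation_null, plugin_mi,
                                pt_bias_correction,
                                subsample_to_performance)
from intersectinfo.preprocess import TrialTensor


def _random_table(seed, shape=(2, 2), n=60):
    rng = np.random.default_rng(seed)
    return rng.multinomial(n, rng.dirichlet(np.ones(shape[0] * shape[1]))
                           ).reshape(shape)


class TestPluginMI:
    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            plugin_mi(np.zeros((2, 2), dtype=int))

    @given(st.integers(0, 2 ** 31 - 1))
    def test_symmetry_under_transposition(self, seed):
        table = _random_table(seed, (3, 4))
        assert plugin_mi(table) == pytest.approx(plugin_mi(table.T))

    @given(st.integers(0, 2 ** 31 - 1))
    def test_merging_response_bins_never_increases_mi(self, seed):
        """Data-processing inequality for deterministic bin coarsening."""
        table = _random_table(seed, (2, 4), n=100)
        merged = table.reshape(2, 2, 2).sum(axis=2)
        assert plugin_mi(merged) <= plugin_mi(table) + 1e-12

    @given(st.integers(0, 2 ** 31 - 1))
    def test_bounded_by_marginal_entropies(self, seed):
        table = _random_table(seed, (2, 2), n=80)
        def h(p):
            p = p[p > 0] / p.sum()
            return -(p * np.log2(p)).sum()
        bound = min(h(table.sum(1).astype(float)),
                    h(table.sum(0).astype(float)))
        assert 0.0 <= plugin_mi(table) <= bound + 1e-12


class TestPtCorrection:
    def test_correction_vanishes_in_large_sample_limit(self):
        table = np.array([[30, 10], [10, 30]]) * 1000
        assert pt_bias_correction(table) == pytest.approx(
            plugin_mi(table), abs=1e-4)

    def test_deterministic_channel_has_negative_estimated_bias(self):
        """Conditionally deterministic responses: R_s = 1 but R = 2, so the
        estimated bias [sum_s(R_s-1) - (R-1)]/(2N ln2) is negative and the
        corrected value exceeds the plugin value by exactly that amount."""
        table = np.array([[25, 0], [0, 25]])
        expected = 1.0 + 1.0 / (2 * 50 * np.log(2))
        assert pt_bias_correction(table) == pytest.approx(expected)

    def test_reduces_bias_under_independence(self, rng):
        """Mean |corrected| < mean plugin bias at several sample sizes."""
        for n in (20, 50, 100):
            plugs, corrs = [], []
            for _ in range(300):
                table = rng.multinomial(n, [0.25] * 4).reshape(2, 2)
                plugs.append(plugin_mi(table))
                corrs.append(pt_bias_correction(table))
            assert abs(np.mean(corrs)) < np.mean(plugs)

    def test_naive_estimator_matches_miller_madow(self):
        table = np.array([[12, 8], [9, 11]])
        n = table.sum()
        expected = plugin_mi(table) - 1.0 / (2 * n * np.log(2))
        assert pt_bias_correction(table, "naive") == pytest.approx(expected)
        # fully occupied table: PT reduces to Miller-Madow
        assert pt_bias_correction(table, "pt") == pytest.approx(expected)


def _tensor(values, frame_rate=15.0, start=0.0):
    values = np.asarray(values, dtype=float)
    end = start + values.shape[2] / frame_rate
    return TrialTensor(values=values, window_start=start, window_end=end,
                       frame_rate=frame_rate,
                       included_trials=np.arange(values.shape[1]))


class TestFramewiseMI:
    def test_independent_labels_give_near_zero_corrected_mi(self, rng):
        tensor = _tensor(rng.standard_normal((4, 400, 6)))
        labels = rng.choice(["Go", "No-go"], 400)
        _, corr = framewise_mi(tensor, labels)
        assert abs(corr.mean()) < 0.005

    def test_go_selective_neuron_has_postonset_information(self, rng):
        n_trials = 120
        labels = np.array(["Go", "No-go"])[rng.integers(0, 2, n_trials)]
        values = rng.standard_normal((1, n_trials, 10)) * 0.1
        values[0, labels == "Go", 5:] += 2.0
        plug, corr = framewise_mi(_tensor(values), labels)
        assert plug[0, :5].max() < 0.1
        assert corr[0, 5:].min() > 0.5

    def test_two_bins_never_exceed_one_bit(self, rng):
        tensor = _tensor(rng.standard_normal((3, 60, 8)))
        labels = rng.choice(["Go", "No-go"], 60)
        plug2, _ = framewise_mi(tensor, labels, n_bins=2)
        plug4, _ = framewise_mi(tensor, labels, n_bins=4)
        assert plug2.max() <= 1.0 + 1e-12
        assert plug4.max() <= 2.0 + 1e-12

    def test_label_validation(self, rng):
        tensor = _tensor(rng.standard_normal((2, 30, 4)))
        with pytest.raises(ValueError):
            framewise_mi(tensor, np.repeat("Go", 30))   # single class
        with pytest.raises(ValueError):
            framewise_mi(tensor, np.repeat("Go", 10))   # length mismatch


class TestPermutationNull:
    def test_null_shape_and_positivity(self, rng):
        tensor = _tensor(rng.standard_normal((3, 50, 6)))
        labels = rng.choice(["Go", "No-go"], 50)
        null = permutation_null(tensor, labels, n_perm=50, rng=rng)
        assert null.shape == (3, 6, 50)
        assert null.mean() > 0          # plugin bias keeps the null positive

    def test_observed_dominates_null_for_tuned_neuron(self, rng):
        labels = np.array(["Go", "No-go"])[rng.integers(0, 2, 100)]
        values = rng.standard_normal((1, 100, 5)) * 0.1
        values[0, labels == "Go"] += 2.0
        tensor = _tensor(values)
        plug, _ = framewise_mi(tensor, labels)
        null = permutation_null(tensor, labels, n_perm=50, rng=rng)
        assert plug[0].min() > np.percentile(null[0], 99)


class TestSignificance:
    def test_tuned_neuron_is_significant(self, rng):
        labels = np.array(["Go", "No-go"])[rng.integers(0, 2, 100)]
        values = rng.standard_normal((1, 100, 5)) * 0.1
        values[0, labels == "Go"] += 2.0
        res = framewise_info(_tensor(values), labels, n_perm=50, rng=rng,
                             sig_window=(0.0, 0.34))
        assert res.significant[0]
        assert res.p_value[0] == pytest.approx(1 / 51)

    def test_untuned_neuron_is_usually_not_significant(self, null_session):
        res = framewise_info(null_session["tensor"],
                             null_session["stimulus"], n_perm=50,
                             rng=np.random.default_rng(7))
        assert res.significant.mean() <= 0.25   # 16 neurons, alpha-level rate

    def test_constant_identical_series_is_not_significant(self):
        obs = np.full(5, 0.2)
        null = np.full((5, 50), 0.2)
        p, flag = mi_significance(obs, null)
        assert p == pytest.approx(1.0)
        assert not flag

    def test_window_shorter_than_two_frames_rejected(self):
        with pytest.raises(ValueError):
            mi_significance(np.array([0.1]), np.zeros((1, 10)))

    def test_result_tidy_export(self, null_session):
        res = framewise_info(null_session["tensor"], null_session["choice"],
                             n_perm=10, rng=np.random.default_rng(1))
        tidy = res.to_frame()
        assert set(tidy.columns) == {"neuron", "frame", "mi_plugin",
                                     "mi_corrected", "p", "significant"}
        assert len(tidy) == res.mi_plugin.size


class TestSubsampling:
    @staticmethod
    def _trials(n_correct, n_wrong):
        outcomes = ["Hit"] * n_correct + ["FA"] * n_wrong
        return pd.DataFrame({"outcome": outcomes})

    def test_drops_correct_trials_to_hit_target_exactly(self, rng):
        kept = subsample_to_performance(self._trials(90, 10), 0.75, rng)
        outcomes = self._trials(90, 10)["outcome"].to_numpy()[kept]
        assert kept.size == 40
        assert (outcomes == "Hit").sum() == 30

    def test_session_already_at_target_keeps_everything(self, rng):
        kept = subsample_to_performance(self._trials(75, 25), 0.75, rng)
        assert kept.size == 100

    def test_balanced_session_drops_wrong_trials(self, rng):
        """50/50 at target 0.75: keep all 50 correct plus 17 wrong."""
        kept = subsample_to_performance(self._trials(50, 50), 0.75, rng)
        outcomes = self._trials(50, 50)["outcome"].to_numpy()[kept]
        assert (outcomes == "Hit").sum() == 50
        assert (outcomes == "FA").sum() == 17

    def test_unreachable_target_raises(self, rng):
        with pytest.raises(ValueError, match="unreachable"):
            subsample_to_performance(self._trials(50, 0), 0.75, rng)

    def test_independent_draws_differ(self):
        t = self._trials(90, 10)
        a = subsample_to_performance(t, 0.75, np.random.default_rng(1))
        b = subsample_to_performance(t, 0.75, np.random.default_rng(2))
        assert not np.array_equal(a, b)
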