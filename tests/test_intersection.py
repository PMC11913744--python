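import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from intersectinfo.info import plugin_mi
from intersectinfo.intersection import (TrivariateCounts, coinformation,
                                        ii_framewise, ii_ratio,
                                        intersection_information, pid_oracle,
                                        shared_info, trivariate_counts)


def _chain():
    """S uniform binary, R = S, C = R: fully redundant 1-bit chain."""
    p = np.zeros((2, 2, 2))
    p[0, 0, 0] = p[1, 1, 1] = 0.5
    return p


def _independent():
    return np.ones((2, 2, 2)) / 8.0


def _random_dist(seed, size=8, shape=(2, 2, 2)):
    return np.random.default_rng(seed).dirichlet(np.ones(size)).reshape(shape)


class TestSharedInfo:
    def test_redundant_chain_gives_one_bit(self):
        assert shared_info(_chain(), "C") == pytest.approx(1.0, abs=1e-9)
        assert shared_info(_chain(), "S") == pytest.approx(1.0, abs=1e-9)

    def test_mutual_independence_gives_zero(self):
        assert shared_info(_independent(), "C") == pytest.approx(0.0, abs=1e-9)
        assert shared_info(_independent(), "S") == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("target", ["C", "S"])
    def test_matches_exhaustive_oracle(self, seed, target):
        p = _random_dist(seed)
        si = shared_info(p, target)
        oracle = pid_oracle(p, 0.02, target=target, refine=4)
        assert si == pytest.approx(oracle, abs=1e-3)

    def test_matches_oracle_on_four_response_bins(self):
        p = _random_dist(123, size=16, shape=(2, 4, 2))
        for target in ("C", "S"):
            si = shared_info(p, target)
            oracle = pid_oracle(p, 0.25, target=target, refine=3)
            assert si == pytest.approx(oracle, abs=1e-3)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25)
    def test_never_below_empirical_coinformation(self, seed):
        """p is feasible, so the maximum is at least CoI(p)."""
        p = _random_dist(seed)
        for target in ("C", "S"):
            assert shared_info(p, target) >= coinformation(p) - 1e-9


class TestOracle:
    def test_refinement_is_monotone(self):
        p = _random_dist(5)
        vals = [pid_oracle(p, s) for s in (0.08, 0.04, 0.02)]
        assert vals[0] <= vals[1] + 1e-12 <= vals[2] + 2e-12

    def test_empirical_distribution_is_in_feasible_set(self):
        p = _random_dist(6)
        assert pid_oracle(p, 0.05) >= coinformation(p) - 1e-9

    def test_large_alphabet_refused(self):
        with pytest.raises(ValueError, match="too large"):
            pid_oracle(np.ones((3, 3, 3)) / 27.0, 0.1)


class TestIntersectionInformation:
    def test_deterministic_chain(self):
        res = intersection_information(_chain())
        assert res.ii == pytest.approx(1.0, abs=1e-9)
        assert res.ii_over_mirs == pytest.approx(1.0, abs=1e-9)

    def test_random_choice_forces_zero_ii(self):
        """R informative about S but C independent: MI(R;C)=0 bounds II at 0."""
        p = np.zeros((2, 2, 2))
        p[0, 0], p[1, 1] = 0.25, 0.25   # R = S, C uniform independent
        res = intersection_information(p)
        assert res.mi_rs == pytest.approx(1.0)
        assert res.mi_rc == pytest.approx(0.0, abs=1e-12)
        assert res.ii == pytest.approx(0.0, abs=1e-9)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25)
    def test_ii_bounded_by_both_mutual_informations(self, seed):
        p = _random_dist(seed)
        res = intersection_information(p)
        assert 0.0 <= res.ii <= min(res.mi_rs, res.mi_rc) + 1e-12
        assert res.ii == pytest.approx(min(res.si_c_sr, res.si_s_cr),
                                       abs=1e-9) or res.clipped

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=15)
    def test_ii_invariant_under_response_relabeling(self, seed):
        p = _random_dist(seed)
        flipped = p[:, ::-1, :]
        assert intersection_information(p).ii == pytest.approx(
            intersection_information(flipped).ii, abs=1e-7)


class TestIIRatio:
    def test_limits(self):
        assert ii_ratio(0.3, 0.3) == 1.0
        assert ii_ratio(0.0, 0.3) == 0.0
        assert np.isnan(ii_ratio(0.1, 0.0))

    def test_clipped_into_unit_interval(self):
        assert ii_ratio(0.31, 0.3) == 1.0


class TestTrivariateCounts:
    def test_counting_and_marginal_consistency(self, rng):
        s = rng.choice(["Go", "No-go"], 200)
        c = rng.choice(["Lick", "No-lick"], 200)
        r = rng.integers(0, 2, 200)
        tc = trivariate_counts(s, r, c)
        assert tc.n == 200
        np.testing.assert_array_equal(
            tc.counts.sum(axis=(1, 2)),
            [(s == "Go").sum(), (s == "No-go").sum()])
        # bivariate marginal matches plugin MI computed directly
        mi_sc_direct = plugin_mi(tc.counts.sum(axis=1))
        assert mi_sc_direct >= 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            TrivariateCounts(counts=np.array([[[-1, 1], [1, 1]],
                                              [[1, 1], [1, 1]]]))


class TestFramewiseII:
    def test_preonset_ii_sits_at_null_level(self, stage3_tensor):
        """Before stimulus onset there is no stimulus information, hence no II."""
        tensor = stage3_tensor["tensor"]
        res = ii_framewise(tensor, stage3_tensor["stimulus"],
                           stage3_tensor["choice"], n_perm=20,
                           rng=np.random.default_rng(0))
        t = tensor.frame_times()
        pre = res.ii_corrected[:, t < -0.5]
        post = res.ii_corrected[:, (t >= 0.2) & (t < 1.0)]
        assert abs(pre.mean()) < 0.01
        assert post.mean() > 3 * abs(pre.mean())

    def test_bounds_hold_on_every_neuron_and_frame(self, stage3_tensor):
        res = ii_framewise(stage3_tensor["tensor"], stage3_tensor["stimulus"],
                           stage3_tensor["choice"], n_perm=10,
                           rng=np.random.default_rng(1))
        bound = np.minimum(res.mi_rs, res.mi_rc)
        assert (res.ii_raw >= -1e-12).all()
        assert (res.ii_raw <= bound + 1e-9).all()
        assert (res.ii_corrected <= res.ii_raw + 1e-12).all()
        ratios = res.ii_over_mirs[np.isfinite(res.ii_over_mirs)]
        assert ((ratios >= 0) & (ratios <= 1)).all()

    def test_null_shape_and_mislabel_rejection(self, stage3_tensor):
        tensor = stage3_tensor["tensor"]
        res = ii_framewise(tensor, stage3_tensor["stimulus"],
                           stage3_tensor["choice"], n_perm=10,
                           rng=np.random.default_rng(2))
        assert res.null_ii.shape == (tensor.values.shape[0], 15, 10)
        with pytest.raises(ValueError):
            ii_framewise(tensor, stage3_tensor["stimulus"][:-1],
                         stage3_tensor["choice"], n_perm=5)
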