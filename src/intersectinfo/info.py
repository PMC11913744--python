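"""Frame-by-frame Shannon mutual information with limited-sampling bias
correction, permutation nulls and significance calls.

MI between a discretized single-trial response r and a trial label s
(stimulus Go/No-go, or choice Lick/No-lick) is the plugin estimate

    MI(S;R) = sum_{s,r} p(s,r) log2[ p(s,r) / (p(s) p(r)) ]

computed from contingency counts across trials, independently at each frame.
The plugin estimator is positively biased at finite trial counts; the
Panzeri-Treves (PT) procedure subtracts an analytic estimate of that bias
built from Bayesian estimates of the number of effectively occupied response
bins.  Significance is assessed per neuron against label permutations applied
consistently across time points, via a Kruskal-Wallis rank test between the
observed and permuted MI values in the first second after stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import TrialTensor, discretize_framewise
from .synthetic import CORRECT_OUTCOMES

__all__ = [
    "JointCounts", "InfoResult", "joint_counts", "plugin_mi",
    "pt_bias_correction", "framewise_mi", "permutation_null",
    "mi_significance", "framewise_info", "subsample_to_performance",
]

LN2 = np.log(2.0)


@dataclass
class JointCounts:
    """S-by-R contingency counts over trials."""

    counts: np.ndarray
    labels: tuple = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 2-D table")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class InfoResult:
    """Per-neuron, per-frame MI with nulls and a single significance call."""

    mi_plugin: np.ndarray        # neurons x frames, bits
    mi_corrected: np.ndarray     # neurons x frames, bits
    null_mi: np.ndarray          # neurons x window-frames x n_perm (plugin)
    window_frames: np.ndarray    # frame indices the null/test were run on
    p_value: np.ndarray          # per neuron
    significant: np.ndarray      # per neuron, at alpha

    def to_frame(self) -> pd.DataFrame:
        """Tidy (neuron, frame, mi_plugin, mi_corrected, p, significant)."""
        j, f = self.mi_plugin.shape
        jj, ff = np.meshgrid(np.arange(j), np.arange(f), indexing="ij")
        return pd.DataFrame({
            "neuron": jj.ravel(), "frame": ff.ravel(),
            "mi_plugin": self.mi_plugin.ravel(),
            "mi_corrected": self.mi_corrected.ravel(),
            "p": np.repeat(self.p_value, f),
            "significant": np.repeat(self.significant, f),
        })


def joint_counts(labels: np.ndarray, responses: np.ndarray) -> JointCounts:
    """Contingency table between per-trial labels and discretized responses."""
    s_cats, s_idx = np.unique(labels, return_inverse=True)
    r_cats, r_idx = np.unique(responses, return_inverse=True)
    counts = np.zeros((s_cats.size, r_cats.size), dtype=np.int64)
    np.add.at(counts, (s_idx, r_idx), 1)
    return JointCounts(counts=counts, labels=(tuple(s_cats), tuple(r_cats)))


def _mi_from_counts(counts: np.ndarray) -> np.ndarray:
    """Plugin MI in bits for stacked tables (..., S, R); 0*log0 := 0."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=(-2, -1), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / n
        ps = p.sum(axis=-1, keepdims=True)
        pr = p.sum(axis=-2, keepdims=True)
        terms = p * np.log2(p / (ps * pr))
    return np.nansum(terms, axis=(-2, -1))


def plugin_mi(jc: JointCounts | np.ndarray) -> float:
    """Plugin MI of one contingency table, in bits."""
    counts = jc.counts if isinstance(jc, JointCounts) else np.asarray(jc)
    if counts.sum() < 1:
        raise ValueError("empty contingency table")
    return float(_mi_from_counts(counts))


def _pt_bayescount(probs: np.ndarray, n: int) -> int:
    """PT Bayesian estimate of the number of relevant (occupiable) bins.

    Starts from the naive occupied-bin count and asks how many additional
    bins, given n samples and a small Bayesian occupancy estimate, would make
    the expected number of occupied bins match the observation.  With every
    bin well occupied it returns the naive count, so the MI bias estimate
    reduces to Miller-Madow.
    """
    probs = np.asarray(probs, dtype=float)
    dim = probs.size
    nz = probs[probs > np.finfo(float).eps]
    r_naive = nz.size
    if r_naive >= dim or n == 0:
        return r_naive
    delta_prev = float(dim)
    delta = abs(r_naive - (r_naive - ((1.0 - nz) ** n).sum()))
    xtr = 0.0
    while delta < delta_prev and r_naive + xtr < dim:
        xtr += 1.0
        gamma = xtr * (1.0 - (n / (n + r_naive)) ** (1.0 / n))
        p_bayes_occ = ((1.0 - gamma) / (n + r_naive)) * (nz * n + 1.0)
        expected = (1.0 - (1.0 - p_bayes_occ) ** n).sum()
        expected += xtr * (1.0 - (1.0 - gamma / xtr) ** n)
        delta_prev = delta
        delta = abs(r_naive - expected)
    extra = xtr - 1.0 if delta >= delta_prev else xtr
    return int(r_naive + max(extra, 0.0))


def _pt_bias(counts: np.ndarray, estimator: str = "pt") -> float:
    """Estimated limited-sampling bias of plugin MI, in bits.

    bias = [sum_s (R_s - 1) - (R - 1)] / (2 N ln 2), with R_s, R either the
    PT Bayesian bin estimates (default) or the naive occupied-bin counts
    (``estimator="naive"``, the Miller-Madow correction).
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < np.count_nonzero(counts):
        raise ValueError("fewer samples than occupied cells")
    occupied_rows = [row for row in counts if row.sum() > 0]
    if estimator == "naive":
        r_s = [np.count_nonzero(row) for row in occupied_rows]
        r_tot = np.count_nonzero(counts.sum(axis=0))
    elif estimator == "pt":
        r_s = [_pt_bayescount(row / row.sum(), int(row.sum()))
               for row in occupied_rows]
        pr = counts.sum(axis=0) / n
        r_tot = _pt_bayescount(pr, int(n))
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return (sum(r - 1 for r in r_s) - (r_tot - 1)) / (2.0 * n * LN2)


def pt_bias_correction(jc: JointCounts | np.ndarray,
                       estimator: str = "pt") -> float:
    """Bias-corrected MI (plugin minus the PT bias estimate), in bits.

    Slightly negative values are possible and expected under independence.
    """
    counts = jc.counts if isinstance(jc, JointCounts) else np.asarray(jc)
    return plugin_mi(counts) - _pt_bias(counts, estimator)


def _framewise_counts(discrete: np.ndarray, label_idx: np.ndarray,
                      n_s: int, n_bins: int) -> np.ndarray:
    """Joint counts per neuron and frame: (neurons, frames, S, R)."""
    n_neurons, n_trials, n_frames = discrete.shape
    onehot = np.zeros((n_trials, n_s))
    onehot[np.arange(n_trials), label_idx] = 1.0
    counts = np.empty((n_neurons, n_frames, n_s, n_bins))
    for b in range(n_bins):
        counts[..., b] = np.einsum("jtf,ts->jfs", discrete == b, onehot)
    return counts


def framewise_mi(tensor: TrialTensor, labels: np.ndarray, n_bins: int = 2,
                 estimator: str = "pt",
                 already_discrete: bool = False
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Plugin and PT-corrected MI per neuron and frame, in bits.

    Responses are discretized into equipopulated bins across trials,
    independently at each frame, then tabulated against the per-trial labels
    (stimulus for MI(R;S), choice for MI(R;C)).
    """
    labels = np.asarray(labels)
    if labels.size != tensor.values.shape[1]:
        raise ValueError("labels length must equal the number of included trials")
    cats, label_idx = np.unique(labels, return_inverse=True)
    if cats.size < 2:
        raise ValueError("labels must contain at least two classes")
    binned = np.bincount(label_idx)
    if (binned == 0).any():
        raise ValueError("every label class needs at least one trial")
    discrete = discretize_framewise(tensor.values, n_bins, already_discrete)
    n_cat = int(discrete.max()) + 1 if already_discrete else n_bins
    counts = _framewise_counts(discrete, label_idx, cats.size, n_cat)
    mi_plugin = _mi_from_counts(counts)
    mi_corr = np.empty_like(mi_plugin)
    for j in range(counts.shape[0]):
        for f in range(counts.shape[1]):
            mi_corr[j, f] = mi_plugin[j, f] - _pt_bias(counts[j, f], estimator)
    return mi_plugin, mi_corr


def permutation_null(tensor: TrialTensor, labels: np.ndarray,
                     n_perm: int = 50,
                     rng: np.random.Generator | None = None,
                     n_bins: int = 2, frames: np.ndarray | None = None,
                     already_discrete: bool = False) -> np.ndarray:
    """Plugin MI under trial permutations: (neurons, frames, n_perm).

    Each permutation draws one random trial ordering and applies it at every
    time point, which destroys the response-label association while keeping
    the within-trial autocorrelation of the fluorescence intact.  Null values
    are deliberately not bias-corrected (the observed values they are ranked
    against are the uncorrected ones).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng() if rng is None else rng
    labels = np.asarray(labels)
    cats, label_idx = np.unique(labels, return_inverse=True)
    values = tensor.values if frames is None else tensor.values[:, :, frames]
    discrete = discretize_framewise(values, n_bins, already_discrete)
    n_cat = int(discrete.max()) + 1 if already_discrete else n_bins
    n_neurons, n_trials, n_frames = discrete.shape
    null = np.empty((n_neurons, n_frames, n_perm))
    for k in range(n_perm):
        perm = rng.permutation(n_trials)
        counts = _framewise_counts(discrete, label_idx[perm], cats.size, n_cat)
        null[:, :, k] = _mi_from_counts(counts)
    return null


def mi_significance(observed: np.ndarray, null: np.ndarray,
                    alpha: float = 0.05) -> tuple[float, bool]:
    """Rank-permutation test of observed vs permuted MI in the test window.

    ``observed``: per-frame plugin MI inside the window (>= 2 frames);
    ``null``: frames x n_perm permuted values.  All values are pooled and
    midranked; the mean rank of the observed window (the per-group
    Kruskal-Wallis statistic) is then compared against the identical
    statistic of every permutation column, giving the one-sided exact
    permutation p-value (1 + #{perm >= observed}) / (n_perm + 1).  Because
    each permutation column shares the observed window's within-window
    autocorrelation, the test is exact under exchangeability — pooling the
    null values into a plain two-sample rank test is not, and is
    anticonservative for slow-indicator data.  Significance additionally
    requires the observed median to exceed the null median (an MI deficit is
    not information).
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if observed.size < 2:
        raise ValueError("significance window must span at least 2 frames")
    if null.ndim != 2 or null.shape[0] != observed.size:
        raise ValueError("null must be (window frames, n_perm)")
    n_perm = null.shape[1]
    pooled = np.concatenate([observed[:, None], null], axis=1)
    ranks = stats.rankdata(pooled.ravel()).reshape(pooled.shape)
    col_stat = ranks.mean(axis=0)
    p = (1.0 + np.sum(col_stat[1:] >= col_stat[0])) / (n_perm + 1.0)
    flag = bool(p < alpha and np.median(observed) > np.median(null))
    return float(p), flag


def framewise_info(tensor: TrialTensor, labels: np.ndarray, n_bins: int = 2,
                   n_perm: int = 50,
                   rng: np.random.Generator | None = None,
                   sig_window: tuple[float, float] = (0.0, 1.0),
                   alpha: float = 0.05, estimator: str = "pt",
                   already_discrete: bool = False) -> InfoResult:
    """Full single-neuron information analysis for one label set.

    MI is computed at every frame of the tensor; the permutation null and the
    per-neuron significance call are restricted to ``sig_window`` (seconds
    relative to stimulus onset, default the first second — quantitative
    claims stop before the response window opens).
    """
    rng = np.random.default_rng() if rng is None else rng
    mi_plugin, mi_corr = framewise_mi(tensor, labels, n_bins, estimator,
                                      already_discrete)
    win = tensor.frames_in(*sig_window)
    if win.size < 2:
        raise ValueError("significance window shorter than 2 frames")
    null = permutation_null(tensor, labels, n_perm, rng, n_bins, frames=win,
                            already_discrete=already_discrete)
    n_neurons = mi_plugin.shape[0]
    p_value = np.empty(n_neurons)
    significant = np.empty(n_neurons, dtype=bool)
    for j in range(n_neurons):
        p_value[j], significant[j] = mi_significance(
            mi_plugin[j, win], null[j], alpha)
    return InfoResult(mi_plugin=mi_plugin, mi_corrected=mi_corr,
                      null_mi=null, window_frames=win,
                      p_value=p_value, significant=significant)


def subsample_to_performance(trials: pd.DataFrame, target: float = 0.75,
                             rng: np.random.Generator | None = None
                             ) -> np.ndarray:
    """Trial subset equalizing behavioral performance at ``target``.

    Drops random trials from the over-represented correctness class until the
    fraction correct is as close to the target as the counts allow (ties are
    broken toward dropping fewer trials).  Meant to be drawn independently
    per neuron, so that equalized information values are not tied to one
    particular subsample.
    """
    rng = np.random.default_rng() if rng is None else rng
    correct_mask = trials["outcome"].isin(CORRECT_OUTCOMES).to_numpy()
    idx_correct = np.flatnonzero(correct_mask)
    idx_wrong = np.flatnonzero(~correct_mask)
    n_c, n_w = idx_correct.size, idx_wrong.size
    current = n_c / (n_c + n_w)

    def _best_k(num_fixed: int, n_var: int, fixed_is_correct: bool) -> int:
        # choose k of the variable class minimizing |achieved - target|
        if fixed_is_correct:
            frac = lambda k: num_fixed / (num_fixed + k) if num_fixed + k else 0.0
        else:
            frac = lambda k: k / (num_fixed + k) if num_fixed + k else 0.0
        ks = np.arange(1, n_var + 1)
        errs = np.array([abs(frac(k) - target) for k in ks])
        best = errs.min()
        return int(ks[np.flatnonzero(errs == best)[-1]])  # tie: keep more

    if np.isclose(current, target):
        return np.arange(len(trials))
    if current > target:
        if n_w == 0 and target < 1.0:
            raise ValueError("target performance unreachable: no wrong trials")
        k_c = _best_k(n_w, n_c, fixed_is_correct=False)
        keep_c = rng.choice(idx_correct, size=k_c, replace=False)
        kept = np.concatenate([keep_c, idx_wrong])
    else:
        if n_c == 0 and target > 0.0:
            raise ValueError("target performance unreachable: no correct trials")
        k_w = _best_k(n_c, n_w, fixed_is_correct=True)
        keep_w = rng.choice(idx_wrong, size=k_w, replace=False)
        kept = np.concatenate([idx_correct, keep_w])
    return np.sort(kept)
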