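"""Intersection information (II) via partial information decomposition.

II quantifies the part of the stimulus information carried by a neural
response that is actually read out into the behavioral choice.  It is the
minimum of two shared-information (redundancy) terms:

    SI(C;{S;R}) = max over q preserving p(s,c), p(r,c) of CoI_q(S;R;C)
    SI(S;{C;R}) = max over q preserving p(s,c), p(s,r) of CoI_q(S;R;C)

where CoI is the co-information.  Because the co-information can be written
as I(S;C) - I(S;C|R) and I_q(S;C) is pinned by the preserved p(s,c) marginal
in both programs, each maximization is equivalent to *minimizing* the
conditional mutual information I_q(S;C|R) over a product of per-group
transportation polytopes — a convex program.  The solver here performs exact
coordinate descent along the 2x2-minor directions of those polytopes (each
line search is a monotone scalar root-find), batched over many tables at
once so that per-frame permutation nulls remain tractable.  An exhaustive
grid oracle over the same polytope provides the independent cross-check.

II is non-negative and bounded by both MI(R;S) and MI(R;C), which makes the
readout-efficiency ratio II/MI(R;S) a meaningful quantity in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .info import _mi_from_counts, mi_significance
from .preprocess import TrialTensor, discretize_framewise

__all__ = [
    "TrivariateCounts", "IIResult", "FramewiseIIResult", "trivariate_counts",
    "shared_info", "pid_oracle", "intersection_information", "ii_ratio",
    "ii_framewise", "coinformation",
]

_TINY = 1e-300


@dataclass
class TrivariateCounts:
    """S x R x C contingency counts over trials."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 3-D array")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def probabilities(self) -> np.ndarray:
        n = self.counts.sum()
        if n == 0:
            raise ValueError("empty trivariate table")
        return self.counts / n


@dataclass
class IIResult:
    """Shared-information terms and their minimum for one trivariate table."""

    si_c_sr: float          # SI(C;{S;R}), bits
    si_s_cr: float          # SI(S;{C;R}), bits
    ii: float               # min of the two, clipped into its bounds
    mi_rs: float            # MI(R;S) of the table, bits
    mi_rc: float            # MI(R;C), bits
    ii_over_mirs: float     # readout efficiency, NaN when MI(R;S) <= 0
    clipped: bool           # whether the bound clip changed the value


@dataclass
class FramewiseIIResult:
    """Per-neuron, per-frame II with permutation nulls and significance."""

    ii_raw: np.ndarray           # neurons x frames
    ii_corrected: np.ndarray     # shuffle-subtracted, clipped at 0
    si_c_sr: np.ndarray
    si_s_cr: np.ndarray
    mi_rs: np.ndarray            # plugin MI(R;S) per neuron/frame
    mi_rc: np.ndarray
    ii_over_mirs: np.ndarray     # NaN where MI(R;S) <= 0
    null_ii: np.ndarray          # neurons x window-frames x n_perm
    window_frames: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray


def trivariate_counts(stimulus: np.ndarray, responses: np.ndarray,
                      choice: np.ndarray) -> TrivariateCounts:
    s_cats, s_idx = np.unique(stimulus, return_inverse=True)
    r_cats, r_idx = np.unique(responses, return_inverse=True)
    c_cats, c_idx = np.unique(choice, return_inverse=True)
    counts = np.zeros((s_cats.size, r_cats.size, c_cats.size), dtype=np.int64)
    np.add.at(counts, (s_idx, r_idx, c_idx), 1)
    return TrivariateCounts(counts=counts)


# ---------------------------------------------------------------------------
# entropic helpers (all batched over leading axes; p need not be normalized)

def _xlogx(x: np.ndarray) -> np.ndarray:
    return x * np.log(np.maximum(x, _TINY))


def _cond_mi_scr(q: np.ndarray) -> np.ndarray:
    """I(S;C|R) in bits for stacked (..., S, R, C) distributions."""
    q_r = q.sum(axis=(-3, -1))
    q_sr = q.sum(axis=-1)
    q_rc = q.sum(axis=-3)
    h = (_xlogx(q).sum(axis=(-3, -2, -1)) + _xlogx(q_r).sum(axis=-1)
         - _xlogx(q_sr).sum(axis=(-2, -1)) - _xlogx(q_rc).sum(axis=(-2, -1)))
    return h / np.log(2.0)


def _mi_sc(q: np.ndarray) -> np.ndarray:
    """I(S;C) in bits for stacked (..., S, R, C) distributions."""
    return _mi_from_counts(q.sum(axis=-2))


def coinformation(q: np.ndarray) -> np.ndarray:
    """Co-information I(S;C) - I(S;C|R) for stacked (..., S, R, C) tables."""
    return _mi_sc(q) - _cond_mi_scr(q)


# ---------------------------------------------------------------------------
# batched convex solver

def _ln(x: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(x, _TINY))


def _objective(q: np.ndarray) -> np.ndarray:
    """sum q ln q - sum_ab Q ln Q (nats) for q of shape (B, K, A, Bb)."""
    return _xlogx(q).sum(axis=(1, 2, 3)) - _xlogx(q.sum(axis=1)).sum(axis=(1, 2))


def _g_gp(t, q11, q12, q21, q22, Q11, Q12, Q21, Q22):
    g = (_ln(q11 + t) + _ln(q22 + t) - _ln(q12 - t) - _ln(q21 - t)
         - _ln(Q11 + t) - _ln(Q22 + t) + _ln(Q12 - t) + _ln(Q21 - t))
    gp = (1.0 / np.maximum(q11 + t, _TINY) + 1.0 / np.maximum(q22 + t, _TINY)
          + 1.0 / np.maximum(q12 - t, _TINY) + 1.0 / np.maximum(q21 - t, _TINY)
          - 1.0 / np.maximum(Q11 + t, _TINY) - 1.0 / np.maximum(Q22 + t, _TINY)
          - 1.0 / np.maximum(Q12 - t, _TINY) - 1.0 / np.maximum(Q21 - t, _TINY))
    return g, gp


def _line_search(q11, q12, q21, q22, Q11, Q12, Q21, Q22) -> np.ndarray:
    """Exact minimizer t of the objective along a 2x2-minor direction.

    The move adds t to the (1,1)/(2,2) cells and subtracts it from the
    (1,2)/(2,1) cells, within one group block (q) and its across-group sums
    (Q).  The directional derivative g(t) is monotone increasing and runs
    from -inf to +inf over the feasible interval, so the root is found by a
    bracketed Newton iteration.  Batched: all arguments are batch vectors;
    entries already stationary along this direction are filtered out up
    front, which is what keeps late sweeps cheap.
    """
    lo = -np.minimum(q11, q22)
    hi = np.minimum(q12, q21)
    width = hi - lo
    t_out = np.zeros_like(q11)
    open_dir = width > 1e-15
    if not open_dir.any():
        return t_out
    g0, gp0 = _g_gp(np.zeros_like(q11), q11, q12, q21, q22,
                    Q11, Q12, Q21, Q22)
    sel = np.flatnonzero(open_dir & (np.abs(g0) > 1e-12))
    if sel.size == 0:
        return t_out
    args = [a[sel] for a in (q11, q12, q21, q22, Q11, Q12, Q21, Q22)]
    lo, hi, width = lo[sel], hi[sel], width[sel]
    t = np.clip(-g0[sel] / np.maximum(gp0[sel], _TINY),
                lo + 1e-3 * width, hi - 1e-3 * width)
    t_lo, t_hi = lo, hi
    for _ in range(40):
        g, gp = _g_gp(t, *args)
        t_lo = np.where(g < 0, t, t_lo)
        t_hi = np.where(g > 0, t, t_hi)
        t_new = t - np.where(gp > 0, g / np.maximum(gp, _TINY), 0.0)
        outside = (t_new <= t_lo) | (t_new >= t_hi)
        t_new = np.where(outside, 0.5 * (t_lo + t_hi), t_new)
        moved = np.max(np.abs(t_new - t), initial=0.0)
        t = t_new
        if moved < 1e-14:
            break
    t_out[sel] = t
    return t_out


def _minimize_transport(tables: np.ndarray, tol: float = 1e-11,
                        max_sweeps: int = 400) -> np.ndarray:
    """Minimize sum q ln q - sum_ab Q ln Q over per-group (A,B) margins.

    ``tables``: (B, K, A, Bb) probability arrays; per-group row/column sums
    are the preserved marginals.  Returns the optimizing q (same shape).
    Exact cyclic coordinate descent over all 2x2 minors of every group block;
    the objective is convex, so no restarts are needed.
    """
    q = np.array(tables, dtype=float)
    B, K, A, Bb = q.shape
    minors = [(a1, a2, b1, b2)
              for a1, a2 in combinations(range(A), 2)
              for b1, b2 in combinations(range(Bb), 2)]
    active = np.arange(B)
    prev = _objective(q)
    while_sweeps = 0
    while active.size and while_sweeps < max_sweeps:
        while_sweeps += 1
        qa = q[active]
        Qa = qa.sum(axis=1)
        for k in range(K):
            for a1, a2, b1, b2 in minors:
                t = _line_search(
                    qa[:, k, a1, b1], qa[:, k, a1, b2],
                    qa[:, k, a2, b1], qa[:, k, a2, b2],
                    Qa[:, a1, b1], Qa[:, a1, b2],
                    Qa[:, a2, b1], Qa[:, a2, b2])
                qa[:, k, a1, b1] += t
                qa[:, k, a2, b2] += t
                qa[:, k, a1, b2] -= t
                qa[:, k, a2, b1] -= t
                Qa[:, a1, b1] += t
                Qa[:, a2, b2] += t
                Qa[:, a1, b2] -= t
                Qa[:, a2, b1] -= t
        np.clip(qa, 0.0, None, out=qa)
        q[active] = qa
        cur = _objective(qa)
        done = prev[active] - cur < tol
        prev[active] = cur
        active = active[~done]
    return q


def _orient(p: np.ndarray, target: str) -> np.ndarray:
    """Move the group axis first: (..., S, R, C) -> (..., K, A, Bb)."""
    if target == "C":
        return np.moveaxis(p, -1, -3)    # groups by c, free block (s, r)
    if target == "S":
        return p                          # groups by s, free block (r, c)
    raise ValueError(f"target must be 'S' or 'C', got {target!r}")


def _restore(q: np.ndarray, target: str) -> np.ndarray:
    return np.moveaxis(q, -3, -1) if target == "C" else q


def _shared_info_batch(p: np.ndarray, target: str) -> np.ndarray:
    """SI terms for stacked (..., S, R, C) probability tables, in bits."""
    p = np.asarray(p, dtype=float)
    batch_shape = p.shape[:-3]
    flat = p.reshape((-1,) + p.shape[-3:])
    oriented = _orient(flat, target)
    q_star = _restore(_minimize_transport(oriented), target)
    si = _mi_sc(flat) - _cond_mi_scr(q_star)
    return si.reshape(batch_shape)


def shared_info(p: TrivariateCounts | np.ndarray, target: str = "C") -> float:
    """Shared (redundant) information about the target, in bits.

    ``target="C"``: SI(C;{S;R}), maximizing co-information over distributions
    preserving p(s,c) and p(r,c).  ``target="S"``: SI(S;{C;R}), preserving
    p(s,c) and p(s,r).
    """
    probs = (p.probabilities() if isinstance(p, TrivariateCounts)
             else np.asarray(p, dtype=float))
    if probs.ndim != 3:
        raise ValueError("expected one S x R x C table")
    total = probs.sum()
    if not np.isclose(total, 1.0):
        probs = probs / total
    return float(_shared_info_batch(probs, target))


def pid_oracle(p: TrivariateCounts | np.ndarray, grid_step: float = 0.01,
               target: str = "C", refine: int = 0) -> float:
    """Brute-force maximal co-information over the marginal polytope.

    Enumerates the free coordinates of every per-group transportation block
    on a regular grid of step ``grid_step`` and returns the best co-
    information found — a lower bound on the true maximum that is monotone
    non-decreasing as the step shrinks (halving keeps all previous grid
    points).  ``refine`` zooms in around the best point that many times.
    Only intended for tiny alphabets (|S|x|R|x|C| <= 16).
    """
    probs = (p.probabilities() if isinstance(p, TrivariateCounts)
             else np.asarray(p, dtype=float))
    probs = probs / probs.sum()
    if probs.size > 16:
        raise ValueError("alphabet too large for the exhaustive oracle")
    oriented = _orient(probs, target)
    K, A, Bb = oriented.shape
    row = oriented.sum(axis=2)      # (K, A) per-group row margins
    col = oriented.sum(axis=1)      # (K, Bb)
    p_k = oriented.sum(axis=(1, 2))
    n_free = K * (A - 1) * (Bb - 1)

    def _assemble(free_flat: np.ndarray) -> np.ndarray:
        # free_flat: (n_points, K, A-1, Bb-1) -> full q, NaN when infeasible
        npts = free_flat.shape[0]
        q = np.empty((npts, K, A, Bb))
        q[:, :, :A - 1, :Bb - 1] = free_flat
        q[:, :, :A - 1, Bb - 1] = row[None, :, :A - 1] - free_flat.sum(axis=3)
        q[:, :, A - 1, :] = col[None, :, :] - q[:, :, :A - 1, :].sum(axis=2)
        feasible = (q > -1e-12).all(axis=(1, 2, 3))
        return np.clip(q, 0.0, None), feasible

    # guaranteed-feasible anchor points: the empirical p and the per-group
    # independence distribution (narrow feasible slivers can fall between
    # grid points, so the scan always evaluates these too)
    with np.errstate(divide="ignore", invalid="ignore"):
        indep = np.where(p_k[:, None, None] > 0,
                         row[:, :, None] * col[:, None, :]
                         / np.maximum(p_k[:, None, None], _TINY), 0.0)
    anchors = np.stack([
        oriented[:, :A - 1, :Bb - 1].ravel(),
        indep[:, :A - 1, :Bb - 1].ravel(),
    ])

    def _axis(l: float, h: float, step: float) -> np.ndarray:
        # union of the step grid with a fixed (step-independent) 9-point
        # subdivision: narrow feasible slivers keep a minimum resolution and
        # halving the step still yields a superset of the previous grid
        return np.union1d(np.arange(l, h + step / 2, step),
                          np.linspace(l, h, 9))

    def _scan(lo: np.ndarray, hi: np.ndarray, step: float
              ) -> tuple[float, np.ndarray]:
        axes = [_axis(l, h, step) for l, h in zip(lo, hi)]
        mesh = np.meshgrid(*axes, indexing="ij")
        free = np.stack([m.ravel() for m in mesh], axis=1)
        free = np.concatenate([free, anchors], axis=0)
        best_val, best_pt = -np.inf, anchors[0]
        for start in range(0, free.shape[0], 100_000):
            chunk = free[start:start + 100_000]
            q, feasible = _assemble(chunk.reshape(-1, K, A - 1, Bb - 1))
            coi = np.where(feasible, coinformation(_restore(q, target)),
                           -np.inf)
            k = int(np.argmax(coi))
            if coi[k] > best_val:
                best_val, best_pt = float(coi[k]), chunk[k]
        return best_val, best_pt

    if A == 2 and Bb == 2:
        # exact feasible interval of the single free coordinate per group
        lo = np.maximum(0.0, row[:, 0] + col[:, 0] - p_k)
        hi = np.minimum(row[:, 0], col[:, 0])
    else:
        lo = np.zeros(n_free)
        hi = np.minimum(row[:, :A - 1, None],
                        col[:, None, :Bb - 1]).reshape(n_free)
    best_val, best_pt = _scan(lo, hi, grid_step)
    step = grid_step
    for _ in range(refine):
        prev_step, step = step, step / 4.0
        lo_r = np.maximum(best_pt - prev_step, lo)
        hi_r = np.minimum(best_pt + prev_step, hi)
        val, best_pt = _scan(lo_r, hi_r, step)
        best_val = max(best_val, val)
    return best_val


def intersection_information(p: TrivariateCounts | np.ndarray) -> IIResult:
    """II = min(SI(C;{S;R}), SI(S;{C;R})), clipped into [0, min(MIs)]."""
    probs = (p.probabilities() if isinstance(p, TrivariateCounts)
             else np.asarray(p, dtype=float))
    probs = probs / probs.sum()
    si_c = float(_shared_info_batch(probs, "C"))
    si_s = float(_shared_info_batch(probs, "S"))
    mi_rs = float(_mi_from_counts(probs.sum(axis=2).T))   # (R, S) -> symmetric
    mi_rc = float(_mi_from_counts(probs.sum(axis=0)))     # (R, C)
    ii = min(si_c, si_s)
    bound = min(mi_rs, mi_rc)
    clipped = not (0.0 <= ii <= bound + 1e-12)
    ii = float(np.clip(ii, 0.0, bound))
    ratio = ii_ratio(ii, mi_rs) if mi_rs > 0 else float("nan")
    return IIResult(si_c_sr=si_c, si_s_cr=si_s, ii=ii, mi_rs=mi_rs,
                    mi_rc=mi_rc, ii_over_mirs=ratio, clipped=clipped)


def ii_ratio(ii: float, mi_rs: float) -> float:
    """Readout efficiency II/MI(R;S), clipped into [0, 1]; NaN if MI <= 0."""
    if mi_rs <= 0:
        return float("nan")
    return float(np.clip(ii / mi_rs, 0.0, 1.0))


def _framewise_trivariate(discrete: np.ndarray, s_idx: np.ndarray,
                          c_idx: np.ndarray, n_s: int, n_c: int,
                          n_bins: int) -> np.ndarray:
    """Counts (neurons, frames, S, R, C) from discretized responses."""
    n_neurons, n_trials, n_frames = discrete.shape
    onehot = np.zeros((n_trials, n_s, n_c))
    onehot[np.arange(n_trials), s_idx, c_idx] = 1.0
    counts = np.empty((n_neurons, n_frames, n_s, n_bins, n_c))
    for b in range(n_bins):
        counts[:, :, :, b, :] = np.einsum("jtf,tsc->jfsc", discrete == b,
                                          onehot)
    return counts


def _batch_ii(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                          np.ndarray, np.ndarray]:
    """(ii, si_c, si_s, mi_rs, mi_rc) for stacked (..., S, R, C) tables."""
    si_c = _shared_info_batch(probs, "C")
    si_s = _shared_info_batch(probs, "S")
    mi_rs = _mi_from_counts(np.swapaxes(probs.sum(axis=-1), -1, -2))
    mi_rc = _mi_from_counts(probs.sum(axis=-3))
    ii = np.clip(np.minimum(si_c, si_s), 0.0, np.minimum(mi_rs, mi_rc))
    return ii, si_c, si_s, mi_rs, mi_rc


def ii_framewise(tensor: TrialTensor, stimulus: np.ndarray,
                 choice: np.ndarray, n_bins: int = 2, n_perm: int = 50,
                 rng: np.random.Generator | None = None,
                 sig_window: tuple[float, float] = (0.0, 1.0),
                 alpha: float = 0.05,
                 already_discrete: bool = False) -> FramewiseIIResult:
    """Frame-by-frame II per neuron with permutation nulls.

    Responses are discretized with the same equipopulated edges as the
    bivariate analyses; the trivariate table is formed against the aligned
    stimulus and choice labels.  Permutations shuffle the neural response
    across trials (consistently over frames), breaking both the stimulus and
    the choice association; null II values feed both the significance call
    (Kruskal-Wallis, as for MI) and the limited-sampling correction, which
    subtracts the per-neuron mean null II (an analytic correction is not
    available for PID atoms).
    """
    rng = np.random.default_rng() if rng is None else rng
    stimulus = np.asarray(stimulus)
    choice = np.asarray(choice)
    if stimulus.size != tensor.values.shape[1] or \
            choice.size != tensor.values.shape[1]:
        raise ValueError("label arrays must match the included trials")
    s_cats, s_idx = np.unique(stimulus, return_inverse=True)
    c_cats, c_idx = np.unique(choice, return_inverse=True)
    discrete = discretize_framewise(tensor.values, n_bins, already_discrete)
    n_cat = int(discrete.max()) + 1 if already_discrete else n_bins
    n_neurons, n_trials, n_frames = discrete.shape
    n = float(n_trials)

    counts = _framewise_trivariate(discrete, s_idx, c_idx, s_cats.size,
                                   c_cats.size, n_cat)
    ii_raw, si_c, si_s, mi_rs, mi_rc = _batch_ii(counts / n)

    win = tensor.frames_in(*sig_window)
    if win.size < 2:
        raise ValueError("significance window shorter than 2 frames")
    null_ii = np.empty((n_neurons, win.size, n_perm))
    d_win = discrete[:, :, win]
    for k in range(n_perm):
        perm = rng.permutation(n_trials)
        counts_k = _framewise_trivariate(d_win, s_idx[perm], c_idx[perm],
                                         s_cats.size, c_cats.size, n_cat)
        null_ii[:, :, k] = _batch_ii(counts_k / n)[0]

    bias = null_ii.mean(axis=(1, 2))
    ii_corr = np.clip(ii_raw - bias[:, None], 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(mi_rs > 0, np.clip(ii_corr / mi_rs, 0.0, 1.0),
                         np.nan)

    p_value = np.empty(n_neurons)
    significant = np.empty(n_neurons, dtype=bool)
    for j in range(n_neurons):
        p_value[j], significant[j] = mi_significance(
            ii_raw[j, win], null_ii[j], alpha)
    return FramewiseIIResult(
        ii_raw=ii_raw, ii_corrected=ii_corr, si_c_sr=si_c, si_s_cr=si_s,
        mi_rs=mi_rs, mi_rc=mi_rc, ii_over_mirs=ratio, null_ii=null_ii,
        window_frames=win, p_value=p_value, significant=significant)
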