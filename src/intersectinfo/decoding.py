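"""Population decoding and confusion-matrix information (decMI).

Linear L2-penalized logistic decoders are trained with stratified 5-fold
cross-validation and a class-balanced penalty to predict stimulus (Go/No-go)
or choice (Lick/No-lick) from frame-concatenated activity in the first second
after stimulus onset.  Decoder performance is summarized as the plugin mutual
information of the held-out confusion matrix (decMI) — a lower bound on the
encoded information that, unlike direct MI estimates, scales to neuron
groups.  A label-shuffle null pooled across the neurons of a field of view
(FOV) classifies single neurons as "discriminative" (decMI above the null's
95th percentile); cumulative-population curves, discriminative/non-
discriminative pairing gains, noise-correlation shuffle gains and
stimulus-conditioned choice gains all build on the same decoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .info import plugin_mi, joint_counts
from .preprocess import TrialTensor

__all__ = [
    "DecoderSpec", "DecoderResult", "SessionFilter", "decoder_features",
    "apply_session_filter", "decode", "decoder_null", "fov_null",
    "classify_discriminative", "cumulative_curve", "pairing_gain",
    "noise_correlation_gain", "stimulus_conditioned_choice_gain",
    "CURVE_GRID_FULL", "CURVE_GRID_NONDISC",
]

#: fixed percentage grids the cumulative curves are resampled onto
CURVE_GRID_FULL = np.linspace(0.0, 100.0, 18)
CURVE_GRID_NONDISC = np.linspace(0.0, 100.0, 11)


@dataclass(frozen=True)
class DecoderSpec:
    """Cross-validated linear decoder settings.

    The L2 strength is expressed as scikit-learn's inverse regularization C;
    the class-balanced penalty (inverse-frequency class weights) is always
    on, so rare classes are learned as accurately as frequent ones.
    """

    folds: int = 5
    C: float = 1.0
    input_window: tuple[float, float] = (0.0, 1.0)
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be at least 2")


@dataclass
class DecoderResult:
    confusion: np.ndarray            # true x predicted held-out counts
    dec_mi: float                    # bits, plugin MI of the confusion table
    balanced_accuracy: float
    classes: np.ndarray
    predictions: np.ndarray          # held-out prediction per trial


@dataclass(frozen=True)
class SessionFilter:
    """Minimum trial counts for a session FOV to enter decoding analyses."""

    min_lick: int = 6
    min_nolick: int = 6
    min_correct: int = 6
    min_wrong: int = 6

    def __post_init__(self) -> None:
        if min(self.min_lick, self.min_nolick,
               self.min_correct, self.min_wrong) < 1:
            raise ValueError("all thresholds must be >= 1")


def apply_session_filter(trials, f: SessionFilter = SessionFilter(),
                         task: str = "stimulus",
                         training_session: bool = True) -> bool:
    """Whether a session passes the trial-count inclusion criteria.

    Choice decoding needs at least ``min_lick`` Lick and ``min_nolick``
    No-lick trials; decoding on task-training sessions additionally needs at
    least ``min_correct`` correct and ``min_wrong`` wrong trials (so stimulus
    and choice decoding can be dissociated).
    """
    included = trials[~trials["excluded"].astype(bool)]
    choice = included["choice"].to_numpy()
    outcome = included["outcome"].to_numpy()
    ok = True
    if task == "choice":
        ok &= (choice == "Lick").sum() >= f.min_lick
        ok &= (choice == "No-lick").sum() >= f.min_nolick
    elif task != "stimulus":
        raise ValueError(f"task must be 'stimulus' or 'choice', got {task!r}")
    if training_session:
        correct = np.isin(outcome, ["Hit", "CR"])
        ok &= correct.sum() >= f.min_correct
        ok &= (~correct).sum() >= f.min_wrong
    return bool(ok)


def decoder_features(tensor: TrialTensor,
                     window: tuple[float, float] = (0.0, 1.0)) -> np.ndarray:
    """Per-neuron frame features in the decoder window: (neurons, trials, frames)."""
    return tensor.values[:, :, tensor.frames_in(*window)]


def _stack(features: np.ndarray) -> np.ndarray:
    """(neurons, trials, frames) -> trials x frame-concatenated features."""
    features = np.atleast_3d(features)
    if features.ndim != 3:
        raise ValueError("features must be (neurons, trials, frames)")
    return np.transpose(features, (1, 0, 2)).reshape(features.shape[1], -1)


def decode(X: np.ndarray, y: np.ndarray,
           spec: DecoderSpec = DecoderSpec(),
           rng: np.random.Generator | None = None) -> DecoderResult:
    """Cross-validated decMI for one feature matrix.

    ``X``: trials x features (use :func:`_stack`/:func:`decoder_features` to
    frame-concatenate neurons).  The confusion matrix is assembled from
    held-out fold predictions only; decMI is its plugin MI.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 3:
        X = _stack(X)
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least two classes to decode")
    min_count = np.bincount(y_idx).min()
    folds = min(spec.folds, int(min_count))
    if folds < 2:
        raise ValueError(
            "cannot stratify: a class has fewer than 2 trials")
    seed = spec.seed if rng is None else int(rng.integers(2 ** 31))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y_idx)
    for train, test in skf.split(X, y_idx):
        clf = LogisticRegression(C=spec.C, class_weight="balanced",
                                 max_iter=spec.max_iter)  # L2 penalty (default)
        clf.fit(X[train], y_idx[train])
        pred[test] = clf.predict(X[test])
    confusion = joint_counts(y_idx, pred).counts
    if confusion.shape != (classes.size, classes.size):
        # a class never predicted: pad the predicted axis
        full = np.zeros((classes.size, classes.size), dtype=np.int64)
        pred_classes = np.unique(pred)
        for col, c in enumerate(pred_classes):
            full[:, c] = confusion[:, col]
        confusion = full
    with np.errstate(invalid="ignore"):
        recalls = np.diag(confusion) / confusion.sum(axis=1)
    return DecoderResult(confusion=confusion, dec_mi=plugin_mi(confusion),
                         balanced_accuracy=float(np.nanmean(recalls)),
                         classes=classes, predictions=classes[pred])


def decoder_null(X: np.ndarray, y: np.ndarray,
                 spec: DecoderSpec = DecoderSpec(), n_shuffles: int = 10,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """decMI values from label-shuffled cross-validations (fresh splits)."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    y = np.asarray(y)
    out = np.empty(n_shuffles)
    for k in range(n_shuffles):
        y_shuf = y[rng.permutation(y.size)]
        out[k] = decode(X, y_shuf, spec, rng).dec_mi
    return out


def fov_null(per_neuron_nulls: list[np.ndarray]) -> np.ndarray:
    """Pool shuffle decMI values across the neurons of one FOV."""
    return np.concatenate([np.asarray(n).ravel() for n in per_neuron_nulls])


def classify_discriminative(dec_mi: float, null: np.ndarray) -> bool:
    """True when decMI exceeds the 95th percentile of the FOV null."""
    null = np.asarray(null)
    if null.size == 0:
        raise ValueError("empty null distribution")
    return bool(dec_mi > np.percentile(null, 95))


def cumulative_curve(features: np.ndarray, y: np.ndarray,
                     individual_dec_mi: np.ndarray,
                     pool: np.ndarray | None = None,
                     spec: DecoderSpec = DecoderSpec(),
                     grid: np.ndarray = CURVE_GRID_FULL,
                     rng: np.random.Generator | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """decMI as neurons are added from least to most informative.

    ``features``: (neurons, trials, frames); ``pool``: boolean mask choosing
    the neuron pool (all neurons, or the non-discriminative subset).  Neurons
    enter in ascending individual decMI; each prefix is decoded from scratch;
    the per-FOV series (x = % of pool) is linearly interpolated onto the
    fixed percentage ``grid`` so curves from FOVs of different sizes can be
    averaged.  Returns (grid, decMI-on-grid).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    pool_idx = (np.arange(features.shape[0]) if pool is None
                else np.flatnonzero(pool))
    if pool_idx.size < 2:
        raise ValueError("pool must contain at least 2 neurons")
    order = pool_idx[np.argsort(individual_dec_mi[pool_idx], kind="stable")]
    pct = 100.0 * np.arange(1, order.size + 1) / order.size
    series = np.empty(order.size)
    for k in range(order.size):
        series[k] = decode(features[order[:k + 1]], y, spec, rng).dec_mi
    return grid, np.interp(grid, pct, series)


def pairing_gain(neuron_features: np.ndarray, pool_features: np.ndarray,
                 y: np.ndarray, spec: DecoderSpec = DecoderSpec(),
                 rng: np.random.Generator | None = None) -> float:
    """decMI gain a discriminative neuron receives from a neuron pool.

    gain = decMI(neuron + pool) - decMI(neuron alone); negative values mean
    the added dimensionality hurt more than the pool's information helped.
    Returns NaN when the pool is empty.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    pool_features = np.atleast_3d(pool_features)
    if pool_features.shape[0] == 0:
        return float("nan")
    alone = decode(neuron_features, y, spec, rng).dec_mi
    joint = np.concatenate([np.atleast_3d(neuron_features), pool_features],
                           axis=0)
    return decode(joint, y, spec, rng).dec_mi - alone


def noise_correlation_gain(features: np.ndarray, y: np.ndarray,
                           n_shuffles: int = 1000,
                           spec: DecoderSpec = DecoderSpec(),
                           rng: np.random.Generator | None = None
                           ) -> tuple[float, np.ndarray]:
    """Decoding gain attributable to noise correlations.

    Within each trial type, trials are shuffled independently per neuron,
    which preserves every neuron's class-conditional response distribution
    but destroys trial-to-trial co-variability.  Returns
    (true decMI - median shuffled decMI, shuffle distribution).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    features = np.atleast_3d(features)
    y = np.asarray(y)
    true_mi = decode(features, y, spec, rng).dec_mi
    class_idx = [np.flatnonzero(y == c) for c in np.unique(y)]
    if min(idx.size for idx in class_idx) < 2:
        raise ValueError("need at least 2 trials per class to shuffle")
    null = np.empty(n_shuffles)
    shuffled = features.copy()
    for k in range(n_shuffles):
        for idx in class_idx:
            for j in range(features.shape[0]):
                shuffled[j, idx] = features[j, idx[rng.permutation(idx.size)]]
        null[k] = decode(shuffled, y, spec, rng).dec_mi
    return true_mi - float(np.median(null)), null


def stimulus_conditioned_choice_gain(features: np.ndarray,
                                     stimulus: np.ndarray,
                                     choice: np.ndarray,
                                     spec: DecoderSpec = DecoderSpec(),
                                     rng: np.random.Generator | None = None
                                     ) -> float:
    """Behavioral %-correct-choice difference between S+ and S- trials.

    A stimulus decoder is trained on the full FOV pool; trials are split by
    whether its held-out stimulus prediction was correct (S+) or not (S-).
    Returns %correct-choice(S+) - %correct-choice(S-) in percentage points;
    NaN when either group is empty (e.g. perfect stimulus decoding).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    stimulus = np.asarray(stimulus)
    choice = np.asarray(choice)
    result = decode(features, stimulus, spec, rng)
    s_plus = result.predictions == stimulus
    if s_plus.all() or not s_plus.any():
        return float("nan")
    correct_choice = ((stimulus == "Go") & (choice == "Lick")) | \
                     ((stimulus == "No-go") & (choice == "No-lick"))
    return 100.0 * (correct_choice[s_plus].mean()
                    - correct_choice[~s_plus].mean())
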