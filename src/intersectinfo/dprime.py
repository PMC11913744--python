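"""Single-cell sensitivity: absolute d-prime for stimulus and choice.

    |d'| = |mu2 - mu1| / sqrt(0.5 * (var1 + var2))

computed on per-trial responses integrated over the first second after
stimulus onset, split by trial type (Go vs No-go for stimulus, Lick vs
No-lick for choice).  Variants operate on raw ΔF/F0, on median-thresholded
ΔF/F0 (all values at or below the across-trial median zeroed, suppressing
baseline fluctuations), or on binarized deconvolved spike counts.
"""

from __future__ import annotations

import numpy as np

__all__ = ["abs_dprime", "median_threshold_dprime", "spike_dprime",
           "split_by_class"]


def split_by_class(responses: np.ndarray, labels: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Split per-trial scalar responses into the two label classes."""
    labels = np.asarray(labels)
    cats = np.unique(labels)
    if cats.size != 2:
        raise ValueError(f"expected exactly 2 classes, got {cats.size}")
    responses = np.asarray(responses, dtype=float)
    return responses[labels == cats[0]], responses[labels == cats[1]]


def abs_dprime(group1: np.ndarray, group2: np.ndarray) -> float:
    """|mu2 - mu1| / sqrt(0.5 (s1^2 + s2^2)) with unbiased variances.

    Degenerate zero-variance groups: equal means give 0, unequal means +inf.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 trials")
    num = abs(g2.mean() - g1.mean())
    denom = np.sqrt(0.5 * (g1.var(ddof=1) + g2.var(ddof=1)))
    if denom == 0.0:
        return 0.0 if num == 0.0 else float("inf")
    return float(num / denom)


def _integrate(values: np.ndarray) -> np.ndarray:
    """Sum per-trial responses over the supplied frame window."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return values.sum(axis=1)


def median_threshold_dprime(values: np.ndarray, labels: np.ndarray) -> float:
    """|d'| on median-thresholded responses.

    ``values``: trials x frames (one neuron, already restricted to the
    integration window).  The across-trial median of all frame values is
    computed once; values at or below it are zeroed (only strictly-above
    survives) before integrating and applying :func:`abs_dprime`.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    med = np.median(values)
    thresholded = np.where(values > med, values, 0.0)
    return abs_dprime(*split_by_class(_integrate(thresholded), labels))


def spike_dprime(spikes: np.ndarray, labels: np.ndarray) -> float:
    """|d'| on spike counts: binary spikes summed over the window per trial."""
    spikes = np.atleast_2d(np.asarray(spikes))
    return abs_dprime(*split_by_class(_integrate(spikes), labels))
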