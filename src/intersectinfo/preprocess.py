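"""Fluorescence preprocessing: ΔF/F0, SNR, binarization, binning, alignment.

ΔF/F0 uses a per-neuron baseline F0 defined as the median of the trace values
lying between its 10th and 70th percentiles — a robust estimate of the
resting fluorescence of a sparsely active neuron — after subtracting a scaled
(r = 0.7) neuropil trace.  Responses are discretized into equipopulated bins
independently at each time point, and aligned into neuron x trial x frame
tensors for the information analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import FluorescenceMatrix

__all__ = [
    "TrialTensor", "compute_dff", "compute_snr", "binarize_deconvolved",
    "equipopulated_bins", "discretize_framewise", "align_trials",
]


@dataclass
class TrialTensor:
    """Trial-aligned responses, neurons x trials x frames."""

    values: np.ndarray
    window_start: float            # s relative to stimulus onset
    window_end: float
    frame_rate: float
    included_trials: np.ndarray    # original trial indices after exclusions

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]

    def frame_times(self) -> np.ndarray:
        """Time of each frame (s) relative to stimulus onset."""
        return self.window_start + np.arange(self.n_frames) / self.frame_rate

    def frames_in(self, start: float, end: float) -> np.ndarray:
        """Indices of frames whose time lies in the half-open window [start, end)."""
        t = self.frame_times()
        return np.flatnonzero((t >= start) & (t < end))


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def _percentile_band_median(trace: np.ndarray, lo_pct: float = 10.0,
                            hi_pct: float = 70.0) -> float:
    lo, hi = np.percentile(trace, [lo_pct, hi_pct])
    band = trace[(trace >= lo) & (trace <= hi)]
    return float(np.median(band))


def compute_dff(fluor: FluorescenceMatrix, contamination_ratio: float = 0.7,
                order: str = "neuropil_first") -> np.ndarray:
    """Neuropil-corrected fractional fluorescence change.

    ``order="neuropil_first"`` (default): Fc = F - r*Fneu, F0 = median of the
    Fc values between its 10th and 70th percentiles (per neuron, over all
    frames), output (Fc - F0)/F0.  ``order="dff_first"`` normalizes F and Fneu
    separately before subtracting r times the neuropil ΔF/F0.

    Neurons whose baseline is non-positive cannot be normalized; their rows
    are returned as NaN with a warning.
    """
    if not 0.0 <= contamination_ratio < 1.0:
        raise ValueError("contamination_ratio must lie in [0, 1)")
    if not (np.isfinite(fluor.F).all() and np.isfinite(fluor.Fneu).all()):
        raise ValueError("fluorescence traces contain non-finite values")

    def _normalize(traces: np.ndarray) -> np.ndarray:
        out = np.empty_like(traces, dtype=float)
        bad = []
        for j, row in enumerate(traces):
            f0 = _percentile_band_median(row)
            if f0 <= 0:
                bad.append(j)
                out[j] = np.nan
            else:
                out[j] = (row - f0) / f0
        if bad:
            warnings.warn(
                f"non-positive baseline F0 for neurons {bad}; rows set to NaN")
        return out

    if order == "neuropil_first":
        return _normalize(fluor.F - contamination_ratio * fluor.Fneu)
    if order == "dff_first":
        return _normalize(fluor.F) - contamination_ratio * _normalize(fluor.Fneu)
    raise ValueError(f"unknown order {order!r}")


def compute_snr(trace: np.ndarray, frame_rate: float,
                noise_window: float = 3.0) -> float:
    """max(trace) / SD of the pre-stimulus stretch (first ``noise_window`` s)."""
    trace = np.asarray(trace, dtype=float)
    n_noise = int(round(noise_window * frame_rate))
    if trace.size <= n_noise:
        raise ValueError("trace shorter than the noise window")
    sd = float(np.std(trace[:n_noise]))
    if sd == 0.0:
        warnings.warn("zero noise SD; SNR is undefined, returning +inf")
        return float("inf")
    return float(np.max(trace)) / sd


def binarize_deconvolved(deconvolved: np.ndarray,
                         threshold: float = 0.01) -> np.ndarray:
    """Inferred spiking: 1 where the deconvolved trace exceeds the threshold."""
    deconvolved = np.asarray(deconvolved)
    if not np.isfinite(deconvolved).all():
        raise ValueError("deconvolved trace contains non-finite values")
    return (deconvolved > threshold).astype(np.int8)


def equipopulated_bins(values: np.ndarray, n_bins: int = 2) -> np.ndarray:
    """Discretize per-trial responses into equipopulated bins.

    Ties are broken by trial index (stable sort), then ranks are split at the
    exact k/n_bins quantile boundaries — deterministic and seed-free, and the
    bin counts differ by at most one even through runs of tied values.
    All-identical input cannot be split; it lands in bin 0 with a warning.
    """
    values = np.asarray(values)
    n = values.size
    if n < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} trials, got {n}")
    if np.all(values == values.flat[0]):
        warnings.warn("all values identical; every trial assigned to bin 0")
        return np.zeros(n, dtype=np.int64)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def discretize_framewise(tensor_values: np.ndarray, n_bins: int = 2,
                         already_discrete: bool = False) -> np.ndarray:
    """Apply equipopulated binning across trials, independently per frame.

    Input neurons x trials x frames; output same shape, integer bin labels.
    With ``already_discrete`` (e.g. binarized deconvolved spikes) values are
    passed through as integer categories.
    """
    if already_discrete:
        return tensor_values.astype(np.int64)
    n_neurons, n_trials, n_frames = tensor_values.shape
    out = np.empty(tensor_values.shape, dtype=np.int64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant frames are legal here
        for j in range(n_neurons):
            for f in range(n_frames):
                out[j, :, f] = equipopulated_bins(tensor_values[j, :, f], n_bins)
    return out


def align_trials(dff: np.ndarray, trials: pd.DataFrame,
                 window: tuple[float, float] = (-3.0, 7.0),
                 frame_rate: float = 15.0) -> TrialTensor:
    """Slice per-trial responses aligned to stimulus onset.

    The window is half-open [start, end) in seconds relative to onset; frame
    counts are computed with round-half-away-from-zero so every included
    trial contributes the same number of frames.  Trials flagged ``excluded``
    (licks during the stimulus) are dropped.
    """
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed window start")
    n_frames = _round_half_away((end - start) * frame_rate)
    offset = _round_half_away(start * frame_rate)

    included = trials.index[~trials["excluded"].astype(bool)].to_numpy()
    slices = []
    for idx in included:
        onset = int(trials.loc[idx, "onset_frame"])
        lo = onset + offset
        hi = lo + n_frames
        if lo < 0 or hi > dff.shape[1]:
            raise ValueError(
                f"window {window} exceeds recording bounds for trial "
                f"{int(trials.loc[idx, 'trial_id'])}")
        slices.append(dff[:, lo:hi])
    values = np.stack(slices, axis=1) if slices else np.empty(
        (dff.shape[0], 0, n_frames))
    return TrialTensor(values=values, window_start=start, window_end=end,
                       frame_rate=frame_rate, included_trials=included)
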