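"""Synthetic Go/No-go imaging sessions.

Generates trial-structured behavior and GCaMP6s-like population fluorescence
with known ground truth, so the whole analysis chain (ΔF/F0 → discretization →
mutual information → intersection information → decoding) can be exercised and
validated without real recordings.

A session emulates a head-fixed whisker-based object localization task: on
each trial a pole is presented in a Go or a No-go position for 1-1.5 s after a
3 s pre-stimulus baseline, and the animal reports the position by licking or
withholding licks during a 4 s response window.  Behavioral performance
(fraction of correct responses) is a direct dial of the generator, which is
what lets a sweep of sessions stand in for the three learning stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "SessionConfig",
    "FluorescenceMatrix",
    "GroundTruth",
    "classify_stage",
    "generate_behavior",
    "generate_population",
    "generate_session",
    "stage_config",
    "STAGE_SWEEP",
]

#: outcome as a deterministic function of (stimulus, choice)
OUTCOME_MAP = {
    ("Go", "Lick"): "Hit",
    ("No-go", "Lick"): "FA",
    ("No-go", "No-lick"): "CR",
    ("Go", "No-lick"): "Miss",
}

CORRECT_OUTCOMES = frozenset({"Hit", "CR"})

TRIAL_COLUMNS = [
    "trial_id", "stimulus", "choice", "outcome",
    "onset_frame", "offset_frame", "excluded",
]


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of one synthetic session.

    Rates and gains are per-frame spike probabilities; durations in seconds.
    ``stim_gain`` / ``choice_gain`` set the *mean* of a log-normal per-neuron
    amplitude distribution (``gain_sigma`` its log-scale spread), emulating the
    heterogeneous, sparse tuning of supragranular barrel-cortex populations.
    """

    n_neurons: int = 80
    n_trials: int = 200
    frame_rate: float = 15.0
    baseline_duration: float = 3.0
    stimulus_duration: tuple[float, float] = (1.0, 1.5)
    response_window: float = 4.0
    inter_trial_interval: float = 1.5
    p_go: float = 0.5
    performance: float = 0.7
    stim_gain: float = 0.10
    choice_gain: float = 0.05
    gain_sigma: float = 0.5
    frac_tuned: float = 0.5
    frac_choice_coupled: float = 0.5
    baseline_rate: float = 0.02
    noise_corr: float = 0.0
    shared_sd: float = 0.05
    gcamp_tau: float = 1.0
    noise_sd: float = 0.10
    f0_level: float = 100.0
    transient_amp: float = 50.0
    neuropil_level: float = 30.0
    exclusion_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("performance", "p_go", "frac_tuned", "frac_choice_coupled"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if not 0.0 <= self.noise_corr < 1.0:
            raise ValueError(f"noise_corr={self.noise_corr} must lie in [0, 1)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        durations = (self.baseline_duration, self.response_window,
                     self.gcamp_tau, *self.stimulus_duration)
        if any(d <= 0 for d in durations):
            raise ValueError("all durations must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be at least 1")

    @property
    def frames_per_trial(self) -> int:
        dur = (self.baseline_duration + self.stimulus_duration[1]
               + self.response_window + self.inter_trial_interval)
        return int(round(dur * self.frame_rate))

    @property
    def n_frames(self) -> int:
        return self.n_trials * self.frames_per_trial


@dataclass
class FluorescenceMatrix:
    """Raw somatic and neuropil traces, neurons x frames."""

    F: np.ndarray
    Fneu: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        if self.F.shape != self.Fneu.shape:
            raise ValueError("F and Fneu must have identical shape")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


@dataclass
class GroundTruth:
    """What the generator actually injected (for parameter-recovery tests)."""

    spikes: np.ndarray                      # neurons x frames, binary
    tuned_ids: np.ndarray                   # indices of stimulus-tuned neurons
    choice_coupled_ids: np.ndarray          # indices of choice-coupled neurons
    preferred_stimulus: np.ndarray          # per-neuron "Go"/"No-go"
    preferred_choice: np.ndarray            # per-neuron "Lick"/"No-lick"
    latent_shared_noise: np.ndarray         # per-trial shared factor values


def classify_stage(fraction_correct: float) -> int:
    """Learning stage from behavioral performance.

    Stage 1: <=55% correct; stage 2: >55% and <=75%; stage 3: >75%.
    """
    if not 0.0 <= fraction_correct <= 1.0:
        raise ValueError(f"fraction_correct={fraction_correct} outside [0, 1]")
    if fraction_correct <= 0.55:
        return 1
    if fraction_correct <= 0.75:
        return 2
    return 3


def generate_behavior(config: SessionConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a trial table for one session.

    Stimulus is i.i.d. Bernoulli(p_go); on each trial the response is correct
    with probability ``config.performance`` independently, which couples choice
    to stimulus exactly as much as the target performance dictates.  Outcomes
    follow deterministically (Go+Lick=Hit, No-go+Lick=FA, No-go+No-lick=CR,
    Go+No-lick=Miss).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_trials
    stimulus = np.where(rng.random(n) < config.p_go, "Go", "No-go")
    correct = rng.random(n) < config.performance
    # the correct choice is Lick on Go and No-lick on No-go
    lick = np.where(stimulus == "Go", correct, ~correct)
    choice = np.where(lick, "Lick", "No-lick")
    outcome = [OUTCOME_MAP[(s, c)] for s, c in zip(stimulus, choice)]

    fpt = config.frames_per_trial
    fr = config.frame_rate
    onset = (np.arange(n) * fpt
             + int(round(config.baseline_duration * fr)))
    lo, hi = config.stimulus_duration
    stim_dur = rng.uniform(lo, hi, size=n)
    offset = onset + np.round(stim_dur * fr).astype(int)
    excluded = rng.random(n) < config.exclusion_prob

    return pd.DataFrame({
        "trial_id": np.arange(n),
        "stimulus": stimulus,
        "choice": choice,
        "outcome": outcome,
        "onset_frame": onset,
        "offset_frame": offset,
        "excluded": excluded,
    })


def _per_neuron_gains(mean: float, sigma: float, size: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Log-normal amplitudes with the requested mean."""
    if mean == 0.0:
        return np.zeros(size)
    return mean * rng.lognormal(-0.5 * sigma ** 2, sigma, size=size)


def _exp_kernel(tau_s: float, frame_rate: float) -> np.ndarray:
    n = max(1, int(round(5.0 * tau_s * frame_rate)))
    t = np.arange(n) / frame_rate
    return np.exp(-t / tau_s)


def generate_population(
    trials: pd.DataFrame,
    config: SessionConfig,
    rng: np.random.Generator | None = None,
) -> tuple[FluorescenceMatrix, GroundTruth]:
    """Simulate spiking and fluorescence for one session.

    Per neuron and frame the spike probability is a baseline rate plus a
    stimulus term (tuned neurons, during pole contact on their preferred
    position), a choice term (coupled neurons, from stimulus onset through the
    response window on trials with their preferred choice), and a trial-wise
    shared Gaussian factor scaled by ``noise_corr`` that produces noise
    correlations.  Binary spikes are convolved with an exponential
    ``exp(-t/gcamp_tau)`` kernel — the first-order autoregressive transient
    shape standard for GCaMP6s — scaled and summed with Gaussian noise on top
    of a constant baseline fluorescence.  The neuropil channel is a temporally
    smoothed population mean, shared across neurons.
    """
    if len(trials) == 0:
        raise ValueError("trial table is empty")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n_neurons, n_frames = config.n_neurons, config.n_frames
    fr = config.frame_rate

    n_tuned = int(round(config.frac_tuned * n_neurons))
    n_coupled = int(round(config.frac_choice_coupled * n_neurons))
    tuned_ids = rng.choice(n_neurons, size=n_tuned, replace=False)
    choice_coupled_ids = rng.choice(n_neurons, size=n_coupled, replace=False)
    preferred_stimulus = rng.choice(["Go", "No-go"], size=n_neurons)
    preferred_choice = rng.choice(["Lick", "No-lick"], size=n_neurons)

    stim_gains = np.zeros(n_neurons)
    stim_gains[tuned_ids] = _per_neuron_gains(
        config.stim_gain, config.gain_sigma, n_tuned, rng)
    choice_gains = np.zeros(n_neurons)
    choice_gains[choice_coupled_ids] = _per_neuron_gains(
        config.choice_gain, config.gain_sigma, n_coupled, rng)

    shared = rng.standard_normal(len(trials))
    resp_frames = int(round(config.response_window * fr))

    p = np.full((n_neurons, n_frames), config.baseline_rate)
    for i, row in enumerate(trials.itertuples(index=False)):
        on, off = int(row.onset_frame), int(row.offset_frame)
        stim_sel = preferred_stimulus == row.stimulus
        p[stim_sel, on:off] += stim_gains[stim_sel, None]
        choice_sel = preferred_choice == row.choice
        end = min(off + resp_frames, n_frames)
        p[choice_sel, on:end] += choice_gains[choice_sel, None]
        # shared factor: identical loading sign across the population
        t0, t1 = i * config.frames_per_trial, (i + 1) * config.frames_per_trial
        p[:, t0:t1] += config.noise_corr * config.shared_sd * shared[i]
    np.clip(p, 0.0, 0.95, out=p)

    spikes = (rng.random((n_neurons, n_frames)) < p).astype(np.int8)

    kernel = _exp_kernel(config.gcamp_tau, fr)
    transients = np.empty((n_neurons, n_frames))
    for j in range(n_neurons):
        transients[j] = np.convolve(spikes[j].astype(float), kernel)[:n_frames]

    F = (config.f0_level
         + config.transient_amp * transients
         + config.noise_sd * config.f0_level
         * rng.standard_normal((n_neurons, n_frames)))
    pop_mean = uniform_filter1d(F.mean(axis=0), size=max(1, int(round(fr))))
    Fneu = np.broadcast_to(
        config.neuropil_level * pop_mean / pop_mean.mean(),
        (n_neurons, n_frames)).copy()

    fluor = FluorescenceMatrix(F=F, Fneu=Fneu, frame_rate=fr)
    truth = GroundTruth(
        spikes=spikes,
        tuned_ids=np.sort(tuned_ids),
        choice_coupled_ids=np.sort(choice_coupled_ids),
        preferred_stimulus=preferred_stimulus,
        preferred_choice=preferred_choice,
        latent_shared_noise=shared,
    )
    return fluor, truth


def generate_session(
    config: SessionConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, FluorescenceMatrix, GroundTruth]:
    """Behavior plus population activity in one call (single seeded stream)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    trials = generate_behavior(config, rng)
    fluor, truth = generate_population(trials, config, rng)
    return trials, fluor, truth


def stage_config(stage: int, base: SessionConfig | None = None) -> SessionConfig:
    """Session parameters emulating one learning stage.

    Stimulus tuning strength is held fixed across stages; behavioral
    performance and choice coupling increase with learning (stage 1: 50%
    correct, no choice coupling; stage 2: 65%, intermediate; stage 3: 85%,
    strong), mirroring how choice-related activity emerges over training while
    sensory drive is present from the start.
    """
    base = SessionConfig() if base is None else base
    params = {
        1: dict(performance=0.50, choice_gain=0.0),
        2: dict(performance=0.65, choice_gain=0.05),
        3: dict(performance=0.85, choice_gain=0.10),
    }
    if stage not in params:
        raise ValueError(f"stage must be 1, 2 or 3, got {stage!r}")
    return replace(base, **params[stage])


#: the three-point learning sweep used by the analysis scripts
STAGE_SWEEP = (1, 2, 3)
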