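# intersectinfo

Information-theoretic analysis of trial-based two-photon calcium imaging in a
Go/No-go sensory task: how much information single neurons and populations
carry about the **stimulus** and about the animal's **choice**, and how much
of the stimulus information is actually **read out into the choice** —
quantified frame by frame, across learning stages.

The package is written for systems neuroscientists analysing trial-structured
ΔF/F₀ data (or wanting a fully synthetic, ground-truth-controlled testbed for
such analyses). It implements:

- **Mutual information.** For a discretized single-trial response r and trial
  label s (stimulus Go/No-go, or choice Lick/No-lick),

  MI(S;R) = Σ_{s,r} p(s,r) log₂ [ p(s,r) / (p(s)p(r)) ]

  with equipopulated response binning per time point, Panzeri–Treves
  limited-sampling bias correction, and per-neuron significance from 50 trial
  permutations applied consistently across time points (exact
  rank-permutation test in the first second after stimulus onset).
- **Intersection information (II).** From the trivariate p(s,r,c), II is the
  minimum of the two partial-information-decomposition redundancy terms
  SI(C;{S;R}) and SI(S;{C;R}), each obtained by maximizing the
  co-information over distributions q that preserve two pairwise marginals —
  a convex program solved exactly by batched coordinate descent and
  cross-checked against an exhaustive polytope-grid oracle. II is bounded by
  both MI(R;S) and MI(R;C), so II/MI(R;S) ∈ [0,1] measures readout
  efficiency.
- **Population decoding (decMI).** Class-balanced L2 logistic decoders,
  stratified 5-fold cross-validation, information scored as the plugin MI of
  the held-out confusion matrix; discriminative-neuron classification
  against a 95th-percentile label-shuffle null, cumulative-population
  curves on fixed 18/11-point percentage grids, pairing gains,
  noise-correlation shuffle gains, and stimulus-conditioned choice gains.
- **Single-cell sensitivity.** |d′| = |μ₂−μ₁| / √(½(σ₁²+σ₂²)) on raw,
  median-thresholded, and deconvolved-spike responses.
- **A synthetic session generator** (Go/No-go behavior with dialled
  performance, sparse log-normal tuning, GCaMP6s-like exponential transients,
  optional shared-factor noise correlations) providing ground truth for every
  stage of the chain.

## Worked example

```python
import numpy as np
from intersectinfo.synthetic import SessionConfig, generate_session
from intersectinfo.preprocess import compute_dff, align_trials
from intersectinfo.info import framewise_info
from intersectinfo.intersection import ii_framewise

cfg = SessionConfig(n_neurons=16, n_trials=120, performance=0.85,
                    choice_gain=0.10, seed=42)          # an "expert" session
trials, fluor, truth = generate_session(cfg)
dff = compute_dff(fluor)                                 # neuropil-corrected ΔF/F0
tensor = align_trials(dff, trials, (-3.0, 7.0), cfg.frame_rate)
inc = tensor.included_trials
stim = trials["stimulus"].to_numpy()[inc]
choice = trials["choice"].to_numpy()[inc]

mi = framewise_info(tensor, stim, n_perm=50, rng=np.random.default_rng(0))
ii = ii_framewise(tensor, stim, choice, n_perm=50,
                  rng=np.random.default_rng(1))
win = mi.window_frames
print(f"MI(R;S) in first second: {mi.mi_corrected[:, win].mean():.3f} bits, "
      f"{mi.significant.mean():.0%} of neurons significant")
print(f"II: {ii.ii_corrected[:, win].mean():.3f} bits, "
      f"readout efficiency {np.nanmean(ii.ii_over_mirs[:, win]):.2f}")
```

prints

```
MI(R;S) in first second: 0.059 bits, 56% of neurons significant
II: 0.040 bits, readout efficiency 0.44
```

i.e. in this strongly coupled session more than half the neurons carry
significant stimulus information (~0.06 bits per frame on average, of a
1-bit maximum), and a little under half of that stimulus information is
redundantly shared with the choice.

The `analysis/` directory holds the numbered end-to-end drivers
(`01_simulate_sessions.py` → `05_group_stats.py`); each reads the outputs of
its predecessors from `results/` and writes tidy CSV tables.

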