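# Methods

This note documents the models, estimators and numerical choices behind
`intersectinfo`, and what the synthetic testbed does and does not establish
about real data.

## Task model and synthetic sessions

A session emulates a head-fixed whisker-based Go/No-go object localization
experiment imaged at ~15 Hz per plane. Each trial is: 3 s pre-stimulus
baseline, pole contact for 1–1.5 s (duration drawn uniformly per trial),
a 4 s response window, and a 1.5 s inter-trial gap. Stimulus identity is
i.i.d. Bernoulli(p_go); the response is correct with probability equal to the
session's `performance` parameter, independently per trial, and the outcome
(Hit/FA/CR/Miss) follows deterministically. Sessions are classified into
learning stages by fraction correct: ≤55% stage 1, ≤75% stage 2, >75%
stage 3 (boundaries inclusive on the low side).

Population activity: each neuron spikes per frame with probability

    baseline_rate
    + stim_gain_i   · 1[preferred stimulus present, pole in contact]
    + choice_gain_i · 1[preferred choice, onset → end of response window]
    + noise_corr · shared_sd · z_trial

with per-neuron gains drawn log-normally (σ_log = 0.5, mean equal to the
configured gain) over a random tuned/coupled subset, and `z_trial` a single
standard-normal shared factor per trial loading with the same sign on every
neuron — the simplest structure that produces noise correlations whose
decoding effect can be sign-flipped by tuning geometry. Choice coupling is
conditioned on the sampled choice label, not the stimulus, so choice
information can exist independently of stimulus information (necessary to
exercise II < min(MI)). Defaults: baseline_rate 0.02/frame, stim_gain 0.10,
noise_sd 0.10 (ΔF/F₀ units), gcamp_tau 1.0 s, amplitude 50 fluorescence
units per spike on a baseline of 100. These place single-neuron MI and decMI
in the 0.02–0.3 bit range typical of supragranular sensory-cortex imaging.

Spikes are convolved with exp(−t/τ), the first-order autoregressive
transient shape that matches GCaMP6s deconvolution assumptions; the neuropil
channel is a 1 s-smoothed population mean shared across neurons. The stage
sweep holds stimulus tuning fixed and increases performance (0.50 / 0.65 /
0.85) and choice coupling (0 / 0.05 / 0.10), the package's operational
definition of "learning" — sensory drive present from the start, behavioral
coupling emerging with training.

What the generator does **not** emulate: lick-time dynamics within the
response window, running/whisking covariates, cross-session neuron identity,
amplitude nonlinearity and saturation of the indicator, or realistic
neuropil contamination structure. Passing tests therefore establish
correctness and calibration of the estimators under a controlled generative
model, not robustness to every artifact of real recordings.

## Preprocessing

ΔF/F₀ uses neuropil subtraction first (Fc = F − 0.7·Fneu), then a baseline
F₀ equal to the median of the Fc values between its own 10th and 70th
percentiles, per neuron over all frames. The alternative reading — baseline
on the raw trace, neuropil subtraction second — is exposed as
`order="dff_first"`; subtract-then-normalize is the default because it is
the convention of the correction method the pipeline follows. Neurons with
F₀ ≤ 0 are flagged invalid (NaN rows) rather than silently divided.

Responses are discretized into R = 2 (default) or 4 equipopulated bins,
independently at each time point, across trials. Ties are broken by trial
index (stable rank), then ranks are split at exact k/R quantile boundaries —
deterministic, seed-free, and balanced to within one trial per bin even
through runs of tied values. Frame windows are half-open [start, end) with
round-half-away-from-zero frame counts.

## Mutual information

Plugin MI on the label × bin contingency table, 0·log 0 := 0. The
limited-sampling bias is estimated as

    bias = [ Σ_s (R̃_s − 1) − (R̃ − 1) ] / (2 N ln 2)

where R̃_s and R̃ are Bayesian (Panzeri–Treves) estimates of the number of
effectively occupiable response bins, conditional on s and overall; when all
bins are occupied this reduces to the Miller–Madow correction (a `naive`
estimator flag selects Miller–Madow outright). Note the bias estimate is
negative for conditionally deterministic channels (R̃_s = 1, R̃ = 2), so the
corrected value can exceed the plugin value there; under independence it
removes the positive ~1/(2N ln 2) bias to within Monte-Carlo error.

Significance: 50 trial permutations, each applied identically at every time
point (preserving within-trial autocorrelation), plugin (uncorrected) MI
recorded per frame. The per-neuron test statistic is the mean pooled
midrank of the observed first-second frames; its null distribution is the
same statistic computed for each permutation column, giving the exact
one-sided p-value (1 + #{perm ≥ obs}) / 51. A pooled two-sample rank test
(all permuted values as one group) was rejected during development: the ~15
within-window frames are strongly autocorrelated through the indicator
kernel, the pooled test treats them as independent, and its measured
type-I error on signal-free sessions was ~0.11 instead of the nominal 0.05.
The permutation form is exact by exchangeability (type-I 2/51 ≈ 0.039) and
keeps the rank flavor of the comparison. A neuron is significant when
p < 0.05 and the observed median exceeds the null median.

Performance equalization: when comparing stages, trials are subsampled to
75% correct by randomly dropping trials from the over-represented
correctness class, choosing the count whose achievable fraction is closest
to the target (ties resolved toward dropping fewer trials), one independent
draw per neuron.

## Intersection information

From the trivariate p(s,r,c), the two redundancy terms are

    SI(C;{S;R}) = max { CoI(q) : q(s,c) = p(s,c), q(r,c) = p(r,c) }
    SI(S;{C;R}) = max { CoI(q) : q(s,c) = p(s,c), q(s,r) = p(s,r) }

with CoI the co-information. Since I_q(S;C) is pinned by the preserved
p(s,c) marginal in both programs, each maximization equals
I(S;C) − min_q I_q(S;C|R), a convex minimization over a product of
per-group transportation polytopes (groups indexed by c in the first
program, by s in the second). The solver performs cyclic exact coordinate
descent along all 2×2-minor directions of each group block; each line
search is a monotone scalar root-find (bracketed Newton, 40-iteration cap,
1e-14 move tolerance), the outer loop stops when the objective decreases by
less than 1e-11 nats, and the whole procedure is batched over thousands of
tables at once — which is what makes per-frame permutation nulls for II
tractable (~50k tables/s). Because the program is convex, no random
restarts are needed; a gradient-style solver with restarts was considered
and dropped in favor of this exact scheme. An independent exhaustive oracle
(grid scan of the polytope's free coordinates, with step-nested refinement
so that halving the step never decreases the result) agrees with the solver
to <1e-3 bits on 2×2×2 and 2×4×2 alphabets and is part of the test suite,
not the runtime path.

II = min of the two SI terms, clipped into [0, min(MI(R;S), MI(R;C))]
(clipping is recorded). No analytic bias correction exists for PID atoms,
so II is corrected by subtracting the per-neuron mean of the permutation
null (response shuffles breaking both associations, the same permutations
used for significance); the raw value is retained alongside. The
readout-efficiency ratio uses the corrected II over plugin MI(R;S), clipped
to [0,1], NaN when MI(R;S) ≤ 0, and is computed frame-wise then averaged.

## Population decoding

Logistic regression with L2 penalty (inverse strength C = 1.0 — the
regularization constant is a free choice, exposed in `DecoderSpec`),
class weights inverse to class frequency, stratified 5-fold CV with seeded
shuffling (folds reduced to the minority-class count when needed). decMI is
the plugin MI of the held-out confusion matrix — the same code path as the
single-neuron MI, so the two cannot drift apart. Null distributions: ten
label-shuffled cross-validations per neuron with independent seeded splits,
pooled across the FOV's neurons; a neuron is discriminative above the
pooled null's 95th percentile.

Cumulative curves add neurons in ascending individual decMI and retrain
from scratch at each prefix (no warm starts, for determinism); per-FOV
series are linearly interpolated onto fixed 18-point (full pool) or
11-point (non-discriminative pool) percentage grids so FOVs of different
sizes can be averaged. The pipeline decodes every k-th prefix (default
k = 4) before interpolating — the curves are smooth in pool size, and this
keeps the sweep inside a desktop-scale budget. Pairing gain is
decMI(discriminative neuron + non-discriminative pool) − decMI(neuron
alone); noise-correlation gain is true decMI minus the median over
within-class per-neuron trial shuffles; the stimulus-conditioned choice
gain splits trials by held-out stimulus-decoder correctness (S+/S−) and
differences the behavioral %-correct-choice (NaN when either group is
empty). Session inclusion requires ≥6 Lick and ≥6 No-lick trials for choice
decoding and ≥6 correct and ≥6 wrong trials for any decoding of training
sessions.

## d-prime and group statistics

|d′| uses unbiased (n−1) variances; zero-variance groups return 0 (equal
means) or +inf (unequal). The median-threshold variant zeroes all frame
values at or below the neuron's across-trial median ("strictly above"
survives) before integrating over the first second. Aggregation is strictly
two-level — neuron → FOV mean → across-FOV mean ± SEM — so unequal neuron
counts never weight a group mean. Stage comparisons use two-sided KS or
Mann-Whitney U tests with explicit per-panel Bonferroni factors; asterisk
codes at 0.05 / 0.01 / 0.001.

## Reproducibility and problem sizes

Every stochastic stage derives its generator from a master seed through
`numpy.random.SeedSequence` spawning (seed, stage, substream), so reruns are
bit-identical; the pipeline writes a manifest with parameters and SHA-256
content hashes of every output. The test suite and the acceptance script
run the sweep at 40 neurons × 160 trials with a −1…+2 s alignment window
and 30 permutations, and the calibration checks at 500 neuron-tests per
significance family (120 for II, whose per-neuron cost is ~15 frames × 51
convex programs × 2 targets) — sizes chosen to keep a full single-core run
in the tens of minutes while leaving the binomial error on a 5% rate near
one percentage point. The analysis drivers default to 80 neurons ×
200 trials.

## Known limitations

- The PT correction targets the MI estimator's leading-order bias; at very
  small trial counts (<30) residual bias remains and the permutation test is
  the more trustworthy signal.
- II significance permutes the neural response, breaking stimulus and choice
  associations simultaneously; a choice-only or stimulus-only null would
  answer a different question and is not implemented.
- The cumulative-curve interpolation reads between computed prefixes;
  below one neuron's pool percentage the curve is clamped to the first
  computed value.
- The exhaustive PID oracle is restricted to |S|·|R|·|C| ≤ 16 and is a lower
  bound at any finite grid step; the solver, not the oracle, is the runtime
  path.
- Decoder regularization (C = 1.0) is a convention, not a fitted value;
  conclusions that depend on absolute decMI levels should sweep it.
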