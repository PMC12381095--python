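# Methods

This note documents the models, conventions and numerical choices behind
`retromem`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Paradigm and schedules

The paradigm has three phases over the same object set. Objects are assigned
a fixed screen location (top, bottom, left, right) and a working-memory (WM)
condition: PT (prioritization + testing — the object is retro-cued and
probed), NPT (non-prioritization + testing — neutral cue; Experiment 2
only), NP (displayed in WM but never cued), ABS (absent from WM).
Experiment 1 splits 180 objects equally over {PT, NP, ABS}; Experiment 2
splits 300 equally over all four.

**Encoding / retrieval.** Each object appears exactly twice; the order is two
concatenated independent permutations, so all objects appear once before any
repetition.

**WM schedule.** Every WM-eligible object appears exactly four times, always
at its encoding location. Selective trials pair one PT with one NP object,
one per display axis (horizontal = left/right, vertical = top/bottom); the
cue points at the PT object's axis. Probes are assigned by shuffled
exact-count templates rather than Bernoulli draws, so the proportions hold
exactly for any trial count divisible by four: match 50%, non-cued 25%, new
25% of selective trials, and for Experiment-2 neutral trials, one of the two
displayed objects 50% / a new object 50%. "No" responses are therefore
exactly half of each cue type's trials. New-object probes come from a
reserved id pool never used in encoding.

Design choices where the design was genuinely open:

* **Location balance.** Locations are balanced across objects — exactly
  n/4 per location overall, and within each condition the per-location
  counts differ by at most one. This removes a location-condition confound
  that would otherwise leak condition information into the location decoder.
  Exact within-condition balance is impossible when a condition's size is
  not divisible by four (Experiment 2: 75 per condition); the remainders are
  rotated across conditions so that the PT/NP horizontal-vertical appearance
  counts stay complementary, which the selective-trial axis pairing
  requires.
* **Neutral-trial pairing.** Two NPT objects cannot always be placed one per
  axis (75 objects cannot split evenly into horizontal/vertical), so neutral
  trials only require the two objects to occupy *different positions*.
  Probing counts of 0–4 per NPT object then arise naturally.
* **Experiment-2 WM trial count.** 75 PT + 75 NPT + 75 NP objects × 4
  appearances ÷ 2 objects per trial = 450 trials under every pairing scheme
  consistent with the stated design, and that is what the scheduler
  produces. Published descriptions of this paradigm sometimes cite 480 WM
  trials; we found no object-accounting that reaches 480 without
  undocumented filler trials, and we do not invent any.

## Synthetic EEG generator

One participant's phase epochs are

```
data(trial, channel, t) = gain_p · A_loc · P_phase[:, loc(trial)] · env_phase(t)
                        + gain_p · A_oldnew(cond) · w_parietal · env_oldnew(t)   (retrieval only)
                        + noise(trial, channel, t)
```

* **Location patterns.** `P_phase` has orthonormal columns (one per
  location). A shared orthonormal block S and mutually orthogonal
  phase-specific blocks give `P_phase = sqrt(ρ)·S + sqrt(1−ρ)·P_spec`, so
  the cosine between one location's patterns in two phases equals ρ
  *exactly*, within-phase Grams are the identity, and different locations
  are orthogonal across phases. ρ = 1 reproduces an identical
  representational format across phases; ρ = 0 an orthogonal one.
* **Temporal envelopes.** Half-cosine bumps (sin πx on the window, zero
  outside): smooth onset/offset with peak 1. Only the windows are
  empirically motivated (location signal: encoding 60–1000 ms, WM
  70–1460 ms, retrieval 330–1360 ms; old-new component 430–670 ms); the
  shape is a modeling convention.
* **Old-new topography.** Gaussian falloff (scale 0.06 m) around the
  centroid of Pz/P1/P3/P5, normalized so the *cluster-averaged* weight is 1;
  an injected amplitude of a μV therefore appears as an a-μV
  cluster-averaged deflection, which the forward-model tests exploit.
* **Noise.** Per trial, 1/f^α spectra (α = 1 by default) with random phases,
  scaled analytically to the target per-sample standard deviation
  (default 5 μV), then mixed across channels by the Cholesky factor of a
  distance-decaying correlation matrix exp(−d/0.12 m) built from standard
  10-05 electrode positions.
* **Participant heterogeneity.** A log-normal amplitude gain per participant
  (log-sd 0.3) on all signal components; behavior adds a common normal shift
  of the per-condition accuracy probabilities (sd 0.10, clipped to
  [0.02, 0.98]) and a mean-one log-normal RT gain (log-sd 0.12). These
  reproduce realistic between-subject spread while leaving grand means at
  the configured values up to negligible clipping bias.
* **Behavior.** Accuracy ~ Bernoulli(p_condition); RT ~ log-normal with
  (μ, σ) solved from the configured mean/SD in ms. Default parameters are
  the Experiment-1 and Experiment-2 condition means/SDs of the empirical
  tables the paradigm is calibrated to (e.g. PT accuracy 81.68%).

All randomness derives from `numpy.random.SeedSequence(seed, spawn_key=
(participant, stream))`, so any (seed, participant, phase) triple is
bit-reproducible and participants are independent streams.

What the generator does **not** emulate: volume-conducted dipole physics,
eye movements and other artifacts, autocorrelated behavior (sequential
effects), non-stationary noise, or trial-to-trial latency jitter. Passing
tests therefore demonstrate the *statistical machinery* (calibration, power,
invariances) under the assumed signal structure, not fidelity to any
particular recording system.

## Preprocessing

Hamming windowed-sinc FIR filters via `scipy.signal.firwin`, with the tap
count odd (symmetric type-I) and the cutoff interpreted as the −6 dB
(half-amplitude) point, matching common EEG-toolbox reporting. Zero-phase
application is forward–backward (`filtfilt`) with odd-reflection padding of
min(3·taps, n−1) samples; the effective magnitude response is the square of
the designed one. Downsampling is an anti-alias lowpass (0.8 × target
Nyquist) followed by integer-factor decimation; non-integer ratios are
rejected.

Automated epoch rejection iterates: flag trials exceeding an absolute
amplitude threshold (default 500 μV) or whose improbability score — the
maximum |z| across trials of three per-trial summaries (mean, log-variance,
peak-to-peak) — exceeds 5 SD; reject at most ⌈5% of current trials⌉ per
iteration, worst first (amplitude violations ranked above score violations);
stop when nothing is flagged. This is a deliberately simple, fully specified
stand-in for joint-probability artifact criteria; it feeds only synthetic
robustness tests, so calibration differences from any particular toolbox are
acceptable. ICA, channel rejection and interpolation are out of scope —
imported data are assumed cleaned upstream.

## Cluster-based permutation test

Cluster statistic: **length in time points** (the procedure records cluster
sizes, not mass). Pointwise paired t, two-sided by default for ERP contrasts
(the sidedness is configurable; decoding uses one-sided by construction).
Clusters require ≥ 2 strictly sub-α p-values. The null permutes each
participant's two condition waveforms independently (a sign flip of the
difference); when `n_permutations ≥ 2^n` the test switches to exhaustive
enumeration. The significance cut is the 95th percentile by the
**nearest-rank** method, and observed clusters must *exceed* it (ties are
not significant). Sampled nulls do not force-include the observed labeling.
The number of time points is always derived from the configured window and
sampling rate (301 points for 0–1200 ms at 250 Hz). Degenerate zero-variance
time points get p = 1 when the mean difference is 0, else p = 0.

The decoding variant swaps each participant-by-timepoint cell's accuracy
with the chance constant (cell-wise sign flips of accuracy − chance) and
uses one-sided t-tests, since only above-chance decoding is meaningful. The
tested unit is the participant-level accuracy; chance is 1/n_classes (0.25
for four locations), with the constant configurable.

## Decoding

LDA is implemented directly: class means, pooled within-class covariance
(dof = n − k), shrinkage toward the covariance's own diagonal,
Σ_reg = (1−λ)Σ + λ·diag(Σ). λ defaults to a Schäfer–Strimmer-style analytic
intensity (ratio of summed sampling variances of the off-diagonal entries to
their summed squares, clipped to [0, 1]); a fixed λ can be forced. Features
with zero within-class variance fall back to unit variance, which makes the
λ = 1, one-trial-per-class limit the nearest-class-mean classifier. Ties in
the discriminant scores resolve to the lowest class index. Fold construction
subsamples every class to the largest common multiple of the fold count and
spreads classes evenly, so the majority-class baseline equals chance
exactly. Super-trials (default k = 4, the per-object repetition count, since
no canonical value exists) average k distinct same-class trials *within* the
train or test side of a fold, never across; leftovers are dropped. Fold and
super-trial randomness is averaged over `n_repeats` (default 10)
repetitions.

Cross-phase decoding trains per time point inside the training window and
averages over training time points (a `window_mean` mode trains once on
window-averaged features — cheaper, nearly as sensitive in practice). The
designated windows (encoding 0–500, WM 300–800, retrieval 500–1000 ms) have
equal length, so the two reciprocal directions are averaged on the common
relative time axis; both directions draw identically seeded randomization
streams, making the result invariant to argument order.

## Behavioral statistics

The omnibus rm-ANOVA uses the textbook sums-of-squares decomposition;
ε_GG comes from the double-centered condition covariance; Mauchly's W uses
the first-order χ² approximation on orthonormal contrasts (reference
implementations that add a second-order term differ in the third decimal of
the p-value). η_p² = SS_cond/(SS_cond + SS_err). The Friedman χ² applies the
standard tie correction; Kendall's W = χ²/(n(k−1)). Wilcoxon reports both
the min-sum and positive-rank-sum statistics (conventions differ across
software), uses exact enumeration for n ≤ 12 and a tie- and
continuity-corrected normal approximation otherwise; r = z/√n with n the
original sample size. BH-FDR is the step-up adjustment with enforced
monotonicity. The JZS Bayes factor integrates the noncentral-t likelihood
over a Cauchy(0, 0.707) effect-size prior by adaptive quadrature; the test
suite checks it against an independent g-prior quadrature to three
significant figures. RT analyses include all trials regardless of accuracy.
A Lilliefors normality screen is attached to the ANOVA output but never
gates which tests run — parametric and non-parametric results are always
produced side by side.

## Calibration and problem sizes

The suite verifies, at sizes chosen to keep a full run in the low minutes:
type-I error of the cluster test within [0.02, 0.08] over 500 null datasets
(15 participants, 75 time points, 1000 permutations each, 1/f noise);
exact agreement with exhaustive enumeration at small n; label-shuffled
decoding within 3 SE of 0.25; cross-phase transfer present at ρ = 0.7 and
absent at ρ = 0; and end-to-end recovery of an injected old-new cluster with
14 participants and 48 objects. The acceptance script simulates the full
Experiment-1 behavioral dataset (43 participants × 360 retrieval trials) and
recovers the configured 81.68% prioritization+testing accuracy within
Monte-Carlo error of the grand mean (≈1.6 percentage points SE).

## Known limitations

* The generator's effect amplitudes are free parameters in μV; no published
  amplitudes exist for the old-new differences, so only detection/power
  properties are meaningful, never absolute amplitudes.
* Channel-space (2-D) cluster formation, TFCE, nonlinear classifiers,
  searchlights, Bayesian ANOVA and mixed-effects models are out of scope.
* The preprocessing module is intentionally minimal (no ICA/IC labeling,
  channel interpolation or re-referencing).
* `decode_within_phase` at full resolution (every time point, 10 repeats,
  64 channels) is CPU-hungry; `time_indices`/`decode_time_step` subsample
  the time axis, and the pipeline defaults do so.
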