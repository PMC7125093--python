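# Methods

## Pipeline model

`eegselect` treats subject identification as a two-layer decision on
fixed-length, epoch-segmented multi-channel EEG. The first layer is
novelty detection: a one-class SVM with an RBF kernel is trained only on
feature vectors of the enrolled (non-intruder) subjects from the enrolment
session and accepts or rejects any incoming vector at the decision
function's natural zero boundary — no threshold tuning. The second layer
is a multi-class linear SVM over the enrolled subjects; an instance is
identified only if the first layer accepted it. Authentication quality is
counted per instance: TAR is the accepted fraction of enrolled subjects'
test-session epochs, TRR the rejected fraction of intruder epochs, and
FAR ≡ 1 − TRR by construction.

The assumptions this rests on: epochs are exchangeable within a
(subject, session); the enrolment and test sessions differ only by
moderate non-stationarity; and subject identity is expressed in the
spectral/complexity structure of the signal, which is what the features
measure.

### Pre-processing

Common average referencing subtracts the instantaneous mean over **all**
recorded electrodes from every channel, per epoch. Two design points:

* CAR is always computed over the full montage, never over a candidate
  channel subset. The per-channel feature cache is built once and reused
  for every mask the optimizer proposes; subset-dependent referencing
  would invalidate that cache.
* CAR is applied per epoch rather than over a concatenated recording —
  the pipeline is epoch-wise throughout, and per-epoch referencing makes
  each epoch self-contained. CAR is an idempotent linear projection, so
  repeated application is harmless.

### Features

Each channel of each epoch is decomposed by empirical mode decomposition
(EMD): cubic-spline envelopes through the local extrema, extrema mirrored
two-deep at the boundaries, the Cauchy standard-deviation sifting criterion
with threshold 0.2, at most 50 sifting iterations per mode and at most 10
modes. Sifting literally subtracts each mode from the running residual, so
the reconstruction identity (sum of IMFs + residual = signal) holds to
floating-point accuracy and is asserted in the tests.

Sifting can produce redundant modes far in shape from the signal; the two
IMFs **closest** to the original signal in Minkowski distance (order p = 2
by default, configurable) are retained. Each is summarized by four
features:

| feature | definition | default knobs |
|---|---|---|
| instantaneous energy | `log10(mean(x²))` | floor 1e-12 inside the log |
| Teager energy | `log10(mean |x[n]² − x[n−1]x[n+1]|)` | same floor |
| Higuchi fractal dimension | negated LS slope of log L(k) vs log k | k_max = 10 |
| Petrosian fractal dimension | `log10 N / (log10 N + log10(N/(N+0.4 N_Δ)))` | zeros in diff carry the previous sign |

The energies are log-scaled so that amplitude ratios, not absolute
microvolt levels, drive distances — a declared convention, visible in the
configuration. Features are used raw (no standardization) by default; a
`standardize` flag on the evaluation config fits a z-scaler on the
training vectors for ablation.

Fixed dimensionality is a hard contract (8 features per channel): when a
degenerate signal yields fewer than two IMFs, the closest available mode
(or the residual itself, for zero IMFs) is duplicated. Classifiers cannot
operate on ragged vectors, and duplication is the least-informative
completion.

### Candidate evaluation

A chromosome of `n_channels + 8` binary genes decodes to a channel mask
plus `nu` and `gamma`, each via a 4-bit most-significant-bit-first index
into the 16-entry value table. One candidate evaluation trains the
one-class model on the enrolment-session vectors of the enrolled subjects
(masked channels only, served from the cache), measures TAR/TRR on the
test session, and scores identification accuracy by stratified 10-fold
cross-validation over the enrolment-session vectors. One fixed fold
assignment (seeded) is shared by all candidates of a run, so objective
differences between candidates reflect channels and parameters, not fold
resampling. The identification pool is the enrolment session's
non-intruder epochs — consistent with training-flow evaluation; pooling
both sessions is possible via the evaluation config.

Numerical guard: the ν-SVM dual is infeasible for `nu < 1/n_train` and
degenerate at `nu = 1`, both of which occur at the ends of the lookup
table; the solver receives the value clipped to `[1/n_train, 0.999]`
while reports carry the decoded value.

The all-zero channel mask is penalized with the sentinel minimization
image `(n_channels_max + 1, 1, 1, 1)` instead of being repaired: repair
would silently inject channels the search never chose, and the sentinel
keeps evaluation total.

### Search

Both NSGA variants share binary-tournament mating selection, two-point
crossover (probability 0.9), per-gene bit-flip mutation (probability
1/n_genes) and elitist survival of the combined parent+offspring pool
through fast non-dominated sorting. NSGA-II thins the last admitted front
by crowding distance; NSGA-III by niche counts against a systematic
(Das–Dennis) reference-point lattice on the unit simplex — 4 divisions on
4 objectives gives 35 points, configurable. These operator choices are
standard binary-GA defaults, all exposed in `GAConfig`.

Run defaults follow the study protocol: population 30, at most 500
generations, and a termination check every 10th generation. The
termination metric (the protocol names a tolerance of 1e-4 but no metric)
is defined here as the mean distance from the current non-dominated set to
the previous checkpoint's, after joint ideal/nadir normalization; movement
below tolerance stops the run.

Every distinct chromosome is evaluated once (evaluations are memoized —
the evaluator contract is deterministic) and logged. The returned front is
the non-dominated set over **all** evaluated candidates rather than the
final population alone: with four objectives the true front routinely
exceeds 30 members (one per channel count is typical), and the archive is
what makes exact comparison against brute-force enumeration meaningful.
Duplicate objective vectors collapse to one representative, so the front
is a fixed point of the brute-force domination filter.

## Synthetic data

The generator emulates the shape of a multi-session ERP study — defaults:
26 subjects, 56 channels, 200 Hz, 1-s epochs, 25 epochs per session, ≥2
sessions — without claiming biophysical realism. Per subject: carrier
sinusoids with frequencies in 6–30 Hz and subject-specific amplitudes,
projected onto the informative channels through subject-specific loadings,
plus a Gaussian ERP-like bump peaking 300 ms after epoch onset. Every
channel receives independent 1/f (exponent ≈ 1) background noise — the
spectral shape of real EEG, chosen over white noise because it stresses
EMD realistically. A per-session multiplicative amplitude jitter models
between-day non-stationarity.

With `distinct_signatures` (default), subject parameters are assigned by
stratified slots: each carrier band, the amplitude scale and the spatial
loading profile are divided into one slot per subject and dealt by
independent random permutations. Any two subjects then differ in several
signature coordinates at once — the premise of biometric EEG. Free random
draws (used by the "hard" benchmark) deliberately allow near-collisions
between subjects, which with pools of only a few subjects otherwise
dominate the intruder-rejection statistics.

Two frozen benchmark instances support end-to-end testing:

* **easy** — 8 subjects × 16 channels × 2 sessions × 25 epochs, 5
  informative channels, amplitude 10 µV vs noise level 1.2, 4% session
  jitter. Identification is near-perfect from the full montage; the
  one-class layer, whose RBF distances the 11 noise-only channels dilute,
  reaches TAR/TRR ≥ 0.9 only on compact informative-channel masks — which
  is precisely what the channel selection is for, and what the recovery
  test checks against the ground-truth channel set.
* **hard** — free-drawn signatures crowded into 9–12 Hz, amplitude 2.5 µV
  under noise 4.0, 40% jitter. No decoded parameter choice reaches a
  balanced TAR/TRR above 0.9, and identification stays far below 1.

What passing on synthetic data does **not** show: robustness to artifacts
(blinks, EMG), volume-conduction correlations between channels, realistic
ERP variability, or long-term drift beyond a scalar amplitude jitter.
Results on these benchmarks validate the machinery, not field performance.

## Problem sizes

Tests and the acceptance script run on reduced instances chosen so the
whole suite completes in minutes on one CPU: the easy benchmark above
(feature cache ≈ 6 400 channel-epochs), a 6-subject/8-channel instance
whose 255 channel masks are exhaustively enumerable as the search oracle,
and a 40-generation NSGA-II budget for the end-to-end run (the archive
front on these instances stabilizes well before that). The study-scale
defaults (56 channels, 26 subjects, 500 generations) remain the
configuration defaults.

## Known limitations

* EMD is the textbook cubic-spline sifting; no ensemble (EEMD) or
  noise-assisted variants, so mode mixing under heavy noise is possible —
  visible as feature-variance inflation on the hard benchmark.
* The one-class layer is a single pooled model over all enrolled
  subjects; per-subject models are a natural extension the architecture
  leaves open.
* `evaluate_candidate` re-trains SVMs per candidate; wall-clock cost is
  dominated by cross-validation, and the memoization only helps within a
  run. Caching across runs of different splits is deliberately not done
  (the objective values depend on the split).
* The tabular text dataset format favours inspectability over size;
  a 56-channel, 26-subject study occupies some hundreds of megabytes as
  text. Standard binary EEG formats are out of scope.
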