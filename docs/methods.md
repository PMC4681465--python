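# Methods

## Problem and model

An EEG channel contaminated by an ocular (EOG) or cardiac (ECG) artifact is
modelled as

    s(k) = e(k) + c(k),

where `e` is the artifact-free EEG and `c` is the artifact's contribution at
the EEG electrode. A simultaneously recorded reference channel `r` (the EOG or
ECG itself) observes the artifact source, but `c` is not simply proportional
to `r`: the propagation path to the scalp electrode distorts the waveform, so
`c = P(r)` for some unknown, possibly nonlinear, pathway `P`.

The cancellation scheme is adaptive noise cancellation: fit a regressor
`f([r(k), r(k-d)]) ≈ s(k)` from the reference and a `d`-sample delayed copy.
Because `e` is (by physiology) uncorrelated with `r`, the clean EEG acts as an
unlearnable residual and the minimizer of the prediction MSE approaches
`E[s | r] = P(r)`; the fitted prediction is therefore an estimate `ĉ` of the
contribution, and the cleaned signal is `ŝ = s − ĉ` (exact subtraction, so
`ŝ + ĉ` reproduces `s` bit-exactly). The regressor delay defaults to
`d = 1` sample and is configurable; the delayed column is zero-padded at the
start so the cleaned output stays sample-aligned with the input.

All filters standardize inputs and target internally — z-scoring with the
population (divide-by-N) standard deviation, except the functional-link
filter, which max-abs scales its inputs into [−1, 1] because its trigonometric
basis is periodic. Predictions are mapped back to signal units before
subtraction. This makes Gaussian widths and novelty thresholds scale-free.

## The three adaptive filters

**ANFIS.** A first-order Takagi–Sugeno fuzzy system on a grid partition:
3 Gaussian membership functions per input → 9 rules (both configurable), each
rule with a linear consequent `p·x₁ + q·x₂ + b`. Training is hybrid: for fixed
premises the consequents are the solution of a ridge-regularized least-squares
problem in the normalized-firing-strength design matrix; the premise
centers/widths then take a gradient step on that optimal-consequent loss, with
the gradient computed by central differences (step 1e-5) and a backtracking
line search (halve the step up to 8 times, revert on failure). Backtracking
makes the per-epoch training MSE non-increasing by construction. Defaults:
20 epochs, normalized step size 0.05, widths floored at 1e-3.

**RBFN.** Gaussian radial basis network with a fixed budget of neurons
(default 9): centers by seeded k-means on the standardized regressor rows,
widths as 1.5× the nearest-other-center distance (floored at 1e-6; duplicate
centers fall back to the median width), output weights and bias by ridge least
squares on the activations. scikit-learn's k-means relocates empty clusters
internally, so no re-seeding logic is needed.

**FLN-RBFN.** Each input value `v` is expanded into the trigonometric
functional-link basis `[v, sin(jπv), cos(jπv)]` for `j = 1..order` (default
order 1, expanded dimension 6 for two inputs). An RBF network in this expanded
space is grown sequentially by a resource-allocating novelty rule: at sample
`k` with prediction error `e` and distance `δ` to the nearest center, a neuron
is allocated when `|e| > e_min` and `δ > ε` (center = expanded input, width =
0.8·min(δ, 10ε) floored at 0.05, weight = `e`); otherwise weights and bias take
a normalized-LMS step. Defaults: `ε = 0.7`, `e_min = 0.05` (both in
standardized units), at most 50 neurons (growth stops with a logged warning
beyond that), 2 sequential passes. After growth the output layer is refit by
ridge least squares on the allocated centers — the architecture stays
data-chosen while the weights become batch-optimal; `refit=False` keeps the
purely sequential weights. The neuron count is consequently data-dependent:
on the default blink scenarios it settles around 7–8.

Every least-squares solve uses ridge regularization (default λ = 1e-6) so
degenerate inputs remain well-posed; with λ = 0 an underdetermined solve
raises instead of silently minimum-norm-fitting. Training is deterministic
given (data, config, seed) — no data shuffling, k-means seeded — and models
serialize to JSON that reloads to bit-identical predictions (Python's float
JSON encoding is exact round-trip).

## Wavelet-threshold baseline

The non-adaptive comparator needs no reference channel. The contaminated
signal is decomposed by a DWT (default db4, 5 levels, symmetric boundary
extension — noted because extension changes edge coefficients). The removed
artifact is reconstructed from the approximation band plus the thresholded
coefficients of the two coarsest detail levels; all finer details are
untouched, since blink energy concentrates below ~4 Hz at 256 Hz sampling
while EEG rhythms live above. The threshold defaults to the universal rule
`σ̂ √(2 ln N)` with `σ̂ = median(|finest detail|)/0.6745`; soft thresholding by
default, manual thresholds supported. A threshold of exactly 0 passes
coefficients through unchanged (avoiding a 0/0 in the soft rule on zero
coefficients); with threshold 0 and all bands assigned to the artifact the
split reproduces the input to 1e-10 — the DWT perfect-reconstruction
identity. `cleaned = contaminated − removed` exactly, so the decomposition is
additive to machine precision.

## Synthetic contamination scenarios

Real contaminated recordings never include the artifact-free EEG, so
evaluation uses generated scenarios where clean signal, reference and true
contribution are all known. Defaults describe a 10-s epoch at 256 Hz:

- **Clean EEG** — band-limited Gaussian components (theta 4–8 Hz at relative
  RMS 0.5, alpha 8–13 Hz at 1.0, beta 13–30 Hz at 0.3) plus a 1/f-shaped
  noise floor (relative RMS 0.4), scaled to overall RMS 10 (microvolt-like
  units). Sampling below 64 Hz is rejected (beta band unrepresentable).
- **EOG** — raised-cosine blink pulses (width 300 ms, amplitude 5× the
  clean-EEG RMS with 15% per-blink variation) at Poisson times, plus a small
  sub-0.5-Hz baseline drift. The default rate is 1.0 Hz — the high end of
  spontaneous blinking — so a 10-s epoch reliably contains several blinks;
  at sparser rates a short epoch can draw no blinks at all and the scenario
  degenerates.
- **ECG** — a biphasic (Mexican-hat) QRS-like template (~80 ms) repeated at
  the heart-rate interval with 5% multiplicative jitter and a 200-ms
  refractory floor.
- **Pathway** — `c = FIR(g(gain · r))` with `g(x) = s·tanh(x/s)` a scaled
  saturating nonlinearity (saturation `s` expressed in signal units, default
  50) and a 3-tap smoothing FIR [0.5, 0.3, 0.2]; defaults gain 0.8. The
  identity pathway (`g = id`, arbitrary FIR) gives controlled linear
  scenarios; `linear_scenario` uses taps [0.8, 0.3], i.e. 0.8 on the direct
  and 0.3 on the one-sample-delayed reference.

Every generator is a pure function of (parameters, seed). With these defaults
the contaminated signal correlates with the reference at ~0.6–0.75 while the
clean EEG stays below |0.1| (verified across seeds). What the generator does
*not* emulate: cortical dipole geometry, non-stationary band power, muscle
(EMG) artifacts, electrode pops, or amplitude distributions of any specific
recording system — so passing tests demonstrate correct mechanics and
relative method behaviour on plausible signals, not clinical performance.

## Evaluation criteria

- **MSE** `(1/N) Σ (y−q)²` between two equal-length signals. On synthetic
  scenarios the benchmark computes cleaned-vs-ground-truth-clean MSE, which
  only simulation makes possible.
- **Correlation** — Pearson coefficient (scale/shift-invariant, undefined and
  rejected for constant signals) between a signal and the reference, before
  vs after cleaning; successful cancellation collapses it toward zero. A raw
  unnormalized variant (inner product of mean-removed signals) is exposed for
  users who want magnitude-style values; it is scale-dependent and not
  bounded by 1.
- **Power spectrum** — Welch periodogram (256-sample segments, 50% overlap,
  density scaling; single-segment periodogram fallback for short signals,
  logged) for inspecting which bands cleaning removed.

The benchmark harness runs any subset of {anfis, rbfn, fln-rbfn, wavelet}
across seeds (each seed drawing a fresh scenario when a factory is passed) and
aggregates per-method medians — medians, not means, to be robust against
occasional bad local optima.

## Problem sizes and numerical choices

Benchmarks and the acceptance script use 10-s, 256-Hz epochs (2560 samples)
and 10–25 seeds per experiment — enough for stable medians while keeping a
full run in tens of seconds. Tolerances: least-squares substeps match a dense
normal-equations oracle to 1e-8; standardization round-trips to 1e-10; the
wavelet split is additive to 1e-10; subtraction-based cancellation is
bit-exact.

## Known limitations

- The two-tap regressor `[r(k), r(k−d)]` cannot model pathway memory longer
  than the FIR the scenario applies; a longer tapped delay line would need a
  wider regressor (single delay kept for parity with the two-input scheme).
- ANFIS cost grows as (MFs per input)^inputs; the grid partition is only
  sensible for the two-input case used here.
- The wavelet baseline removes *all* low-frequency content, clean EEG
  included — visible in its much larger cleaned-vs-clean MSE; that trade-off
  is the point of comparing it against reference-based cancellation.
- EDF reading requires the optional `mne` dependency; CSV needs the sampling
  rate supplied by the caller.
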