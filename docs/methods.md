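# Methods

## Pipeline overview

A decoding run maps a continuous multichannel recording and a self-paced
event table to (i) cross-validated decoding performance, (ii) a
permutation p-value, and (iii) a localization report over (electrode,
frequency band) pairs:

1. **Conditioning** — common-average re-reference (per session), zero-phase
   IIR notch at the line frequency and its harmonics, polyphase
   anti-aliased downsampling to the working rate (436 Hz default).
2. **Epoching** — 1 s windows aligned to integer seconds; an event's onset
   is rounded to the nearest second (halves away from zero) and its
   duration (reaction time; fixed 5 s for cued rest) floored; a window is
   kept only if exactly one stimulus's true, un-rounded interval overlaps
   it. Math windows are balanced against a random subsample of the pooled
   non-math windows. Epochs are cut at −200…+1200 ms with no baseline
   correction or artifact rejection.
3. **Features** — 7-cycle complex Morlet power on a geometric grid of 29
   frequencies (1–110 Hz), log-rescaled point-wise, averaged within the
   six canonical bands (δ, θ, α, β, low-γ, high-γ), cropped to 0–1000 ms.
4. **Kernels** — one linear (dot-product) kernel per (channel, band) pair,
   channel-major order; feature-space mean-centering and normalization use
   training-epoch statistics only and are re-done inside every
   cross-validation split.
5. **Model** — simplex-constrained MKL (simpleMKL family), nested 10-fold
   CV over `C ∈ {10⁻², …, 10³}`, permutation significance, and
   fold-averaged contribution reports.

## The MKL solver

`J(d)` is the optimal SVM dual value on `K(d) = Σ d_m K_m`; it is
minimized over the probability simplex. Each iteration solves the SVM
dual at the current `d` (giving `J` and, by Danskin's theorem, the
gradient `∂J/∂d_m = −½ Σ_ij α_i α_j y_i y_j K_m[i,j]`), forms the reduced
gradient against the largest coordinate `μ` (ties → lowest index), zeroes
descent components that would push a zero coordinate negative (pinned
coordinates may re-enter when their reduced gradient turns favourable),
and line-searches along the direction: full steps are accepted while the
objective falls, pinning each coordinate that reaches zero exactly, and
the remainder is resolved by golden-section search. Line-search
evaluations use `K(d + γD) = K(d) + γ K(D)`, so their cost is independent
of the number of kernels.

**SVM dual.** Solved by an in-package SMO (sequential minimal
optimization) with maximal-violating-pair working-set selection, jitted
with numba and warm-startable — the line search re-solves thousands of
closely related problems, and warm starts plus a relative bound-membership
tolerance (values within 1e-10·C of a bound are treated as at the bound)
keep each re-solve to a handful of iterations. The bias is averaged over
free support vectors; without free support vectors the midpoint of the
KKT interval is used.

**Stopping.** Primary criterion: relative duality gap of the kernel
combination, `(max_m S_m − Σ_m d_m S_m)/|J| ≤ tol` with
`S_m = ½ αᵀQ_mα`, default `tol = 0.01`. A secondary stop triggers when
the relative objective decrease stays below 1e-3 for two consecutive
iterations: on unstructured (e.g. label-permuted) data the iterate
becomes stationary long before the gap criterion fires, and the extra
iterations change nothing but runtime. `stall_tol=0` disables it (the
KKT-focused tests do). Default iteration cap 200; non-convergence returns
the best iterate with a warning. `d` starts uniform over non-degenerate
kernels unless a warm start is given; the inner CV warm-starts along the
ascending C path, which is an optimization only — each fit still solves
its own problem to tolerance.

**Degenerate kernels.** A kernel whose training block is constant (zero
trace after centering) is flagged, zeroed, and excluded from the simplex,
with a warning.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| working rate | 436 Hz | sampling rate after downsampling; sets the 436-sample feature length per kernel. Studies in this repo that only need band power up to 110 Hz use 256 Hz to halve feature cost |
| notch Q, harmonics | 30, 3 | −3 dB width f₀/Q ≈ 2 Hz at 60 Hz; harmonics at/above Nyquist are skipped with a warning |
| wavelet cycles | 7 | constant across frequencies; the ±200 ms epoch margins absorb edge effects before the 0–1000 ms crop |
| log floor ε | 1e-12·max power | keeps zero-power bins finite |
| kernel normalization | unit mean diagonal of the centered train block | makes kernel scale irrelevant to the fit; trace-based rather than Frobenius — selectable in principle but the choice only rescales C per kernel |
| C grid | 10⁻²…10³ | six decades; inner CV picks by balanced accuracy, ties to the smallest C |
| outer folds | 10, contiguous blocks | contiguous blocks keep temporally adjacent (autocorrelated) epochs in the same fold, limiting optimistic bias; random stratified folds available |
| inner folds | 3, stratified | leaves ⅔ of the outer-training set per inner fit; 3 rather than 5 keeps the nested procedure (and its permutation refits) tractable on a single CPU without changing what is estimated |
| permutations | 1000 (library default); studies here use 99 | p = (1+#{null ≥ obs})/(1+n_perm) |

## Permutation scope

Two schemes are implemented. The default, `scope="global"`, draws one
label permutation per replicate and uses it consistently: every fold
trains on the permuted labels and its test block is scored against the
same permuted labels. Under the null hypothesis (features independent of
labels) the permuted runs are then exactly exchangeable with the observed
run, so `P(p ≤ α) ≤ α` holds by construction — we measure a false-positive
rate of ~4% at nominal 5% over 100 scaled-down null studies (slightly
conservative because pooled accuracies tie frequently at small n).

`scope="within_train"` re-shuffles labels independently inside each
outer-training set and scores against the true test labels. This reads
naturally as "permuting the training labels", but it destroys a
correlation the observed statistic has — all observed folds share one
consistent labelling, so their errors co-vary — and at small sample sizes
the observed metric is over-dispersed relative to that null (we measured
~12–13% false positives at nominal 5%). It is kept selectable for
comparison, not as the default.

Balanced accuracy is flagged significant only when both per-class
accuracies are individually significant; with very small test sets the
class-accuracy nulls tie at 100% (a degenerate all-one-class null
predictor), making this flag deliberately conservative there.

## The synthetic generator

Each channel is a sum of six band-limited components — Gaussian noise
spectrally masked to each canonical band, unit RMS, with 1/√f amplitude
shaping inside the band under the `one_over_f` model. During each math
stimulus the components of the configured informative (channel, band)
pairs are multiplied by `effect_gain`; `effect_gain = 1` is an exact
null, under which the two classes are exchangeable by construction.
Events alternate in uniformly random order, separated by a fixed
inter-stimulus interval (200 ms default); reaction times are uniform on a
configurable range; non-math conditions cycle through the three
self-referential categories plus 5 s cued rests, so the non-math window
pool exceeds the math pool as in the emulated paradigm. Identical seeds
reproduce recordings bit-for-bit.

What the generator does **not** emulate: epileptiform or movement
artifacts, volume conduction / correlated noise across channels,
non-stationary background, evoked (phase-locked) components, or subject
anatomy. Passing recovery tests therefore show that the chain of
estimator and inference is correct under the model's own assumptions —
not that real ECoG effects of a given size will be recovered.

## Study problem sizes

The recovery study uses 8 channels (48 kernels), an amplitude gain of 2.0
on one (channel, band) pair, 100 epochs per class, nested 10-fold CV at a
256 Hz working rate, 10 seeded replicates, and a 99-permutation test on
the first replicate. The null-calibration study uses 100 replicates of a
2-channel, single-band (2-kernel), ~36-epoch, 5-fold, fixed-C
configuration with 99 permutations each. These sizes were chosen so the
complete battery runs in minutes on one CPU while keeping every
inferential quantity (top-1 recovery rate, p-value calibration) at a
sample size where its expected behaviour is unambiguous.

## Numerical choices and edge cases

- Onset rounding uses round-half-away-from-zero (0.5 s → 1 s), matching
  the convention most readers expect from "nearest integer".
- Windows extending past the recording end are dropped with a warning;
  epoch extraction beyond the recording raises.
- An epoch whose onset rounds ~0.5 s from the true stimulus start carries
  a diluted effect; synthetic studies therefore occasionally misclassify
  single epochs even at large gains.
- `svm_dual_solve` validates symmetry and positive semi-definiteness
  (min eigenvalue ≥ −1e-8·trace/n); the KKT gap tolerance is 1e-8 for the
  public contract and 1e-4 inside cross-validation loops, where the
  model-selection decisions it feeds are far coarser than either.
- Fold sizes differ by at most one; `random_stratified` folds keep class
  ratios within one epoch of the global ratio. Contiguous folds cannot
  guarantee stratification for arbitrary label orderings — with the
  generator's randomised event order they are near-stratified, and a
  single-class training set raises immediately.
- Reports conserve mass exactly: mean contributions and band totals each
  sum to 100% (asserted to 1e-6), and stability counts are monotone in
  the fold-fraction threshold by construction.

## Known limitations

- Binary classification only; no multiclass or regression variants.
- L1 (simplex) regularization only — correlated informative kernels are
  not co-selected, one of a correlated set typically absorbs the mass;
  elastic-net style MKL is out of scope.
- The EDF import path is thin (via MNE) and untested against vendor
  quirks; the NPZ/HDF5 container is the first-class format.
- 3-D cortical rendering is out of scope; localization ships as CSV
  tables plus a 2-D electrode scatter.
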