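# Methods

This note documents the models the package implements, the defaults it
ships, and the design choices made where the underlying procedure left the
design open.  Nothing here asserts an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Stimulus model

Raw grayscale images (default 300×300) are standardized to zero mean and
unit variance, smoothed with a normalized discrete 7×7 Gaussian kernel
(σ = 1.5 px, replicate-padded borders), optionally phase-scrambled, faded
at the edges with a centered Gaussian window, affinely rescaled to span
[−1, 1], and mapped to display intensities

    I(c) = b (I_scaled · c + 1),   b = 127,   c ∈ [0, 1],

so that the displayed contrast is exactly `c = (I_max − I_min)/2b` whenever
the scaled image attains ±1.  Choices:

- **Phase scrambling** draws fresh phases with exact Hermitian symmetry by
  taking the phase field of the FFT of white Gaussian noise; the amplitude
  spectrum is preserved exactly, the DC phase is kept (pixel mean
  unchanged), and Nyquist bins stay real.  Shuffling the existing phases
  would give the same spectral guarantee; drawing fresh ones is simpler.
- **Edge window σ = 0.2** is read as a fraction of image width (60 px at
  300 px); the window is peak-normalized so the center pixel is untouched.
- **Processing order** standardize → smooth → (scramble) → window →
  rescale → contrast.  Whether rescaling precedes or follows the window is
  a genuine ambiguity; rescaling last guarantees the contrast equations
  hold exactly, which is the property the rest of the pipeline relies on.
- Display intensities are kept as floats; quantization to 8-bit gray
  happens only on PNG export, so the contrast round-trip is exact.
- Because real object photographs cannot be redistributed, the fixture
  generator draws synthetic geometric "photographs" (one motif per
  category) with mild texture noise; they exercise every stage of the
  chain but are not natural-image statistics.

## QUEST staircase

Each staircase process maintains a discrete posterior over log₁₀ threshold
(200 nodes on [−4, 0]; Gaussian prior mean −1.3, sd 0.7) for a Weibull
observer

    P(yes | c) = γ + (1 − γ − λ) (1 − exp(−k (c/T)^β)),

with guess rate γ = 0.05, lapse λ = 0.02, slope β = 3.5, and k chosen so
that `P(yes | c = T)` equals the staircase target (0.55 for Day-1
calibration, 0.50 for the Day-2 pooled criterion) — the tracked parameter
*is* the target-probability contrast.  Trials are placed at the posterior
mean (clipped to [10⁻⁴, 1]); the same posterior mean is the final
estimate.  None of γ, λ, β, the prior, or the placement rule is pinned by
the original procedure's description; these defaults are explicit,
configurable stand-ins, and the acceptance surface is parameter recovery
(median relative threshold error < 15% over 50 simulated observers at 40
trials/process), not agreement with any human data.

Interleaving shuffles the 20 processes within blocks of 20, so every image
appears once per block.  Day-2 validation presents 4 trials per image at
the Day-1 thresholds; a recognition rate outside (30%, 80%] triggers two
interleaved 40-trial pooled processes that estimate a single log-gain
applied to all thresholds (targeting 50% across images) — correcting a
global threshold shift, not new between-image differences.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, not
the biophysics of BOLD:

- **Sessions**: 15 runs × 24 trials (20 real = 5/category, 4 scrambled =
  1/category), randomized order, pre-stimulus fixation ~ Exp(mean 9 s)
  truncated to [6, 20] s, stimulus 66.7 ms, post-stimulus fixation 4 s or
  6 s with 2:1 odds, 4 s of questions.
- **Behavior**: recognition ~ Bernoulli(0.50) for real and
  Bernoulli(0.28) for scrambled images; reported category correct with
  probability 0.788 (recognized) / 0.32 (unrecognized), errors uniform
  over the other three categories.  These defaults equal the observed
  group rates, so simulated summaries land on the empirical scale.
- **Betas** per (run, condition, voxel), in percent-signal-change units:
  class amplitude (activated +0.6/+0.3 for recognized/unrecognized real,
  deactivated mirrored negative, subcortical +0.4/+0.2) + a per-ROI
  subject offset (sd 0.15) + pattern strength × a unit-norm ROI- and
  category-specific vector + i.i.d. Gaussian voxel noise (sd 1.0).
  Pattern strength defaults to 2.0 in cortical ROIs on recognized trials
  and 0 elsewhere — the all-or-none structure under test.  The value 2.0
  was calibrated once so that default cortical decoding lands in the
  ~50–60% balanced-accuracy band at the default session size; it is a
  generator parameter, not an estimate.
- **BOLD forward model**: time series = design × betas (+ white or AR(1)
  noise) at TR 2 s, so the GLM is exactly identified on noiseless data.

Real data differ in ways the generator deliberately ignores: spatial
autocorrelation of noise (relevant to how TFCE cluster sizes behave),
temporal autocorrelation beyond AR(1), voxel-wise amplitude heterogeneity,
and session-to-session drift.  Passing tests therefore demonstrate that
the *procedures* are correct and calibrated under their own assumptions,
not that effect sizes transfer to 7 T data.

## GLM

The HRF is a gamma density with mean (lag) 6 s and sd (width) 3 s — shape
(lag/width)² = 4, scale width²/lag = 1.5 s — sampled at TR/16 and
peak-normalized to 1 so betas read as response amplitudes.  "Width" is
read as the gamma's standard deviation, the convention of the fitting
software this replaces; it is configurable.  The 66.7-ms stimulus is
modelled as an impulse (duration ≪ TR).  Each run's design holds one
regressor per (category × recognition × image type) present — up to 16 —
plus a no-response regressor, a 4-s question-period regressor,
discrete-cosine drift columns implementing the 150-s high-pass (kept as
regressors so the model stays linear), and an intercept.  Fitting is
ordinary least squares with an explicit rank check that names collinear
columns.  Percent signal change rescales a beta by the peak of an isolated
unit-event regressor on the TR grid and the voxel mean.  Group inference
on subject-level contrast effects uses a one-sided sign-flip permutation
test (+1-corrected); parametric mixed-effects group models and
Gaussian-random-field cluster correction are out of scope because their
smoothness estimation is tied to real-data preprocessing.

## Decoding

Four-way category decoding uses the six pairwise linear SVMs (C = 1,
scikit-learn's libsvm solver, deterministic given the data up to solver
tolerance ~10⁻³).  Each pairwise decision value is oriented positive
toward the pair's index-first category; prediction is majority vote, ties
broken by the largest summed signed decision value, residual exact ties by
the lowest category index.  Cross-validation leaves one run out;
per-category accuracies are pooled over folds by summing correct/total
counts before dividing (avoiding fold-weighting ambiguity when test runs
are unbalanced) and averaged into a balanced accuracy.  Folds whose
training split lacks a category are skipped and recorded; scrambled-trial
decoding ignores recognition status (scrambled recognized trials are too
few per run for stratified cross-validation).  ROI size matching removes
the lowest-selection-statistic voxels from the larger ROI, ties broken by
voxel index.

`cross_validate` also offers a nearest-class-centroid decoder.  It exists
for Monte-Carlo calibration studies that re-run the decoder tens of
thousands of times, where the SVM's per-fit overhead dominates and the
property under study (error-rate control of the permutation machinery) is
decoder-agnostic.  All headline decoding results use the SVM.

## Permutation inference

Labels are shuffled within runs, preserving the cross-validation
structure and hence exchangeability.  The group null averages one sampled
permuted accuracy per subject (sampling with replacement), by default 100
permutations/subject and 1000 group means; p-values are one-sided with
+1-corrected counts (p ≥ 1/(N+1), never 0), FDR across ROIs at q = 0.05.
The recognized-minus-unrecognized test compares the observed difference to
paired resampled differences.  The searchlight uses spheres of radius 3
(123 voxels when interior, truncated to the mask at edges); group maps are
one-sample t statistics against 25% chance, TFCE-enhanced (E = 0.5,
H = 2, 6-connectivity, dh = max/n_steps with n_steps = 100 by default),
and thresholded by the permutation null of the image-wide maximum TFCE
score.  Group permutations reuse the per-subject permuted maps rather than
re-decoding per group permutation.  Calibration is asserted empirically:
the ROI test's type-I error and the searchlight's family-wise error stay
within three binomial standard errors of 0.05 on signal-free data (200 and
100 replicates respectively, at reduced permutation counts).

A discretization note: with n_steps = 100 the TFCE integral of an isolated
voxel of height h is ≈ 1.015 · h³/3; the closed form is approached as the
step shrinks.  TFCE enhances only the positive part of the map (the tests
are one-sided against chance).

## Mixed model

Balanced accuracies are angular-transformed (arcsin √p), voxel counts
scaled by 1/1000 and mean-centered, location treatment-coded with cortical
as reference (a negative location coefficient ⇒ weaker subcortical
decoding).  The REML fit attempts the maximal per-subject random-effects
structure (correlated intercept and slopes for all three non-intercept
fixed effects) and prunes to random intercepts when that fit is singular
or non-convergent; the fallback is recorded on the fit object.  The
optimizer cascade is L-BFGS, then bounded derivative-free routines; the
contract is on recovered estimates (95% Wald CI coverage ≈ 0.95 over
simulated tables), not on optimizer identity.  The random-effects
covariance is modelled as unstructured (correlated); with ~10 subjects and
~20 ROIs the maximal structure is frequently singular, which is why the
pruning path is first-class rather than an error.

## Pipeline scale and determinism

The default end-to-end configuration is desk-scale: 6 subjects, 6 runs,
the 20-ROI default atlas on a 30³ grid, 12 permutations/subject for ROI
nulls (1000 group means), 10 searchlight permutations/subject with 50
group permutations.  These sizes keep a full run in a few minutes while
leaving every inferential decision identical in structure to the
full-scale procedure; `build_group_null` defaults to the full 100/1000
scheme when called directly.  One master seed spawns independent
per-stage generators (`numpy.random.SeedSequence`), so identical
configurations produce byte-identical TSV outputs, each stamped with the
seed and a configuration digest.

## Known limitations

- No spatial noise correlation: TFCE FWER calibration on white-noise maps
  does not probe the smoothness regime of real BOLD data.
- The nearest-centroid searchlight used in large calibration studies is
  not the SVM decoder; their accuracy maps agree qualitatively on strong
  signal but are not interchangeable estimators.
- The behavioral simulator treats trials as independent; sequential
  effects (learning, fatigue, criterion drift) are absent.
- The BOLD forward model omits run-length physiological confounds, so the
  drift regressors are exercised structurally rather than adversarially.
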