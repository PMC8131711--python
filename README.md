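# liminal

Analysis pipeline for *liminal* object-recognition fMRI experiments —
studies in which object photographs are shown at each participant's
individual recognition threshold (~50% of trials consciously recognized),
and the question is which brain regions' responses and multivoxel patterns
track subjective recognition.

The package implements, as a tested and reusable library, the full
computational chain such a study needs:

- **Stimulus generation** (`liminal.stimgen`) — grayscale normalization,
  Gaussian smoothing, Fourier **phase scrambling** (amplitude spectrum
  preserved), Gaussian edge-windowing, and the contrast parameterization
  `I(c) = b (I_scaled · c + 1)` around background `b = 127`, with
  `c = (I_max − I_min) / 2b` exactly recoverable from the pixels.
- **Adaptive staircasing** (`liminal.staircase`) — QUEST: a Bayesian
  posterior over the log contrast threshold of a Weibull observer, updated
  per trial and placed at the posterior mean; 20 per-image processes × 40
  trials interleaved into an 800-trial calibration session, plus the
  second-day 80-trial validation block with a pooled re-staircase branch.
- **Synthetic data** (`liminal.synth`) — trial tables (15 runs × 24 trials,
  20 real + 4 scrambled images), behavioral reports calibrated to the
  empirical rates (~50%/28% recognition for real/scrambled, ~79%/32%
  categorisation accuracy), ROI atlases on a 3-D grid, run-wise condition
  beta patterns with recognition-dependent amplitudes and
  recognized-trials-only cortical category patterns, and a BOLD forward
  model (TR 2 s).
- **GLM** (`liminal.glm`) — gamma HRF (lag 6 s, width 3 s ⇒ shape 4, scale
  1.5), up-to-16-condition designs with control and discrete-cosine drift
  regressors (150 s high-pass), voxelwise OLS, percent signal change, and
  sign-flip group contrasts.
- **Decoding** (`liminal.decoding`) — six pairwise linear SVMs (C = 1),
  one-vs-one voting with summed-decision-value tie-break,
  leave-one-run-out cross-validation, balanced accuracy, ROI voxel-count
  matching.
- **Inference** (`liminal.inference`) — within-run label permutation,
  subject→group resampled nulls (100 permutations/subject, 1000 group
  means), one-sided +1-corrected p-values, Benjamini–Hochberg FDR,
  paired accuracy-difference tests, a 3-voxel-radius searchlight, TFCE
  (E = 0.5, H = 2, 6-connectivity) and max-statistic FWE control.
- **Region statistics** (`liminal.roi_stats`) — arcsin(√p) transform,
  covariate scaling, and the REML linear mixed model
  `accuracy ~ location × voxel count` with per-subject random effects.
- **Workflow** (`liminal.workflow`) — one seeded, deterministic driver from
  generation to report tables, plus NIfTI/TSV I/O in `liminal.io`.

## Worked example

`examples/` contains one short script per capability.  For instance, group
inference on recognized-trial decoding (`examples/06_group_inference.py`)
prints:

```
visual     group accuracy 0.451  null mean 0.228  p = 0.0020
mpfc       group accuracy 0.497  null mean 0.253  p = 0.0020
thalamus   group accuracy 0.263  null mean 0.238  p = 0.2615
visual     FDR-significant: True
mpfc       FDR-significant: True
thalamus   FDR-significant: False
```

Category is decodable well above 4-way chance (0.25) from the activated
visual ROI *and* the deactivated medial-prefrontal ROI on recognized
trials, while the subcortical thalamus ROI stays inside its permutation
null — the core dissociation the pipeline is designed to detect.  The full
driver (`examples/09_full_pipeline.py`) adds unrecognized/scrambled
conditions, difference tests, the searchlight TFCE map, a percent-signal-
change summary, and the mixed-model report.

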