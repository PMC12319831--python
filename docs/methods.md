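# Methods

## Model and estimator

The package decomposes masked fMRI data `X ∈ R^{v×N}` as
`X = S M B + ε`: spatial maps `S` (voxels × d networks), a mixing matrix
`M` (d × k), and temporally independent mode time courses `B` (k × N).
Three estimation stages invert this model.

**Spatial stage (dual regression).** Given a template set (4D NIfTI, one
map per volume), stage 1 solves, per frame, the least-squares regression
of the template maps onto that volume, producing d network time series;
stage 2 regresses those time series onto each voxel's data, producing
subject-specific maps. Template columns are demeaned across voxels
before stage 1 (the usual dual-regression convention), except that a
numerically constant column is left untouched so it can act as an
intercept. The spatial un-mixing operator `A` is the Moore–Penrose
pseudoinverse of the subject-specific maps by default; a switch selects
the template maps instead, which is also what the noise-free recovery
tests use (see *Degenerate inputs*). Stage-1 time series are not
variance-normalized before temporal ICA beyond the ICA's own whitening.

**Temporal stage (temporal ICA).** FastICA with the logcosh (tanh)
negentropy contrast, run on the time dimension with PCA whitening to k
components. Five seeded restarts are run and the solution with the
largest negentropy proxy (summed squared deviation of E[log cosh] from
its Gaussian value) is kept; maximum 1000 iterations at tolerance 1e-6,
with non-convergence reported and the best iterate returned. Fitting is
per run (the fast sampling provides thousands of frames per run).
Normalization convention: rows of `B` are z-scored with the population
SD, all scale lives in `M`, and modes are ordered by descending column
norm of `M`. With this convention `Z = (B Bᵀ)⁻¹ ≈ I/N` for uncorrelated
modes and `f` magnitudes are comparable across runs. ICA is identifiable
only up to permutation and sign; `match_components` aligns a fit to a
reference by optimal assignment on |correlation|, and the task stage
fixes signs by the task correlation.

**Time-resolved stage.** `Mt(t) = A X(t) B(t)ᵀ Z` and `f(t) = N·Mt(t)`,
computed for all frames in one einsum. `Z` is k × k (it is the inverse
second moment of the k mode time courses; `M` is d × k, so a d × d `Z`
would not compose). When `X` is the denoised reconstruction `S M B` and
`A S = I`, the temporal mean of `f` equals `M` exactly; this identity is
enforced to 1e-8 in the tests and is the core correctness check of the
implementation. The denoised reconstruction is the default input because
residual structured noise in raw `X` inflates the variance of `Mt`; raw
`X` is available as a configuration option, and the per-entry *expected*
variance of `f` from raw data exceeds that from denoised data. On a
single run that ordering can be flipped in individual entries by the
O(1/√N) sampling covariance between the model and residual product
terms, so the acceptance check estimates the per-entry variances by
averaging over eight independently seeded runs. Demeaning (per run, per
network × mode entry) happens before sign alignment; the removed mean is
kept as the static mixing so the original `f` is always recoverable.

**Reading f.** Each frame of `f` is a rank-one instantaneous estimate
whose fluctuations are dominated by products of mode time courses
(heavy-tailed, variance of order the squared mixing weights). Slow
allocation changes are therefore read out after temporal averaging:
trial averaging for task epochs, or a moving average for continuous
modulations — the recovery analyses use a window of a quarter of the
target modulation's period, which attenuates the target by < 10 % while
suppressing the per-frame noise by the square root of the window length.

## Task and trial statistics

The task regressor is the stimulus impulse train (onsets mapped to
frames by floor(onset/TR), 0-based) convolved with a unit-peak
double-gamma HRF (response peak 6 s, undershoot 16 s, ratio 1/6, 32 s
support), z-scored. The mode with the largest |correlation| with this
regressor is the task-relevant mode; if that correlation is negative the
mode's weight series is flipped so directions are comparable across
runs. A warning (not an error) is raised when no correlation exceeds
0.05.

Trials are 60-frame epochs (60 × 0.206 s = 12.36 s) starting at the
stimulus-onset frame, or — for response locking — 10 frames before the
response frame; windows leaving the run are dropped and logged. Per
time point: rank ordering of network weights (ties break to the lower
index), one-sample t of weights against zero (df = trials − 1), and
Welch two-sample t oriented fail − hit with delayed/unscored trials
excluded (both groups constant and equal makes the difference exactly
zero, reported as t = 0). Run-level t maps are converted to signed z by
two-sided tail matching and combined across units with Stouffer's
Σz/√count, skipping undefined cells; the combination method is
deliberately simple and swappable, since no particular group rule is
canonical here. Runs are combined within participant first, then across
participants.

## HRF basis set and GLM

HRFs are parametrized as four half-cosine segments — flat onset delay,
rise 0→1, fall 1→−u, recovery −u→0 — with segment durations sampled
uniformly from onset 0–2.5 s, rise 2.5–6 s, fall 2.5–8 s, recovery
2.5–6 s, and undershoot depth u uniform on [0, 0.5] (a typical-HRF
range; the duration ranges say nothing about amplitude). 1000 sampled
curves on a common zero-padded grid (dt = run TR) are reduced by SVD to
6 orthonormal basis functions. The SVD is taken *without* mean-centering:
the first component then tracks the mean response shape (correlation
≈ 0.998 with the mean sampled HRF), while centering first would make
the leading component a variation-around-the-mean shape nearly
orthogonal to it. Component signs are fixed so each component's
largest-magnitude sample is positive. This is a re-implementation in
spirit, not a bit-level reproduction of FSL's FLOBS tool.

Design matrices convolve the stimulus impulse train with each basis
function (columns BF1..BF6). The task-success family adds hit and fail
epoch-spanning boxcar main effects plus per-outcome convolved columns
(BFi × Hit, BFi × Fail); note that without any third outcome (e.g.
delayed trials) the all-trials and per-outcome groups are collinear, and
a near-singular design triggers a warning. Fits use generalized least
squares with AR(p) errors (default p = 5): iterate OLS/GLS fit →
Yule–Walker AR estimation on residuals → whitening → refit, to 1e-8
relative coefficient change or 20 iterations (statsmodels GLSAR
machinery). Two-sided p-values on the t distribution of the whitened
fit; BH-FDR within one fitted model (configurable family); post-hoc
contrasts `cᵀβ` use the whitened coefficient covariance. Temporal
profiles are reconstructed as Σ βᵢ·basisᵢ (plus the group offset for
hit/fail families).

## Synthetic data

The generator materializes the forward model with known truth:

- **Maps**: d Gaussian profiles on contiguous blocks of the C-order
  voxel raster (slabs of the 3D grid); adjacent blocks share exactly
  round(overlap_fraction × width) voxels, making spatial overlap — the
  condition that motivates mode-level analysis — an exact, first-class
  parameter.
- **Modes**: iid Laplace series (super-Gaussian, so temporal ICA is
  identifiable), or task-locked (HRF-convolved events plus Laplace
  noise), z-scored.
- **Static mixing**: standard-normal entries, redrawn until the
  condition number is ≤ 5 so the planted modes load networks in
  distinguishable patterns — near-collinear mixing would make the
  decomposition ill-posed for any estimator.
- **Time-varying mixing**: per-entry sinusoid, boxcar, or event-locked
  waveforms added to the static value; waveforms are demeaned over
  frames so the temporal mean of the true time-varying mixing equals the
  declared static mixing to 1e-12.
- **Events**: truncated-normal ISIs (mean 19.46 s, SD 3.28 s, support
  16.19–41.59 s, emulating a slow event-related design), stimulus
  duration 0.2 s, uniform 0.3–1.2 s response times, Bernoulli(hit_rate)
  outcomes with an optional delayed fraction.
- **Noise**: isotropic Gaussian, `noise_sd` per voxel per frame.

Everything is a deterministic function of the seed. Defaults (12×12×8
grid, d = 4, k = 3, 3000 frames, TR 0.206 s, noise SD 0.5) are sized so
a full end-to-end analysis runs in seconds. What the generator does
*not* emulate: physiological (cardiac/respiratory) noise, head motion,
spatial autocorrelation of noise, scanner drifts, and non-stationary
spatial maps. Passing tests therefore demonstrate the estimator's
correctness under the model's own assumptions plus white noise, not
robustness to real-scanner artefacts.

## Numerical choices and degenerate inputs

- Voxel-wise variance normalization uses the sample SD (ddof = 1);
  constant voxels are zeroed (not dropped) and logged, keeping matrix
  rows aligned with the mask. Mode time courses and task regressors are
  z-scored with the population SD so that `Z = 1/N` holds exactly in
  the scalar case and the mean of a product of z-scored series is
  exactly Pearson r.
- Rank checks use a relative singular-value tolerance of 1e-10·σmax;
  `B Bᵀ` is declared singular at the same relative threshold.
- Noise-free synthetic data with k < d yield network time series of
  exact rank k, so stage-2 subject maps are rank deficient *by
  construction*; noiseless analyses must use the template pseudoinverse
  (the subject-map route raises a rank error, which is correct
  behaviour).
- Synthetic recovery analyses run on the generated data's native scale:
  voxel-wise variance normalization rescales voxels non-uniformly,
  which linearly distorts the effective mixing the pipeline estimates
  and would invalidate a direct column-wise comparison with the planted
  truth even at perfect mode recovery. Normalization remains the
  default for scanner data.
- Epoch start frames use floor(); exact rank ties go to the lower
  network index; double demeaning and repeated sign flips are guarded.
- TR precedence: an explicit configuration value overrides the NIfTI
  header.

## Problem sizes in the tests

Unit and acceptance tests run at desk scale: grids of 6×6×4 to 12×12×8
voxels, 3000–6000 frames, 4 networks / 3 modes, 8 replicate runs for
variance-ordering estimates, 200 Monte-Carlo replicates for the AR(1)
calibration and 1000 for the t-test type-I rate. These sizes were chosen
as the smallest at which the measured quantities are stable across
seeds; the estimators themselves are vectorized and run comfortably at
real-data scale (10⁵ voxels, 10³–10⁴ frames).

## Known limitations

- Cross-run/cross-subject mode correspondence relies on task-sign
  alignment only; no group-level temporal ICA or dual-regression-like
  mode matching is implemented.
- No automatic model-order selection for the temporal ICA, and no
  AR-lag selection for the GLM (p = 5 fixed by default).
- Group inference on z maps is descriptive (no permutation or cluster
  correction); participant is not modelled as a random effect.
- Per-frame values of `f` are individually noisy rank-one estimates;
  all interpretable read-outs are averages (trials, windows, GLM fits).
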