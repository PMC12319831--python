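# trifle

Time-resolved temporal functional mode analysis for fast fMRI.

Functional brain networks overlap in space, and several temporal
processes can recruit the same anatomy at once. Classical temporal
functional mode (TFM) analysis separates such processes by running
temporal ICA on network time series, but it returns a *fixed* picture:
one mixing matrix describing how much each mode loads each network over
a whole run. `trifle` unfolds that picture in time. It computes a
closed-form, per-frame estimate of the mixing matrix, so that the
allocation of spatially overlapping networks by each temporally
independent mode can be followed frame by frame — at fast sampling rates
(TR ≈ 0.2 s), trial by trial.

It is written for neuroimaging researchers working with task or resting
fMRI who want instantaneous network-allocation estimates, together with
the trial-level statistics needed to validate them, and a synthetic-data
generator that makes every estimation stage testable against known
ground truth without any data download.

## The model

With `X ∈ R^{v×N}` the masked, variance-normalized BOLD data, the
classical three-matrix decomposition is

```
X = S M B + ε
```

where `S` (voxels × d) holds spatial network maps, `B` (k × N) holds
temporally independent, non-Gaussian mode time courses, and
`M` (d × k) is the mixing matrix mapping modes onto networks. Writing
`A = pinv(S)` and `Z = (B Bᵀ)⁻¹`, the mixing matrix is a sum over
frames of rank-one terms, which defines its time-resolved counterpart
and its N-scaled form:

```
Mt(t) = A X(t) B(t)ᵀ Z          f(t) = N · Mt(t)
M     = Σ_t Mt(t)               M    = mean_t f(t)
```

For z-scored series the product underlying `Mt` is the instantaneous
correlation between the network expression `A X` and the mode time
course, so `f(t)` measures how the allocation of each network by each
mode fluctuates around its fixed value `M`. Because residual structured
noise in `X` inflates the variance of `Mt`, `f` is computed from the
denoised reconstruction `S M B` by default (raw `X` is an option).

The pipeline: (1) dual regression against spatial network templates
gives network time series and subject-specific maps; (2) temporal ICA
(FastICA, logcosh contrast) on those time series gives `M` and `B`;
(3) the closed form above gives `f`, demeaned and sign-aligned to the
task. Validation statistics epoch `f` into trials (60 frames of 0.206 s
= 12.36 s), rank networks per time point, test weights per (network,
time point) with group-level Z combination, and parametrize allocation
time courses with a GLM on an HRF basis set (half-cosine samples →
PCA), fit by generalized least squares with AR(5) errors and
Benjamini–Hochberg FDR.

## Worked example

`examples/simulate_and_recover.py` generates a synthetic run
(1152 voxels × 3000 frames, 4 overlapping networks, 3 Laplace modes,
noise SD 0.5) in which the weight of mode 0 on network 0 carries a slow
sinusoidal modulation, then runs the full estimation chain:

```
$ python examples/simulate_and_recover.py
synthetic run: 1152 voxels x 3000 frames, TR 0.206s, 4 networks, 3 modes
static mixing column 0: |corr(est, truth)| = 0.992
static mixing column 1: |corr(est, truth)| = 1.000
static mixing column 2: |corr(est, truth)| = 1.000
planted modulation of weight (network 0, mode 0): corr = 0.929 (smoothed over 243 frames)
```

The column correlations say the static mixing matrix is recovered
almost exactly after permutation/sign matching; the last line says the
time-resolved estimate `f` tracks the planted time-varying allocation
(correlation 0.93 after smoothing with a quarter of the modulation
period). The other examples demonstrate the temporal-average identity,
the HRF basis set, and the trial statistics / AR(5) GLM layer.

## Command line

Every stage is also reachable through a thin CLI driven by YAML
configs:

```
trifle simulate spec.yaml --outdir data/     # synthetic dataset (NIfTI + TSV)
trifle run config.yaml                       # full pipeline -> TSV/NPZ/JSON
trifle flobs --dt 0.206 --out basis.tsv      # HRF basis set
trifle validate-task RUNDIR --events events.tsv
```

`trifle run` wants `bold`, `mask`, `templates` (4D NIfTI, one map per
volume), `events` (BIDS-style TSV), and writes network time series, the
mixing matrix, mode time courses, `f` per mode, per-timepoint t/z maps
and GLM tables into the output directory.

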