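"""Synthetic fMRI runs with known spatially overlapping sources.

The generator embodies the forward model the estimation stages invert:
fixed spatial maps S (smooth, possibly overlapping profiles), temporally
independent super-Gaussian mode time courses B, a time-varying mixing
matrix M(t) whose temporal mean is a declared static mixing M, and
isotropic Gaussian noise:

    X(:, t) = S @ (M(t) @ B(:, t)) + noise

Spatial overlap between adjacent maps is a first-class parameter, since
overlapping sources are exactly the condition under which per-network
time series mix the underlying modes.  Laplace-distributed modes keep
temporal ICA identifiable.  Everything is determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .hrf import canonical_hrf
from .io import BoldRun, EventTable, TemplateSet

#: ISI distribution of the emulated visuomotor task: truncated normal,
#: mean 19.46 s, SD 3.28 s, support 16.19-41.59 s.
DEFAULT_ISI = dict(isi_mean=19.46, isi_sd=3.28, isi_bounds=(16.19, 41.59))


@dataclass
class Modulation:
    """A planted time-varying component of one mixing weight."""

    network: int
    mode: int
    waveform: str = "sinusoid"     # "sinusoid" | "boxcar" | "event"
    amplitude: float = 1.0
    frequency: float = 0.01        # Hz, for sinusoids
    # boxcar/event modulations lock onto the generated trials


@dataclass
class SyntheticSpec:
    grid: tuple = (12, 12, 8)
    d: int = 4
    k: int = 3
    n_frames: int = 3000
    tr: float = 0.206
    overlap_fraction: float = 0.2
    mode_distribution: str = "laplace"   # "laplace" | "task_locked"
    modulation: tuple = ()
    noise_sd: float = 0.5
    n_trials: int = 10
    hit_rate: float = 0.8
    delayed_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        v = int(np.prod(self.grid))
        if self.d > v:
            raise ValueError("more networks than voxels")
        if self.k > self.d:
            raise ValueError("more modes than networks")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticTruth:
    maps_true: np.ndarray            # voxels x d
    modes_true: np.ndarray           # k x frames
    mixing_static: np.ndarray        # d x k, temporal mean of the next field
    mixing_true_time: np.ndarray     # d x k x frames
    events: EventTable
    spec: SyntheticSpec = None


def _overlapping_maps(v: int, d: int, overlap_fraction: float,
                      rng: np.random.Generator) -> np.ndarray:
    """d smooth source profiles over v voxels with controlled overlap.

    Each map occupies a contiguous block of the C-order raster (a slab of
    the 3D grid) carrying a Gaussian profile; adjacent blocks share
    exactly round(overlap_fraction * width) voxels.
    """
    width = int(np.floor(v / (d - (d - 1) * overlap_fraction)))
    if width < 4:
        raise ValueError("infeasible overlap for grid size")
    step = width - int(round(overlap_fraction * width))
    maps = np.zeros((v, d))
    for j in range(d):
        start = j * step
        idx = np.arange(start, start + width)
        center = start + (width - 1) / 2.0
        maps[idx, j] = np.exp(-0.5 * ((idx - center) / (width / 4.0)) ** 2)
    return maps


def generate_events(n_trials: int, isi_mean: float = 19.46, isi_sd: float = 3.28,
                    hit_rate: float = 0.8, seed: int = 0,
                    run_length: float | None = None,
                    isi_bounds: tuple = (16.19, 41.59),
                    stimulus_duration: float = 0.2,
                    delayed_rate: float = 0.0) -> EventTable:
    """Trial onsets with truncated-normal ISIs and Bernoulli(hit_rate) outcomes.

    A fraction ``delayed_rate`` of trials is marked "delayed" (no scored
    hit/fail); the remainder split hit/fail by ``hit_rate``.  Raises if
    the trials do not fit into ``run_length`` seconds.
    """
    rng = np.random.default_rng(seed)
    if n_trials == 0:
        empty = np.empty(0)
        return EventTable(empty, empty, empty, np.empty(0, dtype=object))
    lo, hi = isi_bounds
    a, b = (lo - isi_mean) / isi_sd, (hi - isi_mean) / isi_sd
    isis = truncnorm.rvs(a, b, loc=isi_mean, scale=isi_sd, size=n_trials,
                         random_state=rng)
    onsets = np.cumsum(isis)
    if run_length is not None and onsets[-1] + stimulus_duration > run_length:
        raise ValueError("run too short for the requested trials")
    rts = rng.uniform(0.3, 1.2, size=n_trials)
    outcomes = np.where(rng.random(n_trials) < hit_rate, "hit", "fail").astype(object)
    delayed = rng.random(n_trials) < delayed_rate
    outcomes[delayed] = "delayed"
    rts[delayed] = np.nan
    durations = np.full(n_trials, stimulus_duration)
    return EventTable(onsets, durations, rts, outcomes)


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=1, keepdims=True)
    return x / x.std(axis=1, keepdims=True)


def _make_modes(spec: SyntheticSpec, events: EventTable,
                rng: np.random.Generator) -> np.ndarray:
    if spec.mode_distribution == "laplace":
        B = rng.laplace(size=(spec.k, spec.n_frames))
    elif spec.mode_distribution == "task_locked":
        hrf = canonical_hrf(spec.tr)
        stick = np.zeros(spec.n_frames)
        frames = np.floor(events.onsets / spec.tr).astype(int)
        stick[frames[frames < spec.n_frames]] = 1.0
        response = np.convolve(stick, hrf)[:spec.n_frames]
        B = 0.5 * rng.laplace(size=(spec.k, spec.n_frames))
        B[0] += response / max(response.std(), 1e-12)
    else:
        raise ValueError(f"unknown mode_distribution '{spec.mode_distribution}'")
    return _zscore_rows(B)


def _event_locked_wave(events: EventTable, tr: float, n_frames: int) -> np.ndarray:
    hrf = canonical_hrf(tr)
    stick = np.zeros(n_frames)
    frames = np.floor(events.onsets / tr).astype(int)
    stick[frames[frames < n_frames]] = 1.0
    wave = np.convolve(stick, hrf)[:n_frames]
    return wave / max(np.abs(wave).max(), 1e-12)


def _mixing_time(spec: SyntheticSpec, static: np.ndarray, events: EventTable,
                 t_seconds: np.ndarray) -> np.ndarray:
    Mt = np.repeat(static[:, :, None], spec.n_frames, axis=2)
    for mod in spec.modulation:
        if mod.waveform == "sinusoid":
            wave = mod.amplitude * np.sin(2 * np.pi * mod.frequency * t_seconds)
        elif mod.waveform == "boxcar":
            wave = np.zeros(spec.n_frames)
            for onset in events.onsets:
                start = int(np.floor(onset / spec.tr))
                wave[start:start + 60] = mod.amplitude
        elif mod.waveform == "event":
            wave = mod.amplitude * _event_locked_wave(events, spec.tr,
                                                      spec.n_frames)
        else:
            raise ValueError(f"unknown waveform '{mod.waveform}'")
        wave = wave - wave.mean()   # keep the declared static mixing exact
        Mt[mod.network, mod.mode, :] += wave
    return Mt


def generate_run(spec: SyntheticSpec):
    """Generate one synthetic run: returns ``(BoldRun, SyntheticTruth)``."""
    rng = np.random.default_rng(spec.seed)
    v = int(np.prod(spec.grid))
    maps = _overlapping_maps(v, spec.d, spec.overlap_fraction, rng)

    run_length = spec.n_frames * spec.tr
    events = generate_events(spec.n_trials, hit_rate=spec.hit_rate,
                             seed=spec.seed + 1, run_length=run_length,
                             delayed_rate=spec.delayed_rate, **{
                                 k: DEFAULT_ISI[k] for k in
                                 ("isi_mean", "isi_sd", "isi_bounds")})

    B = _make_modes(spec, events, rng)

    # Static mixing stays well conditioned (cond <= 5) so the planted
    # modes load the networks in distinguishable patterns; near-collinear
    # mixing would make the decomposition ill-posed by construction.
    for _ in range(100):
        static = rng.normal(size=(spec.d, spec.k))
        if np.linalg.cond(static) <= 5:
            break
    t_seconds = np.arange(spec.n_frames) * spec.tr
    Mt = _mixing_time(spec, static, events, t_seconds)

    signal = maps @ np.einsum("dkt,kt->dt", Mt, B)
    data = signal + spec.noise_sd * rng.standard_normal(signal.shape)

    grid = tuple(spec.grid)
    voxel_index = np.argwhere(np.ones(grid, dtype=bool))
    run = BoldRun(data=data, tr=spec.tr, mask_shape=grid,
                  voxel_index=voxel_index, run_id=f"synthetic-seed{spec.seed}")
    truth = SyntheticTruth(maps_true=maps, modes_true=B, mixing_static=static,
                           mixing_true_time=Mt, events=events, spec=spec)
    return run, truth


def templates_from_truth(truth: SyntheticTruth) -> TemplateSet:
    """Wrap the true maps as a template set for dual regression."""
    d = truth.maps_true.shape[1]
    return TemplateSet(maps=truth.maps_true,
                       labels=[f"net{i:02d}" for i in range(d)],
                       source_tag="synthetic-truth")


def write_dataset(spec: SyntheticSpec, outdir) -> dict:
    """Materialize a synthetic run on disk (NIfTI + events TSV + truth npz)."""
    from pathlib import Path

    from .io import save_bold, save_events, save_templates

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run, truth = generate_run(spec)
    paths = {
        "bold": outdir / "bold.nii.gz",
        "mask": outdir / "mask.nii.gz",
        "templates": outdir / "templates.nii.gz",
        "events": outdir / "events.tsv",
        "truth": outdir / "truth.npz",
    }
    save_bold(run, paths["bold"], mask_path=paths["mask"])
    save_templates(templates_from_truth(truth), run.mask_shape,
                   run.voxel_index, paths["templates"])
    save_events(truth.events, paths["events"])
    np.savez_compressed(paths["truth"], maps_true=truth.maps_true,
                        modes_true=truth.modes_true,
                        mixing_static=truth.mixing_static,
                        mixing_true_time=truth.mixing_true_time)
    return {k: str(p) for k, p in paths.items()}
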