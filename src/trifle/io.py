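"""Input/output for BOLD runs, spatial network templates, and task events.

BOLD data live on disk as 4D NIfTI volumes; in memory they are 2D
``voxels x frames`` matrices obtained by masking, with a deterministic
C-order raster mapping from matrix row to 3D voxel coordinate so that
results can always be projected back into the volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("trifle")

#: Outcomes an event row may carry.  "n/a" marks trials without a scored
#: response (e.g. practice or missing behavioural data).
ALLOWED_OUTCOMES = ("hit", "fail", "delayed", "n/a")


@dataclass
class BoldRun:
    """A masked fMRI run: ``data[i, t]`` is voxel *i* at frame *t*.

    ``voxel_index[i]`` gives the 3D coordinate of row *i*; rows follow the
    C-order raster scan of the mask's True voxels.
    """

    data: np.ndarray
    tr: float
    mask_shape: tuple
    voxel_index: np.ndarray
    run_id: str = "run"
    variance_normalized: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("BoldRun.data must be 2D (voxels x frames)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BoldRun.data contains non-finite values")
        if self.tr <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Run length in seconds."""
        return self.n_frames * self.tr

    def unmask(self) -> np.ndarray:
        """Scatter the 2D matrix back into a 4D ``mask_shape + (frames,)`` array."""
        vol = np.zeros(tuple(self.mask_shape) + (self.n_frames,))
        idx = tuple(self.voxel_index.T)
        vol[idx] = self.data
        return vol


@dataclass
class TemplateSet:
    """Spatial network templates: ``maps`` is voxels x d, one column per network."""

    maps: np.ndarray
    labels: list
    source_tag: str = "custom"

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        d = self.maps.shape[1]
        if d < 2:
            raise ValueError("a TemplateSet needs at least 2 networks")
        if len(self.labels) != d:
            raise ValueError("labels must match the number of template maps")
        norms = np.linalg.norm(self.maps, axis=0)
        if np.any(norms == 0):
            raise ValueError("template maps must not be all-zero")
        sv = np.linalg.svd(self.maps, compute_uv=False)
        if sv[-1] <= 1e-10 * sv[0]:
            raise ValueError("template maps are numerically rank deficient")

    @property
    def d(self) -> int:
        return self.maps.shape[1]


@dataclass
class EventTable:
    """Task events: onsets/durations in seconds from run start.

    ``response_time`` is seconds from stimulus onset (NaN when missing);
    ``outcome`` is one of :data:`ALLOWED_OUTCOMES`.
    """

    onsets: np.ndarray
    durations: np.ndarray
    response_times: np.ndarray
    outcomes: np.ndarray

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.response_times = np.asarray(self.response_times, dtype=float)
        self.outcomes = np.asarray(self.outcomes, dtype=object)
        n = len(self.onsets)
        if not (len(self.durations) == len(self.response_times) == len(self.outcomes) == n):
            raise ValueError("event columns have inconsistent lengths")
        if n > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("event onsets must be strictly increasing")
        bad = set(self.outcomes) - set(ALLOWED_OUTCOMES)
        if bad:
            raise ValueError(f"unknown outcome values: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.onsets)

    def subset(self, mask) -> "EventTable":
        mask = np.asarray(mask)
        return EventTable(self.onsets[mask], self.durations[mask],
                          self.response_times[mask], self.outcomes[mask])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "onset": self.onsets,
            "duration": self.durations,
            "response_time": self.response_times,
            "outcome": self.outcomes,
        })


def load_bold(nifti_path, mask_path, tr: float | None = None, run_id: str | None = None) -> BoldRun:
    """Load a 4D NIfTI and a 3D mask into a masked :class:`BoldRun`.

    ``tr`` overrides the header's 4th zoom when given; without either a
    positive header TR or an explicit value this raises.
    """
    img = nib.load(str(nifti_path))
    mask_img = nib.load(str(mask_path))
    if img.ndim != 4:
        raise ValueError(f"expected a 4D image, got {img.ndim}D")
    mask = np.asarray(mask_img.dataobj) != 0
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    if mask.shape != img.shape[:3]:
        raise ValueError(
            f"image spatial dims {img.shape[:3]} do not match mask {mask.shape}")
    if not mask.any():
        raise ValueError("empty mask")
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr <= 0:
            raise ValueError("TR missing from header; pass tr explicitly")
    data = np.asarray(img.dataobj)[mask]  # C-order raster of True voxels
    voxel_index = np.argwhere(mask)
    if run_id is None:
        run_id = Path(str(nifti_path)).name.split(".")[0]
    return BoldRun(data=data, tr=float(tr), mask_shape=mask.shape,
                   voxel_index=voxel_index, run_id=run_id)


def save_bold(run: BoldRun, nifti_path, mask_path=None) -> None:
    """Write a BoldRun back to a 4D NIfTI (and optionally its mask)."""
    vol = run.unmask().astype(np.float32)
    affine = np.eye(4)
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((1.0, 1.0, 1.0, run.tr))
    nib.save(img, str(nifti_path))
    if mask_path is not None:
        mask = np.zeros(run.mask_shape, dtype=np.uint8)
        mask[tuple(run.voxel_index.T)] = 1
        nib.save(nib.Nifti1Image(mask, affine), str(mask_path))


def load_templates(nifti_path, mask_path, labels=None, source_tag="custom") -> TemplateSet:
    """Load a 4D template image (one map per volume) masked to 2D voxels x d."""
    img = nib.load(str(nifti_path))
    mask = np.asarray(nib.load(str(mask_path)).dataobj) != 0
    if img.ndim != 4:
        raise ValueError("templates must be a 4D image, one map per volume")
    if mask.shape != img.shape[:3]:
        raise ValueError("template spatial dims do not match mask")
    maps = np.asarray(img.dataobj)[mask]
    d = maps.shape[1]
    if labels is None:
        labels = [f"net{i:02d}" for i in range(d)]
    return TemplateSet(maps=maps, labels=list(labels), source_tag=source_tag)


def save_templates(templates: TemplateSet, mask_shape, voxel_index, nifti_path) -> None:
    vol = np.zeros(tuple(mask_shape) + (templates.d,), dtype=np.float32)
    vol[tuple(np.asarray(voxel_index).T)] = templates.maps
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(nifti_path))


def variance_normalize(run: BoldRun) -> BoldRun:
    """Z-score every voxel time course (mean 0, unit sample SD).

    Constant voxels cannot be scaled; they are set to all-zero (keeping the
    matrix aligned with the mask) and counted in the log.
    """
    if run.n_frames < 3:
        raise ValueError("variance normalization needs at least 3 frames")
    data = run.data - run.data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, ddof=1)
    constant = sd <= 1e-12 * np.maximum(1.0, np.abs(run.data).max())
    sd_safe = np.where(constant, 1.0, sd)
    data = data / sd_safe[:, None]
    data[constant] = 0.0
    if constant.any():
        logger.warning("%s: %d constant voxel(s) set to zero during variance "
                       "normalization", run.run_id, int(constant.sum()))
    return replace(run, data=data, variance_normalized=True)


def load_events(tsv_path) -> EventTable:
    """Read a BIDS-style events TSV (onset, duration[, response_time, outcome])."""
    df = pd.read_csv(tsv_path, sep="\t")
    for col in ("onset", "duration"):
        if col not in df.columns:
            raise ValueError(f"events TSV is missing required column '{col}'")
    onsets = pd.to_numeric(df["onset"], errors="coerce")
    if onsets.isna().any():
        raise ValueError("non-numeric onset value in events TSV")
    durations = pd.to_numeric(df["duration"], errors="coerce").fillna(0.0)
    if "response_time" in df.columns:
        rts = pd.to_numeric(df["response_time"], errors="coerce")
    else:
        rts = pd.Series(np.nan, index=df.index)
    if "outcome" in df.columns:
        outcomes = df["outcome"].astype(object).where(df["outcome"].notna(), "n/a")
    else:
        outcomes = pd.Series("n/a", index=df.index, dtype=object)
    return EventTable(onsets.to_numpy(float), durations.to_numpy(float),
                      rts.to_numpy(float), outcomes.to_numpy(object))


def save_events(events: EventTable, tsv_path) -> None:
    events.to_dataframe().to_csv(tsv_path, sep="\t", index=False, na_rep="n/a")


def write_matrix_tsv(matrix, path, columns, index_name="frame") -> None:
    """Write a 2D array as a labeled TSV (rows indexed 0..n-1)."""
    df = pd.DataFrame(np.asarray(matrix), columns=list(columns))
    df.index.name = index_name
    df.to_csv(path, sep="\t")


def setup_logging(log_path=None, level=logging.INFO) -> logging.Logger:
    """Route package logs to stderr and, optionally, a file."""
    log = logging.getLogger("trifle")
    log.setLevel(level)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(h)
    if log_path is not None:
        fh = logging.FileHandler(log_path)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
        log.addHandler(fh)
    return log
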