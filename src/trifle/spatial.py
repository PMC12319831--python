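"""Dual regression against spatial network templates.

Stage 1 regresses the template maps onto each fMRI volume, yielding one
time series per network; stage 2 regresses those time series onto each
voxel's data, yielding subject-specific spatial maps.  The Moore-Penrose
pseudoinverse of the subject maps is the spatial un-mixing operator used
by the time-resolved stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import BoldRun, TemplateSet

logger = logging.getLogger("trifle")

_RANK_RTOL = 1e-10  # singular values below rtol * sigma_max count as zero


@dataclass
class SpatialDecomposition:
    """Outputs of the spatial stage: X ~ S T with A = pinv(S)."""

    maps_subject: np.ndarray     # voxels x d
    timeseries: np.ndarray       # d x frames
    pinv_maps: np.ndarray        # d x voxels
    template_tag: str
    condition_number: float
    labels: list


def _check_rank(matrix, what: str) -> np.ndarray:
    sv = np.linalg.svd(matrix, compute_uv=False)
    if sv[-1] <= _RANK_RTOL * sv[0]:
        raise np.linalg.LinAlgError(f"{what} is numerically rank deficient")
    return sv


def stage1_timeseries(run: BoldRun, templates: TemplateSet,
                      demean_maps: bool = True) -> np.ndarray:
    """Spatial regression: per frame, least-squares fit of template maps.

    Returns the d x frames network time-series matrix.  Template columns
    are demeaned across voxels before fitting (conventional in dual
    regression); a numerically constant column is left untouched so it
    acts as an intercept rather than collapsing to zero.
    """
    if run.n_voxels != templates.maps.shape[0]:
        raise ValueError("voxel count of run and templates differ")
    G = np.array(templates.maps, dtype=float)
    if demean_maps:
        mu = G.mean(axis=0)
        spread = G.max(axis=0) - G.min(axis=0)
        varying = spread > 1e-12 * np.maximum(1.0, np.abs(G).max())
        G[:, varying] -= mu[varying]
    _check_rank(G, "template set")
    ts, *_ = np.linalg.lstsq(G, run.data, rcond=None)
    return ts


def stage2_maps(run: BoldRun, timeseries: np.ndarray,
                demean_timeseries: bool = True,
                cond_warn: float = 1e6) -> np.ndarray:
    """Temporal regression: per voxel, least-squares fit of the stage-1 series.

    Returns the voxels x d subject-specific spatial maps.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.shape[1] != run.n_frames:
        raise ValueError("frame counts of run and time series differ")
    if demean_timeseries:
        ts = ts - ts.mean(axis=1, keepdims=True)
    cond = np.linalg.cond(ts)
    if cond > cond_warn:
        logger.warning("stage-2 regressors are nearly collinear "
                       "(condition number %.3g)", cond)
    coefs, *_ = np.linalg.lstsq(ts.T, run.data.T, rcond=None)
    return coefs.T


def spatial_pinv(maps_subject: np.ndarray) -> np.ndarray:
    """Moore-Penrose left inverse A of the spatial maps: A @ S = I_d."""
    S = np.asarray(maps_subject, dtype=float)
    _check_rank(S, "subject spatial maps")
    return np.linalg.pinv(S)


def dual_regression(run: BoldRun, templates: TemplateSet,
                    demean_maps: bool = True,
                    pinv_of: str = "subject") -> SpatialDecomposition:
    """Run both dual-regression stages and compute the spatial pseudoinverse.

    ``pinv_of`` selects which map set the downstream un-mixing operator is
    built from: the subject-specific stage-2 maps (default) or the
    original templates.
    """
    ts = stage1_timeseries(run, templates, demean_maps=demean_maps)
    maps = stage2_maps(run, ts)
    basis = maps if pinv_of == "subject" else templates.maps
    pinv = spatial_pinv(basis)
    cond = float(np.linalg.cond(basis))
    return SpatialDecomposition(maps_subject=maps, timeseries=ts,
                                pinv_maps=pinv, template_tag=templates.source_tag,
                                condition_number=cond, labels=list(templates.labels))
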