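"""Time-resolved mixing: instantaneous estimates of network allocation.

Classical temporal-functional-mode analysis factorizes fMRI data as
X = S M B, with fixed spatial maps S, a fixed networks x modes mixing
matrix M, and temporally independent mode time courses B.  The mixing
matrix admits a closed-form, per-frame estimate

    Mt(t) = A X(t) B(t)^T Z,      Z = (B B^T)^(-1),  A = pinv(S)

whose sum over frames recovers M.  The scaled form f(t) = N * Mt(t) makes
M the temporal *average* of f, so f describes how the allocation of each
network by each mode fluctuates around its fixed value.  For z-scored
series the elementwise product underlying Mt is the instantaneous
correlation between the network expression A X and the mode time course.

Because residual structured noise in X inflates the variance of Mt, the
default input is the denoised reconstruction S M B rather than raw X.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io import EventTable
from .spatial import SpatialDecomposition
from .tfm import TfmDecomposition

logger = logging.getLogger("trifle")


@dataclass
class TimeResolvedMixing:
    """Instantaneous allocation weights f (networks x modes x frames).

    When ``demeaned`` is False and the input was the denoised
    reconstruction, the temporal mean of ``f`` equals the static mixing
    matrix M; after demeaning, that mean is kept in ``static_mixing``.
    """

    f: np.ndarray
    scaling: np.ndarray          # Z = (B B^T)^(-1), k x k
    n_frames: int
    static_mixing: np.ndarray    # temporal mean of f at construction time
    demeaned: bool = False
    sign_flips: np.ndarray | None = None
    source: str = "denoised"

    def __post_init__(self):
        if self.sign_flips is None:
            self.sign_flips = np.ones(self.f.shape[1])

    @property
    def d(self) -> int:
        return self.f.shape[0]

    @property
    def k(self) -> int:
        return self.f.shape[1]

    def mode_weights(self, mode_index: int) -> np.ndarray:
        """Networks x frames weight series for one mode."""
        return self.f[:, mode_index, :]


def mode_covariance_scaling(modes: np.ndarray) -> np.ndarray:
    """Z = (B B^T)^(-1), the inverse second-moment matrix of the modes.

    For zero-mean, unit-power, mutually uncorrelated rows this approaches
    I/N.  Raises on a (numerically) singular B B^T, e.g. duplicated modes.
    """
    B = np.asarray(modes, dtype=float)
    C = B @ B.T
    sv = np.linalg.svd(C, compute_uv=False)
    if sv[-1] <= 1e-10 * sv[0]:
        raise np.linalg.LinAlgError("B B^T is singular; modes are not full row rank")
    Z = np.linalg.inv(C)
    return 0.5 * (Z + Z.T)  # symmetrize against round-off


def denoised_reconstruction(spatial: SpatialDecomposition,
                            tfm: TfmDecomposition) -> np.ndarray:
    """Model-implied data S M B (voxels x frames), free of residual noise."""
    S = spatial.maps_subject
    if S.shape[1] != tfm.mixing.shape[0]:
        raise ValueError("spatial and temporal decompositions disagree on d")
    return S @ (tfm.mixing @ tfm.modes)


def time_resolved_mixing(pinv_maps: np.ndarray, data: np.ndarray,
                         modes: np.ndarray, scaling: np.ndarray | None = None,
                         source: str = "denoised") -> TimeResolvedMixing:
    """Compute f(t) = N * A X(t) B(t)^T Z for every frame.

    ``data`` is voxels x frames — by default the denoised reconstruction
    S M B (pass raw X with ``source='raw'`` to keep residual noise in the
    estimate).  Each frame yields the rank-one d x k matrix
    outer(A X(:,t), B(:,t)) scaled by Z; stacked over frames this is the
    d x k x N array f whose temporal mean is the static mixing matrix.
    """
    A = np.asarray(pinv_maps, dtype=float)
    X = np.asarray(data, dtype=float)
    B = np.asarray(modes, dtype=float)
    if A.shape[1] != X.shape[0]:
        raise ValueError("pinv_maps and data disagree on voxel count")
    if B.shape[1] != X.shape[1]:
        raise ValueError("modes and data disagree on frame count")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(B))):
        raise ValueError("non-finite input")
    if scaling is None:
        scaling = mode_covariance_scaling(B)
    n = X.shape[1]
    AX = A @ X                      # d x N network expression
    ZB = scaling @ B                # k x N
    f = n * np.einsum("dt,kt->dkt", AX, ZB)
    return TimeResolvedMixing(f=f, scaling=np.asarray(scaling), n_frames=n,
                              static_mixing=f.mean(axis=2), source=source)


def demean_over_time(trm: TimeResolvedMixing) -> TimeResolvedMixing:
    """Remove each (network, mode) series' temporal mean.

    The removed mean stays available as ``static_mixing``, so the original
    f is ``demeaned.f + static_mixing[:, :, None]``.
    """
    if trm.demeaned:
        raise ValueError("time-resolved mixing is already demeaned")
    mean = trm.f.mean(axis=2)
    return replace(trm, f=trm.f - mean[:, :, None], static_mixing=mean,
                   demeaned=True)


def task_regressor(events: EventTable, hrf_samples: np.ndarray, tr: float,
                   n_frames: int, zscore: bool = True) -> np.ndarray:
    """HRF-convolved stimulus regressor, one value per frame, z-scored.

    Onsets map to frames by floor(onset / TR).  With no events the zero
    vector is returned un-scaled (and logged).
    """
    stick = np.zeros(n_frames)
    if len(events):
        frames = np.floor(events.onsets / tr).astype(int)
        if np.any(frames >= n_frames) or np.any(frames < 0):
            raise ValueError("event onset falls outside the run")
        np.add.at(stick, frames, 1.0)
    else:
        logger.warning("task_regressor: no events; returning zero regressor")
        return stick
    reg = np.convolve(stick, np.asarray(hrf_samples, dtype=float))[:n_frames]
    if zscore:
        sd = reg.std()
        if sd == 0:
            logger.warning("task_regressor is constant; z-scoring skipped")
            return reg - reg.mean()
        reg = (reg - reg.mean()) / sd
    return reg


def select_task_tfm(tfm: TfmDecomposition, regressor: np.ndarray,
                    corr_floor: float = 0.05):
    """Pick the mode most correlated (in magnitude) with the task regressor.

    Returns ``(mode_index, correlation, sign)``; ``sign`` is the sign of
    the winning correlation, used to orient the time-resolved weights.
    """
    reg = np.asarray(regressor, dtype=float)
    if reg.std() == 0:
        raise ValueError("task regressor is constant")
    corrs = np.array([np.corrcoef(mode, reg)[0, 1] for mode in tfm.modes])
    idx = int(np.argmax(np.abs(corrs)))
    if np.abs(corrs[idx]) < corr_floor:
        logger.warning("no mode correlates with the task above %.2f "
                       "(best |r|=%.3f)", corr_floor, abs(corrs[idx]))
    sign = 1.0 if corrs[idx] >= 0 else -1.0
    return idx, float(corrs[idx]), sign


def align_sign(trm: TimeResolvedMixing, mode_index: int, sign: float) -> TimeResolvedMixing:
    """Orient one mode's weight series by the sign of its task correlation.

    ICA signs are arbitrary; flipping when the task correlation is
    negative makes weight directions comparable across runs.  Applying the
    same flip twice restores the original.
    """
    if sign not in (+1, -1, +1.0, -1.0):
        raise ValueError("sign must be +1 or -1")
    if sign == 1:
        return trm
    f = trm.f.copy()
    f[:, mode_index, :] *= -1.0
    static = trm.static_mixing.copy()
    static[:, mode_index] *= -1.0
    flips = trm.sign_flips.copy()
    flips[mode_index] *= -1.0
    return replace(trm, f=f, static_mixing=static, sign_flips=flips)


def project_loci(maps_subject: np.ndarray, trm: TimeResolvedMixing,
                 mode_index: int, frame: int | None = None) -> np.ndarray:
    """Instantaneous voxel map(s) of one mode: S @ f(:, mode, frame).

    With ``frame=None`` returns the full voxels x frames array (one map
    per frame); otherwise a single voxels vector.
    """
    if not 0 <= mode_index < trm.k:
        raise IndexError("mode index out of range")
    S = np.asarray(maps_subject, dtype=float)
    if frame is None:
        return S @ trm.f[:, mode_index, :]
    if not 0 <= frame < trm.n_frames:
        raise IndexError("frame out of range")
    return S @ trm.f[:, mode_index, frame]


def moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along the last axis (edge values repeated).

    The per-frame weights are rank-one estimates and individually noisy;
    smoothing over a window short relative to the dynamics of interest is
    the standard way to read slow allocation changes out of f.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    return uniform_filter1d(np.asarray(series, dtype=float), size=window,
                            axis=-1, mode="nearest")
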