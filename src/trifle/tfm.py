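"""Temporal functional modes: temporal ICA on network time series.

The d x frames network time-series matrix T is modelled as T = M B + e,
with B a set of k temporally independent, non-Gaussian mode time courses
and M the (time-invariant) networks x modes mixing matrix.  Estimation
uses FastICA with the logcosh (tanh) negentropy contrast, run on the
time dimension, with PCA whitening to k dimensions.

Normalization convention: each row of B is z-scored (population SD), all
scale lives in M, and modes are ordered by descending column norm of M.
ICA is identifiable only up to permutation and sign; use
:func:`match_components` to align a fit with a reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import norm
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

logger = logging.getLogger("trifle")

# E[log cosh(Z)] for Z ~ N(0,1); reference point of the negentropy proxy.
_GAUSS_LOGCOSH = 0.3745672956485929


@dataclass
class TfmDecomposition:
    """A temporal-ICA fit: mixing (d x k) and mode time courses (k x frames)."""

    mixing: np.ndarray
    modes: np.ndarray
    k: int
    seed: int
    n_iter: int
    converged: bool
    order_index: np.ndarray
    negentropy: float

    @property
    def n_frames(self) -> int:
        return self.modes.shape[1]


def _negentropy_proxy(sources: np.ndarray) -> float:
    """Sum over components of (E[log cosh(s)] - E[log cosh(Z)])^2."""
    g = np.mean(np.logaddexp(sources, -sources) - np.log(2.0), axis=-1)
    return float(np.sum((g - _GAUSS_LOGCOSH) ** 2))


def fit_temporal_ica(timeseries: np.ndarray, k: int, seed: int = 0,
                     max_iter: int = 1000, tol: float = 1e-6,
                     n_restarts: int = 5) -> TfmDecomposition:
    """Fit k temporally independent modes to a d x frames matrix.

    Runs ``n_restarts`` seeded FastICA fits and keeps the one with the
    largest logcosh negentropy proxy.  Deterministic for a fixed seed.
    Raises if frames < 2k; warns below 10k frames per mode.
    """
    T = np.asarray(timeseries, dtype=float)
    if T.ndim != 2:
        raise ValueError("timeseries must be 2D (networks x frames)")
    if not np.all(np.isfinite(T)):
        raise ValueError("timeseries contains non-finite values")
    d, n_frames = T.shape
    if k > d:
        raise ValueError(f"model order k={k} exceeds number of series d={d}")
    if n_frames < 2 * k:
        raise ValueError(f"{n_frames} frames is too few for k={k} modes")
    if n_frames < 10 * k:
        logger.warning("only %d frames for k=%d modes; estimates may be "
                       "unstable", n_frames, k)

    X = T.T  # samples (frames) x features (networks)
    best = None
    for r in range(n_restarts):
        ica = FastICA(n_components=k, fun="logcosh", whiten="unit-variance",
                      max_iter=max_iter, tol=tol, random_state=seed + r)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            sources = ica.fit_transform(X)  # frames x k
            converged = not any(issubclass(w.category, ConvergenceWarning)
                                for w in caught)
        score = _negentropy_proxy(sources.T)
        if best is None or score > best[0]:
            best = (score, sources, ica.mixing_, ica.n_iter_, converged)
    score, sources, mixing, n_iter, converged = best
    if not converged:
        logger.warning("FastICA did not converge in %d iterations; returning "
                       "best iterate", max_iter)

    B = sources.T
    B = B - B.mean(axis=1, keepdims=True)
    sd = B.std(axis=1)  # population SD so rows have exactly unit power
    if np.any(sd == 0):
        raise np.linalg.LinAlgError("degenerate (constant) mode time course")
    B = B / sd[:, None]
    M = mixing * sd[None, :]

    order = np.argsort(-np.linalg.norm(M, axis=0), kind="stable")
    M = M[:, order]
    B = B[order]
    return TfmDecomposition(mixing=M, modes=B, k=k, seed=seed, n_iter=int(n_iter),
                            converged=bool(converged), order_index=order,
                            negentropy=score)


def match_components(est_modes: np.ndarray, ref_modes: np.ndarray):
    """Optimal permutation/sign alignment of estimated modes to a reference.

    Returns ``(perm, signs)`` such that ``signs[i] * est_modes[perm[i]]``
    is the best match for ``ref_modes[i]``, maximizing total |correlation|
    by optimal assignment.
    """
    est = np.asarray(est_modes, dtype=float)
    ref = np.asarray(ref_modes, dtype=float)
    if est.shape[0] != ref.shape[0]:
        raise ValueError("mode counts differ")
    k = est.shape[0]
    if np.any(est.std(axis=1) == 0) or np.any(ref.std(axis=1) == 0):
        raise ValueError("degenerate zero-variance mode")
    C = np.corrcoef(ref, est)[:k, k:]  # C[i, j] = corr(ref_i, est_j)
    rows, cols = linear_sum_assignment(-np.abs(C))
    perm = cols[np.argsort(rows)]
    signs = np.sign(C[np.arange(k), perm])
    signs[signs == 0] = 1.0
    return perm, signs.astype(float)


def matched_correlations(est_modes: np.ndarray, ref_modes: np.ndarray) -> np.ndarray:
    """|corr| between each reference mode and its matched estimate."""
    perm, _ = match_components(est_modes, ref_modes)
    k = len(perm)
    C = np.corrcoef(np.asarray(ref_modes), np.asarray(est_modes)[perm])[:k, k:]
    return np.abs(np.diag(C))
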