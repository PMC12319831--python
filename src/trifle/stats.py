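"""Trial-locked descriptive statistics for time-resolved mixing weights.

The per-frame weights of the task-relevant mode are cut into fixed-length
trial epochs (60 frames by default, stimulus- or response-locked), ranked
per time point to show which network dominates, and tested per (network,
time point): one-sample t against zero for task-evoked allocation, and
Welch two-sample t (fail - hit) for outcome differences.  Run-level t
maps are combined into group-level Z maps by probability matching and
Stouffer's method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import EventTable

logger = logging.getLogger("trifle")


@dataclass
class TrialEpochs:
    """Trial-epoched weights: trials x networks x epoch_frames."""

    weights: np.ndarray
    outcomes: np.ndarray
    epoch_frames: int
    tr: float
    lock: str = "stimulus"

    def __post_init__(self):
        if self.weights.shape[0] != len(self.outcomes):
            raise ValueError("trial count does not match outcome count")
        if self.weights.shape[2] != self.epoch_frames:
            raise ValueError("weights last axis must equal epoch_frames")

    @property
    def n_trials(self) -> int:
        return self.weights.shape[0]

    @property
    def n_networks(self) -> int:
        return self.weights.shape[1]

    @property
    def epoch_duration(self) -> float:
        """Epoch length in seconds (epoch_frames * TR)."""
        return self.epoch_frames * self.tr


@dataclass
class TimepointStats:
    """Per-(network, time point) statistics; NaN marks undefined cells."""

    t_values: np.ndarray            # networks x epoch_frames
    df: np.ndarray                  # scalar-like or per-cell degrees of freedom
    n_per_cell: np.ndarray
    z_values: np.ndarray | None = None


def epoch_trials(mode_weights: np.ndarray, events: EventTable, tr: float,
                 epoch_frames: int = 60, lock: str = "stimulus",
                 response_lock_offset: int = 10) -> TrialEpochs:
    """Cut a networks x frames weight series into per-trial epochs.

    Stimulus-locked windows start at floor(onset/TR); response-locked
    windows start ``response_lock_offset`` frames before
    floor((onset + response_time)/TR).  Trials whose window leaves the run
    (or lack a response time under response locking) are dropped and
    logged.
    """
    if epoch_frames < 1:
        raise ValueError("epoch_frames must be >= 1")
    if lock not in ("stimulus", "response"):
        raise ValueError("lock must be 'stimulus' or 'response'")
    W = np.asarray(mode_weights, dtype=float)
    n_frames = W.shape[1]
    epochs, kept = [], []
    for i in range(len(events)):
        if lock == "stimulus":
            start = int(np.floor(events.onsets[i] / tr))
        else:
            rt = events.response_times[i]
            if not np.isfinite(rt):
                logger.info("trial %d dropped: no response time", i)
                continue
            start = int(np.floor((events.onsets[i] + rt) / tr)) - response_lock_offset
        if start < 0 or start + epoch_frames > n_frames:
            logger.info("trial %d dropped: window [%d, %d) outside run of %d "
                        "frames", i, start, start + epoch_frames, n_frames)
            continue
        epochs.append(W[:, start:start + epoch_frames])
        kept.append(i)
    if not epochs:
        raise ValueError("no trial window fits inside the run")
    return TrialEpochs(weights=np.stack(epochs), outcomes=events.outcomes[kept],
                       epoch_frames=epoch_frames, tr=tr, lock=lock)


def rank_networks(epochs: TrialEpochs, average: bool = False) -> np.ndarray:
    """Index of the top-weighted network per time point.

    Per trial by default (trials x epoch_frames); with ``average=True``
    the weights are first averaged across trials (epoch_frames,).  Exact
    ties resolve to the lower network index (and are logged).
    """
    W = epochs.weights.mean(axis=0, keepdims=True) if average else epochs.weights
    top = W.max(axis=1)
    ties = (W == top[:, None, :]).sum(axis=1) > 1
    if ties.any():
        logger.info("rank_networks: %d tied time point(s); lower index kept",
                    int(ties.sum()))
    ranks = W.argmax(axis=1)
    return ranks[0] if average else ranks


def group_modal_rank(rank_vectors) -> np.ndarray:
    """Most common highest-ranking network per time point across runs."""
    R = np.vstack([np.asarray(r) for r in rank_vectors])
    mode, _ = sps.mode(R, axis=0, keepdims=False)
    return np.asarray(mode)


def timepoint_one_sample_t(epochs: TrialEpochs) -> TimepointStats:
    """One-sample t of trial weights against zero, per (network, time point)."""
    W = epochs.weights
    n = W.shape[0]
    if n < 2:
        raise ValueError("one-sample t needs at least 2 trials")
    mean = W.mean(axis=0)
    sd = W.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    undefined = zero_var & (mean != 0)
    t = np.where(zero_var, np.where(mean == 0, 0.0, np.nan), t)
    if undefined.any():
        logger.warning("%d cell(s) with zero variance; t undefined there",
                       int(undefined.sum()))
    return TimepointStats(t_values=t, df=np.full(t.shape, n - 1, dtype=float),
                          n_per_cell=np.full(t.shape, n))


def timepoint_two_sample_t(epochs: TrialEpochs) -> TimepointStats:
    """Welch t of fail minus hit trials per (network, time point).

    Delayed and unscored trials are excluded.  Requires at least 2 trials
    in each outcome group.
    """
    fail = epochs.weights[epochs.outcomes == "fail"]
    hit = epochs.weights[epochs.outcomes == "hit"]
    if len(fail) < 2 or len(hit) < 2:
        raise ValueError("need >= 2 trials per outcome group "
                         f"(hit={len(hit)}, fail={len(fail)})")
    res = sps.ttest_ind(fail, hit, axis=0, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    df = np.asarray(res.df, dtype=float)
    # both groups constant with equal means: the difference is exactly 0
    no_var = (fail.std(axis=0) == 0) & (hit.std(axis=0) == 0)
    equal = fail.mean(axis=0) == hit.mean(axis=0)
    t = np.where(no_var & equal, 0.0, t)
    df = np.where(no_var & equal, len(fail) + len(hit) - 2, df)
    n_cell = np.full(t.shape, len(fail) + len(hit))
    bad = ~np.isfinite(t)
    if bad.any():
        logger.warning("%d undefined fail-hit cell(s)", int(bad.sum()))
    return TimepointStats(t_values=t, df=df, n_per_cell=n_cell)


def t_to_z(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Map t values to standard-normal z with matching two-sided tails."""
    t = np.asarray(t, dtype=float)
    df = np.asarray(df, dtype=float)
    p_two = 2.0 * sps.t.sf(np.abs(t), df)
    # clip to keep the normal quantile finite for extreme t
    p_two = np.clip(p_two, 1e-300, 1.0)
    return np.sign(t) * sps.norm.isf(p_two / 2.0)


def combine_group_z(per_unit_stats) -> TimepointStats:
    """Stouffer combination of run/participant-level t maps into group Z.

    Each unit's t map is converted to signed z (tail matching), and cells
    are combined as sum(z) / sqrt(#units with an estimate); cells with no
    contributing unit stay NaN.
    """
    per_unit_stats = list(per_unit_stats)
    if not per_unit_stats:
        raise ValueError("no units to combine")
    zs = np.stack([t_to_z(s.t_values, s.df) for s in per_unit_stats])
    valid = np.isfinite(zs)
    count = valid.sum(axis=0)
    if not count.any():
        raise ValueError("all cells undefined across units")
    zsum = np.where(valid, zs, 0.0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(count > 0, zsum / np.sqrt(np.maximum(count, 1)), np.nan)
    t_ref = per_unit_stats[0]
    return TimepointStats(t_values=t_ref.t_values, df=t_ref.df,
                          n_per_cell=count, z_values=z)
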