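"""Haemodynamic response functions and the optimal linear basis set.

HRFs are parametrized as four half-cosine segments (a flat onset delay, a
rise to peak, a fall into an undershoot, and a recovery to baseline).
Sampling many such HRFs with parameters drawn uniformly from preset
ranges and taking the leading principal components yields a small
orthonormal basis (in the spirit of FSL's FLOBS) that can represent a
wide family of plausible response shapes; the first component tracks the
average response, the second mainly latency shifts, the third dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Parameter ranges (seconds) for sampled HRFs: onset delay 0-2.5, rise
#: 2.5-6, fall 2.5-8, recovery 2.5-6, plus an undershoot depth of 0-0.5
#: relative to the peak.
DEFAULT_RANGES = {
    "onset_latency": (0.0, 2.5),
    "rise": (2.5, 6.0),
    "fall": (2.5, 8.0),
    "recover": (2.5, 6.0),
    "undershoot_ratio": (0.0, 0.5),
}


@dataclass
class HrfParams:
    """Half-cosine HRF segment durations (s) and undershoot depth."""

    onset_latency: float
    rise: float
    fall: float
    recover: float
    undershoot_ratio: float = 0.2

    def __post_init__(self):
        for name in ("onset_latency", "rise", "fall", "recover"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.undershoot_ratio < 1:
            raise ValueError("undershoot_ratio must be in [0, 1)")

    @property
    def total_duration(self) -> float:
        return self.onset_latency + self.rise + self.fall + self.recover


@dataclass
class HrfBasis:
    """Orthonormal basis functions (rows) sampled every ``dt`` seconds."""

    basis: np.ndarray
    dt: float
    n_sampled: int
    explained_variance: np.ndarray = field(default=None)

    @property
    def n_basis(self) -> int:
        return self.basis.shape[0]

    @property
    def n_samples(self) -> int:
        return self.basis.shape[1]


def half_cosine_hrf(params: HrfParams, dt: float, n_samples: int | None = None) -> np.ndarray:
    """Sample one half-cosine HRF on a dt grid.

    The continuous curve is 0 during the onset delay, rises 0 -> 1 over
    ``rise``, falls 1 -> -undershoot_ratio over ``fall``, and recovers to
    0 over ``recover``; its peak is exactly 1.  ``n_samples`` pads (or
    clips) to a fixed grid length.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_samples is None:
        n_samples = int(np.ceil(params.total_duration / dt)) + 1
    t = np.arange(n_samples) * dt
    u = params.undershoot_ratio
    t0 = params.onset_latency
    t1, t2, t3 = t0 + params.rise, t0 + params.rise + params.fall, params.total_duration
    h = np.zeros(n_samples)
    if params.rise > 0:
        m = (t >= t0) & (t < t1)
        h[m] = 0.5 * (1.0 - np.cos(np.pi * (t[m] - t0) / params.rise))
    if params.fall > 0:
        m = (t >= t1) & (t < t2)
        h[m] = -u + (1.0 + u) * 0.5 * (1.0 + np.cos(np.pi * (t[m] - t1) / params.fall))
    if params.recover > 0:
        m = (t >= t2) & (t < t3)
        h[m] = -u * 0.5 * (1.0 + np.cos(np.pi * (t[m] - t2) / params.recover))
    return h


def sample_hrf_params(ranges: dict, rng: np.random.Generator) -> HrfParams:
    """Draw one parameter set uniformly within ``ranges``."""
    vals = {}
    for name, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValueError(f"degenerate range for {name}: min > max")
        vals[name] = rng.uniform(lo, hi)
    return HrfParams(**vals)


def flobs_basis(ranges: dict | None = None, n_sampled: int = 1000,
                n_basis: int = 6, dt: float = 0.206, seed: int = 0) -> HrfBasis:
    """Optimal basis set: PCA of ``n_sampled`` randomly parametrized HRFs.

    Curves are built on a common grid spanning the longest possible HRF
    (zero-padded), and the top ``n_basis`` right singular vectors of the
    sample matrix are returned as unit-norm, mutually orthogonal rows.
    The singular vectors are taken without mean-centering so that the
    first component follows the mean sampled response; each component's
    sign is fixed so its largest-magnitude sample is positive.
    Deterministic for a fixed seed.
    """
    ranges = dict(DEFAULT_RANGES if ranges is None else ranges)
    if n_basis > n_sampled:
        raise ValueError("n_basis cannot exceed n_sampled")
    for name, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValueError(f"degenerate range for {name}: min > max")
    max_total = sum(ranges[k][1] for k in ("onset_latency", "rise", "fall", "recover"))
    n_samples = int(np.ceil(max_total / dt)) + 1
    rng = np.random.default_rng(seed)
    H = np.empty((n_sampled, n_samples))
    for i in range(n_sampled):
        H[i] = half_cosine_hrf(sample_hrf_params(ranges, rng), dt, n_samples)
    _, s, Vt = np.linalg.svd(H, full_matrices=False)
    basis = Vt[:n_basis].copy()
    for row in basis:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    explained = (s ** 2 / np.sum(s ** 2))[:n_basis]
    return HrfBasis(basis=basis, dt=dt, n_sampled=n_sampled,
                    explained_variance=explained)


def canonical_hrf(dt: float, length: float = 32.0) -> np.ndarray:
    """Double-gamma HRF: unit peak at 6 s, undershoot at 16 s, ratio 1/6."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, length, dt)
    peak = stats.gamma.pdf(t, a=7.0, scale=1.0)       # mode at (a-1)*scale = 6
    under = stats.gamma.pdf(t, a=17.0, scale=1.0)     # mode at 16
    h = peak - under / 6.0
    return h / h.max()


def save_basis_tsv(basis: HrfBasis, path) -> None:
    """Write the basis as a TSV (samples x n_basis) with dt in a comment."""
    with open(path, "w") as fh:
        fh.write(f"# dt={basis.dt}\tn_sampled={basis.n_sampled}\n")
        header = "\t".join(f"BF{i + 1}" for i in range(basis.n_basis))
        fh.write(header + "\n")
        for row in basis.basis.T:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")
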