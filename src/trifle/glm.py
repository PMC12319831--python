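"""GLM parametrization of allocation time courses with AR(p) errors.

Weight time series are predicted from the task impulse train convolved
with each HRF basis function (optionally split by trial outcome with
hit/fail main effects), fit by generalized least squares with an
autoregressive error model of fixed order (statsmodels GLSAR, iterated
until the coefficients stabilize), followed by Benjamini-Hochberg FDR
over the model's p-values, post-hoc linear contrasts (fail - hit), and
reconstruction of temporal profiles as basis-weighted sums of the fitted
coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .hrf import HrfBasis
from .io import EventTable

logger = logging.getLogger("trifle")


@dataclass
class DesignMatrix:
    columns: np.ndarray          # frames x p
    names: list
    family: str = "baseline"

    def __post_init__(self):
        self.columns = np.asarray(self.columns, dtype=float)
        if len(self.names) != self.columns.shape[1]:
            raise ValueError("names must match design columns")
        if len(set(self.names)) != len(self.names):
            raise ValueError("design column names must be unique")
        if np.any(np.all(self.columns == 0, axis=0)):
            raise ValueError("design contains an all-zero column")

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.columns))

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class GlmFit:
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p_values: np.ndarray
    ar_coeffs: np.ndarray
    sigma2: float
    names: list
    df_resid: float
    converged: bool
    fdr_mask: np.ndarray | None = None
    p_adjusted: np.ndarray | None = None
    contrasts: list = field(default_factory=list)
    results: object = None  # statsmodels results, kept for contrasts


def _convolved_columns(onsets: np.ndarray, basis: HrfBasis, tr: float,
                       n_frames: int, suffix: str = "") -> tuple:
    stick = np.zeros(n_frames)
    frames = np.floor(onsets / tr).astype(int)
    if np.any(frames >= n_frames) or np.any(frames < 0):
        raise ValueError("event onset falls outside the run")
    np.add.at(stick, frames, 1.0)
    cols, names = [], []
    for i in range(basis.n_basis):
        cols.append(np.convolve(stick, basis.basis[i])[:n_frames])
        names.append(f"BF{i + 1}{suffix}")
    return cols, names


def build_design(events: EventTable, basis: HrfBasis, tr: float, n_frames: int,
                 family: str = "baseline", epoch_frames: int = 60) -> DesignMatrix:
    """Design matrix of basis-convolved task regressors.

    ``family='baseline'``: one column per basis function, the stimulus
    impulse train convolved with it (BF1..BFn).

    ``family='success'``: hit and fail epoch-spanning boxcar main effects,
    the all-trials convolved columns, and per-outcome convolved
    interaction columns (Hit, Fail, BFi, BFi x Hit, BFi x Fail).  Trials
    of any third outcome (e.g. delayed) contribute to the BFi columns
    only; without such trials the three column groups are collinear.
    """
    if abs(basis.dt - tr) > 1e-9:
        raise ValueError("basis sampling interval must equal the TR")
    if len(events) == 0:
        raise ValueError("no events to build a design from")
    if family == "baseline":
        cols, names = _convolved_columns(events.onsets, basis, tr, n_frames)
        return DesignMatrix(np.column_stack(cols), names, family)
    if family != "success":
        raise ValueError(f"unknown design family '{family}'")

    hit = events.outcomes == "hit"
    fail = events.outcomes == "fail"
    if not hit.any() or not fail.any():
        missing = "hit" if not hit.any() else "fail"
        raise ValueError(f"no events of outcome '{missing}'")
    cols, names = [], []
    for label, mask in (("Hit", hit), ("Fail", fail)):
        box = np.zeros(n_frames)
        for onset in events.onsets[mask]:
            start = int(np.floor(onset / tr))
            box[start:start + epoch_frames] = 1.0
        cols.append(box)
        names.append(label)
    c, n = _convolved_columns(events.onsets, basis, tr, n_frames)
    cols += c
    names += n
    for label, mask in (("Hit", hit), ("Fail", fail)):
        c, n = _convolved_columns(events.onsets[mask], basis, tr, n_frames,
                                  suffix=f" x {label}")
        cols += c
        names += n
    design = DesignMatrix(np.column_stack(cols), names, family)
    if design.condition_number > 1e8:
        logger.warning("success design is near-singular (condition number "
                       "%.3g); add trials outside hit/fail or drop terms",
                       design.condition_number)
    return design


def fit_glsar(y: np.ndarray, design: DesignMatrix, ar_order: int = 5,
              max_iter: int = 20, tol: float = 1e-8,
              alpha: float | None = 0.05) -> GlmFit:
    """Generalized least squares with AR(ar_order) errors.

    Iterates fit -> AR estimation from residuals -> whitening -> refit
    until the coefficients move less than ``tol`` (relative) or
    ``max_iter`` passes.  ``ar_order=0`` reduces exactly to OLS.  When
    ``alpha`` is given, BH-FDR across this model's p-values fills
    ``fdr_mask`` / ``p_adjusted``.
    """
    y = np.asarray(y, dtype=float)
    X = design.columns
    if y.shape[0] != X.shape[0]:
        raise ValueError("y and design disagree on frame count")
    if y.shape[0] <= X.shape[1] + ar_order:
        raise ValueError("too few frames for this design and AR order")
    if ar_order == 0:
        res = sm.OLS(y, X).fit()
        rho = np.empty(0)
        converged = True
    else:
        model = sm.GLSAR(y, X, rho=ar_order)
        prev = None
        converged = False
        res = model.fit()
        for _ in range(max_iter):
            rho_est, _ = sm.regression.yule_walker(res.resid, order=ar_order)
            model = sm.GLSAR(y, X, rho=np.asarray(rho_est))
            res = model.fit()
            b = np.asarray(res.params)
            if prev is not None and np.linalg.norm(b - prev) <= tol * max(
                    1.0, np.linalg.norm(prev)):
                converged = True
                break
            prev = b
        rho = np.atleast_1d(np.asarray(model.rho, dtype=float))
        if not converged:
            logger.warning("GLSAR did not converge in %d iterations", max_iter)
    fit = GlmFit(
        beta=np.asarray(res.params), se=np.asarray(res.bse),
        t=np.asarray(res.tvalues), p_values=np.asarray(res.pvalues),
        ar_coeffs=rho, sigma2=float(res.scale), names=list(design.names),
        df_resid=float(res.df_resid), converged=converged, results=res)
    if alpha is not None:
        fit.fdr_mask, fit.p_adjusted = fdr_bh(fit.p_values, alpha)
    return fit


def fdr_bh(p_values: np.ndarray, alpha: float = 0.05):
    """Benjamini-Hochberg step-up FDR: (reject mask, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def posthoc_contrast(fit: GlmFit, contrast_vector: np.ndarray,
                     name: str | None = None):
    """Linear contrast c'beta with t and two-sided p from the whitened fit."""
    c = np.asarray(contrast_vector, dtype=float)
    if c.shape[0] != len(fit.beta):
        raise ValueError("contrast length must match the number of coefficients")
    tt = fit.results.t_test(c)
    var = float(np.squeeze(tt.sd)) ** 2
    if var <= 0 or not np.isfinite(var):
        raise ValueError("contrast has zero variance")
    delta = float(np.squeeze(tt.effect))
    t = float(np.squeeze(tt.tvalue))
    p = float(np.squeeze(tt.pvalue))
    fit.contrasts.append((name or "contrast", delta, t, p))
    return delta, t, p


def fail_minus_hit_contrasts(fit: GlmFit, n_basis: int) -> list:
    """The table-style post-hoc contrasts: Fail-Hit and BFi x (Fail-Hit)."""
    out = []
    pairs = [("Fail", "Hit", "Fail - Hit")]
    pairs += [(f"BF{i + 1} x Fail", f"BF{i + 1} x Hit",
               f"BF{i + 1} x (Fail - Hit)") for i in range(n_basis)]
    for pos, neg, label in pairs:
        c = np.zeros(len(fit.names))
        c[fit.names.index(pos)] = 1.0
        c[fit.names.index(neg)] = -1.0
        out.append((label,) + posthoc_contrast(fit, c, name=label))
    return out


def reconstruct_profile(fit: GlmFit, basis: HrfBasis,
                        group: str = "baseline") -> np.ndarray:
    """Temporal profile implied by the fitted coefficients.

    baseline: sum_i beta_BFi * basis_i.  hit/fail: adds the outcome's
    interaction-weighted basis functions and its main-effect offset.
    """
    profile = np.zeros(basis.n_samples)
    try:
        for i in range(basis.n_basis):
            profile += fit.beta[fit.names.index(f"BF{i + 1}")] * basis.basis[i]
        if group in ("hit", "fail"):
            label = group.capitalize()
            for i in range(basis.n_basis):
                idx = fit.names.index(f"BF{i + 1} x {label}")
                profile += fit.beta[idx] * basis.basis[i]
            profile += fit.beta[fit.names.index(label)]
        elif group != "baseline":
            raise ValueError(f"unknown group '{group}'")
    except ValueError as err:
        if "is not in list" in str(err):
            raise KeyError(f"fit lacks coefficients for group '{group}'") from err
        raise
    return profile


def fit_table(fit: GlmFit) -> "pd.DataFrame":
    """Coefficient table (Predictor, b, SE, t, p, FDR) plus contrasts."""
    import pandas as pd

    df = pd.DataFrame({
        "Predictor": fit.names, "b": fit.beta, "SE": fit.se, "t": fit.t,
        "p": fit.p_values,
        "fdr_significant": fit.fdr_mask if fit.fdr_mask is not None else False,
    })
    if fit.contrasts:
        extra = pd.DataFrame(fit.contrasts,
                             columns=["Predictor", "delta_b", "t_contrast",
                                      "p_contrast"])
        df = pd.concat([df, extra], ignore_index=True)
    return df
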