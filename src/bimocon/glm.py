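"""Minimal first-level GLM on ROI-averaged BOLD series.

The design contains, per coupling mode occurring in the run, the mode's
boxcar convolved with a canonical double-gamma HRF plus its temporal
derivative, together with an intercept and low-order polynomial drift.
Fitting is ordinary least squares per ROI; the per-subject "parameter
estimate" handed to the connectivity analysis is the task-vs-rest contrast
on the HRF column alone (the derivative column absorbs small onset-latency
mismatch but is excluded from the contrast by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .schedule import TaskSchedule


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    dispersion_s: float = 1.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at times ``t``.

    Positive lobe with delay parameter 6 s (gamma mode near 5 s), undershoot
    with delay 16 s at 1/6 relative amplitude; normalized to unit peak so
    regressor amplitudes are in signal units.
    """
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, peak_delay_s / dispersion_s, scale=dispersion_s)
    h = h - undershoot_ratio * gamma_dist.pdf(
        t, undershoot_delay_s / dispersion_s, scale=dispersion_s
    )
    peak = h.max()
    return h / peak if peak > 0 else h


def _convolved_regressor(
    schedule: TaskSchedule, mode: str, oversample: int, hrf_params: dict
) -> tuple[np.ndarray, np.ndarray]:
    """(regressor, derivative) for one mode, sampled at the volume times."""
    dt = schedule.tr_s / oversample
    n_fine = int(np.ceil(schedule.total_duration_s / dt)) + 1
    t_fine = np.arange(n_fine) * dt
    boxcar = np.zeros(n_fine)
    for b in schedule.task_blocks(mode):
        boxcar[(t_fine >= b.start_s) & (t_fine < b.end_s)] = 1.0
    hrf_t = np.arange(0.0, 32.0 + dt, dt)
    hrf = double_gamma_hrf(hrf_t, **hrf_params)
    conv = np.convolve(boxcar, hrf)[:n_fine] * dt
    deriv = np.gradient(conv, dt)
    vol_idx = np.round(schedule.volume_times() / dt).astype(int)
    return conv[vol_idx], deriv[vol_idx]


def mode_regressors(
    schedule: TaskSchedule, oversample: int = 10, hrf_params: dict | None = None
) -> dict[str, np.ndarray]:
    """HRF-convolved boxcar per mode present in the run (no derivatives).

    Each regressor is rescaled to unit plateau so a simulated amplitude of
    ``a`` produces a sustained response of height ``a``.
    """
    hrf_params = hrf_params or {}
    out = {}
    dt = schedule.tr_s / oversample
    hrf_t = np.arange(0.0, 32.0 + dt, dt)
    area = np.trapezoid(double_gamma_hrf(hrf_t, **hrf_params), hrf_t)
    for mode in dict.fromkeys(schedule.mode_sequence):
        reg, _ = _convolved_regressor(schedule, mode, oversample, hrf_params)
        out[mode] = reg / area  # plateau of a long block -> HRF area -> 1
    return out


@dataclass(frozen=True)
class DesignMatrix:
    """Named regressors sampled at the volume acquisition times."""

    frame: pd.DataFrame  # rows: volumes, columns: named regressors
    task_columns: tuple[str, ...]

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


def build_design(
    schedule: TaskSchedule,
    hrf_params: dict | None = None,
    drift_order: int = 1,
    oversample: int = 10,
) -> DesignMatrix:
    """Design matrix: intercept, polynomial drift, and per-mode HRF + derivative."""
    hrf_params = hrf_params or {}
    t = schedule.volume_times()
    n = len(t)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    if n > 1:
        u = 2.0 * (t - t.min()) / (t.max() - t.min()) - 1.0
        for k in range(1, drift_order + 1):
            cols[f"drift_{k}"] = u**k
    task_cols = []
    dt = schedule.tr_s / oversample
    hrf_t = np.arange(0.0, 32.0 + dt, dt)
    area = np.trapezoid(double_gamma_hrf(hrf_t, **hrf_params), hrf_t)
    for mode in dict.fromkeys(schedule.mode_sequence):
        reg, deriv = _convolved_regressor(schedule, mode, oversample, hrf_params)
        if not np.any(reg):
            raise ValueError(f"mode {mode!r} occurs in the run but its regressor is all zero")
        cols[mode] = reg / area
        cols[f"{mode}_deriv"] = deriv / area
        task_cols.append(mode)
    frame = pd.DataFrame(cols, index=np.round(t, 6))
    X = frame.to_numpy()
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        bad = [frame.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return DesignMatrix(frame=frame, task_columns=tuple(task_cols))


@dataclass(frozen=True)
class GLMFit:
    """OLS estimates per ROI plus what is needed for contrasts."""

    design: DesignMatrix
    coef: pd.DataFrame  # regressor x ROI
    sigma2: pd.Series  # residual variance per ROI
    dof: int
    xtx_inv: np.ndarray


def fit_glm(series: pd.DataFrame, design: DesignMatrix) -> GLMFit:
    """Ordinary least squares of each ROI series on the design."""
    Y = np.asarray(series, dtype=float)
    X = design.matrix
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"series has {Y.shape[0]} volumes but design has {X.shape[0]} rows"
        )
    if np.isnan(Y).any():
        raise ValueError("series contains NaN values")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = X.shape[0] - np.linalg.matrix_rank(X)
    sigma2 = (resid**2).sum(axis=0) / dof
    rois = list(series.columns) if isinstance(series, pd.DataFrame) else ["roi"]
    return GLMFit(
        design=design,
        coef=pd.DataFrame(beta, index=design.columns, columns=rois),
        sigma2=pd.Series(sigma2, index=rois),
        dof=dof,
        xtx_inv=xtx_inv,
    )


def contrast(fit: GLMFit, weights: dict[str, float] | np.ndarray) -> pd.DataFrame:
    """Linear contrast w'beta per ROI with OLS standard error and t value."""
    cols = fit.design.columns
    if isinstance(weights, dict):
        unknown = set(weights) - set(cols)
        if unknown:
            raise ValueError(f"unknown regressors in contrast: {sorted(unknown)}")
        w = np.array([weights.get(c, 0.0) for c in cols])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(cols),):
            raise ValueError(f"weight vector must have length {len(cols)}")
    if not np.any(w):
        raise ValueError("contrast weights are all zero")
    est = w @ fit.coef.to_numpy()
    var_scale = float(w @ fit.xtx_inv @ w)
    se = np.sqrt(fit.sigma2.to_numpy() * var_scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, est / se, np.inf * np.sign(est))
    return pd.DataFrame(
        {"estimate": est, "se": se, "t": tval}, index=fit.coef.columns
    )


def task_betas(fit: GLMFit, mode: str, include_derivative: bool = False) -> pd.DataFrame:
    """Task-vs-rest parameter estimate per ROI for one mode.

    By default only the HRF column enters the contrast; setting
    ``include_derivative`` combines HRF and derivative as the RMS-signed
    amplitude is *not* standard here -- the derivative is simply added with
    zero weight unless requested.
    """
    if mode not in fit.design.task_columns:
        raise ValueError(f"mode {mode!r} not in design task columns {fit.design.task_columns}")
    weights = {mode: 1.0}
    if include_derivative:
        weights[f"{mode}_deriv"] = 1.0
    return contrast(fit, weights)
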