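"""Dual fMRI preprocessing pipelines.

Two divergent paths are deliberately kept apart:

* the **gBOLD path** applies slice-timing correction, nuisance regression
  (24 motion regressors plus white-matter and CSF mean signals), linear
  detrending and 0.01-0.1 Hz band-pass filtering;
* the **CSF path** applies only slice-timing correction, detrending and
  band-pass filtering -- crucially it never regresses out CSF signal,
  since that signal *is* the quantity of interest.

All filtering is zero-phase (forward-backward Butterworth), so the lag
geometry of the coupling analysis is not distorted by the filter.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, detrend as _sp_detrend, sosfiltfilt

from .core import MotionParams, PhantomLabels, Volume4D

__all__ = [
    "slice_timing_correct",
    "detrend",
    "bandpass",
    "friston24",
    "nuisance_regress",
    "preprocess_gbold",
    "preprocess_csf",
    "GBOLD_STAGES",
    "CSF_STAGES",
]

logger = logging.getLogger(__name__)

GBOLD_STAGES = ("slice_timing", "nuisance_regression", "detrend", "bandpass")
CSF_STAGES = ("slice_timing", "detrend", "bandpass")


# ---------------------------------------------------------------------------
# stage operations
# ---------------------------------------------------------------------------

def slice_timing_correct(
    vol: Volume4D,
    slice_order: np.ndarray | list[int] | None,
    tr_s: float | None = None,
    ref_slice: int = 0,
) -> Volume4D:
    """Resample each slice's time series to the reference slice's acquisition time.

    ``slice_order`` lists slice indices in the order they were acquired
    within a TR (a permutation of ``range(nz)``); acquisition times are
    assumed evenly spread over the TR. ``None`` means all slices were
    acquired simultaneously (already aligned data): the volume passes
    through unchanged. Temporal interpolation is cubic-spline with clamped
    edges; output dimensions are unchanged.
    """
    if slice_order is None:
        return vol.copy()
    tr = vol.tr_s if tr_s is None else tr_s
    nz = vol.shape[2]
    order = np.asarray(slice_order, dtype=int)
    if order.size != nz or sorted(order.tolist()) != list(range(nz)):
        raise ValueError(
            f"slice_order must be a permutation of 0..{nz - 1}, got length {order.size}"
        )
    # acquisition time (s) of each slice within the TR
    acq_time = np.empty(nz)
    acq_time[order] = np.arange(nz) * (tr / nz)
    t_idx = np.arange(vol.n_timepoints, dtype=float)
    out = np.empty_like(vol.data, dtype=float)
    for z in range(nz):
        shift = (acq_time[z] - acq_time[ref_slice]) / tr  # in samples
        if shift == 0:
            out[:, :, z, :] = vol.data[:, :, z, :]
            continue
        series = vol.data[:, :, z, :].reshape(-1, vol.n_timepoints)
        spline = CubicSpline(t_idx, series, axis=1, bc_type="natural")
        target = np.clip(t_idx - shift, 0.0, t_idx[-1])
        out[:, :, z, :] = spline(target).reshape(vol.data.shape[0], vol.data.shape[1], -1)
    return Volume4D(out, vol.voxel_size_mm, vol.tr_s)


def detrend(ts: np.ndarray, axis: int = -1) -> np.ndarray:
    """Remove the least-squares linear trend (and mean) along ``axis``."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[axis] < 3:
        raise ValueError("need at least 3 samples to detrend")
    return _sp_detrend(ts, axis=axis, type="linear")


def bandpass(
    ts: np.ndarray,
    fs_hz: float,
    low: float = 0.01,
    high: float = 0.1,
    order: int = 4,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass filter.

    Forward-backward application (``sosfiltfilt``) cancels the phase
    response, so an in-band sinusoid emerges with no lag -- a hard
    requirement here, because a filter-induced lag would masquerade as
    coupling lag.
    """
    nyq = fs_hz / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"infeasible band [{low}, {high}] Hz for sampling rate {fs_hz} Hz"
        )
    sos = butter(order, [low, high], btype="bandpass", fs=fs_hz, output="sos")
    return sosfiltfilt(sos, np.asarray(ts, dtype=float), axis=axis)


def friston24(motion: MotionParams) -> np.ndarray:
    """24-parameter motion regressor matrix.

    Columns are ordered ``[R(t), R(t-1), R(t)^2, R(t-1)^2]`` where R holds
    the six realignment parameters; the lagged blocks are zero-padded at
    the first time point.
    """
    R = motion.params
    R_lag = np.vstack([np.zeros((1, 6)), R[:-1]])
    return np.hstack([R, R_lag, R**2, R_lag**2])


def nuisance_regress(
    ts: np.ndarray, regressors: np.ndarray, add_intercept: bool = True
) -> np.ndarray:
    """OLS residual of ``ts`` (1D, or (n_series, n_t)) on the regressor columns.

    Collinear regressor columns are dropped with a logged warning before
    the fit; the residual is orthogonal to every retained column.
    """
    ts = np.asarray(ts, dtype=float)
    one_d = ts.ndim == 1
    Y = ts[None, :] if one_d else ts
    X = np.asarray(regressors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != Y.shape[1]:
        raise ValueError(
            f"length mismatch: series have {Y.shape[1]} samples, "
            f"regressors {X.shape[0]} rows"
        )
    if add_intercept:
        X = np.hstack([np.ones((X.shape[0], 1)), X])
    X = _drop_collinear(X)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    return resid.T[0] if one_d else resid.T


def _drop_collinear(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Drop columns that are numerically linear combinations of earlier ones."""
    _, R, piv = _qr_with_pivoting(X)
    diag = np.abs(np.diag(R))
    keep_rank = int((diag > tol * max(diag[0], 1.0)).sum()) if diag.size else 0
    if keep_rank < X.shape[1]:
        dropped = sorted(piv[keep_rank:].tolist())
        logger.warning(
            "dropping %d collinear regressor column(s): %s", len(dropped), dropped
        )
        keep = sorted(piv[:keep_rank].tolist())
        return X[:, keep]
    return X


def _qr_with_pivoting(X: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


# ---------------------------------------------------------------------------
# composed pipelines
# ---------------------------------------------------------------------------

def preprocess_gbold(
    vol: Volume4D,
    labels: PhantomLabels,
    motion: MotionParams,
    slice_order: np.ndarray | list[int] | None = None,
    band_hz: tuple[float, float] = (0.01, 0.1),
    filter_order: int = 4,
) -> Volume4D:
    """Full nuisance pipeline for the global-BOLD analysis.

    Stage order (recorded in :data:`GBOLD_STAGES`): slice timing ->
    nuisance regression (24 motion regressors + WM mean + CSF mean) ->
    detrend -> band-pass, applied voxel-wise inside the brain mask.
    """
    if not labels.mask("WM").any():
        raise ValueError("labels contain no WM voxels for nuisance extraction")
    if not labels.mask("CSF_bottom").any():
        raise ValueError("labels contain no CSF voxels for nuisance extraction")
    vol = slice_timing_correct(vol, slice_order)
    fs = 1.0 / vol.tr_s

    wm_mean = vol.data[labels.mask("WM")].mean(axis=0)
    csf_mean = vol.data[labels.mask("CSF_bottom")].mean(axis=0)
    X = np.hstack([friston24(motion), wm_mean[:, None], csf_mean[:, None]])

    brain = labels.brain_mask()
    out = np.zeros_like(vol.data, dtype=float)
    series = vol.data[brain]
    series = nuisance_regress(series, X)
    series = detrend(series, axis=-1)
    series = bandpass(series, fs, *band_hz, order=filter_order, axis=-1)
    out[brain] = series
    return Volume4D(out, vol.voxel_size_mm, vol.tr_s)


def preprocess_csf(
    vol: Volume4D,
    slice_order: np.ndarray | list[int] | None = None,
    band_hz: tuple[float, float] = (0.01, 0.1),
    filter_order: int = 4,
) -> Volume4D:
    """Minimal pipeline for the CSF inflow analysis.

    Exactly three stages -- slice timing, detrend, band-pass
    (:data:`CSF_STAGES`). No nuisance regression is applied anywhere on
    this path, so CSF fluctuations survive intact. Each voxel's temporal
    mean is restored after filtering (the usual fMRI-toolbox convention),
    so the downstream fraction-of-mean CSF normalization stays meaningful.
    """
    vol = slice_timing_correct(vol, slice_order)
    fs = 1.0 / vol.tr_s
    mean = vol.data.mean(axis=-1, keepdims=True)
    out = detrend(vol.data, axis=-1)
    out = bandpass(out, fs, *band_hz, order=filter_order, axis=-1)
    out = out + mean
    return Volume4D(out, vol.voxel_size_mm, vol.tr_s)
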