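"""Time-series quality control and denoising for ROI-level resting-state data.

Implements the fixed preprocessing order used throughout the package:

    discard initial volumes -> nuisance regression -> scrubbing -> band-pass

Framewise displacement follows the Power convention: the sum of absolute
backward differences of the six rigid-body parameters, with rotations
converted from radians to millimetres of arc on a sphere (default radius
50 mm).  Scrubbed volumes are censored (deleted), never interpolated, and a
subject is excluded when *more than* a fixed fraction (default 20%) of the
retained volumes is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

DEFAULT_SPHERE_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 0.5
DEFAULT_GLOBAL_SD_THRESHOLD = 2.0
DEFAULT_EXCLUSION_FRACTION = 0.20
DEFAULT_N_DISCARD = 10
DEFAULT_BAND_HZ = (0.01, 0.08)


@dataclass
class QcReport:
    """Per-subject quality-control summary.

    ``fd_series`` has length T-1 (one value per transition); ``scrub_mask``
    has length T with ``True`` marking volumes removed before connectivity.
    ``excluded`` is True when ``n_scrubbed`` exceeds
    ``floor(exclusion_fraction * T)`` strictly.
    """

    fd_series: np.ndarray
    scrub_mask: np.ndarray
    n_scrubbed: int
    excluded: bool
    mean_fd: float
    exclusion_fraction: float = DEFAULT_EXCLUSION_FRACTION


def discard_initial(timeseries: np.ndarray, n_discard: int = DEFAULT_N_DISCARD) -> np.ndarray:
    """Drop the first ``n_discard`` volumes (signal-equilibration frames)."""
    ts = np.asarray(timeseries)
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if ts.shape[0] <= n_discard:
        raise ValueError(
            f"cannot discard {n_discard} volumes from a series of length {ts.shape[0]}"
        )
    return ts[n_discard:]


def framewise_displacement(
    motion: np.ndarray, sphere_radius_mm: float = DEFAULT_SPHERE_RADIUS_MM
) -> np.ndarray:
    """Power-style framewise displacement from a T x 6 motion-parameter matrix.

    Columns 1-3 are translations in mm, columns 4-6 rotations in radians;
    FD_t = sum|Delta translation| + radius * sum|Delta rotation| for each
    backward difference, giving a vector of length T-1.
    """
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion must be a T x 6 matrix")
    if m.shape[0] < 2:
        raise ValueError("need at least two frames to compute FD")
    if not np.all(np.isfinite(m)):
        raise ValueError("motion parameters contain non-finite values")
    d = np.abs(np.diff(m, axis=0))
    return d[:, :3].sum(axis=1) + sphere_radius_mm * d[:, 3:].sum(axis=1)


def scrub(
    timeseries: np.ndarray,
    fd: np.ndarray,
    global_sd_threshold: float = DEFAULT_GLOBAL_SD_THRESHOLD,
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    exclusion_fraction: float = DEFAULT_EXCLUSION_FRACTION,
) -> QcReport:
    """Flag motion- or intensity-corrupted volumes.

    A volume is flagged when the FD of the transition leading into it exceeds
    ``fd_threshold_mm`` (the later frame of a high-FD pair is flagged), or
    when the global mean intensity (mean across ROIs, z-scored over time)
    deviates by more than ``global_sd_threshold`` SDs.
    """
    if fd_threshold_mm <= 0 or global_sd_threshold <= 0:
        raise ValueError("thresholds must be positive")
    ts = np.asarray(timeseries, dtype=float)
    fd = np.asarray(fd, dtype=float)
    t = ts.shape[0]
    if fd.shape[0] != t - 1:
        raise ValueError("fd must have length T-1")

    mask = np.zeros(t, dtype=bool)
    mask[1:] = fd > fd_threshold_mm

    gm = ts.mean(axis=1)
    sd = gm.std(ddof=1) if t > 1 else 0.0
    if sd > 0:
        mask |= np.abs(gm - gm.mean()) / sd > global_sd_threshold

    n_scrubbed = int(mask.sum())
    if n_scrubbed == t:
        raise ValueError("all volumes flagged: degenerate subject")
    excluded = n_scrubbed > int(np.floor(exclusion_fraction * t))
    return QcReport(
        fd_series=fd,
        scrub_mask=mask,
        n_scrubbed=n_scrubbed,
        excluded=excluded,
        mean_fd=float(fd.mean()),
        exclusion_fraction=exclusion_fraction,
    )


def drop_scrubbed(timeseries: np.ndarray, report: QcReport) -> np.ndarray:
    """Censor flagged volumes (no interpolation)."""
    return np.asarray(timeseries)[~report.scrub_mask]


def build_nuisance_regressors(
    motion: np.ndarray, nuisance_signals: np.ndarray | None = None
) -> np.ndarray:
    """Assemble the standard nuisance design: intercept, 6 motion parameters,
    their backward first differences (first row zero), and any extra signal
    columns (white-matter / CSF means)."""
    m = np.asarray(motion, dtype=float)
    t = m.shape[0]
    deriv = np.zeros_like(m)
    deriv[1:] = np.diff(m, axis=0)
    cols = [np.ones((t, 1)), m, deriv]
    if nuisance_signals is not None:
        ns = np.asarray(nuisance_signals, dtype=float)
        if ns.ndim == 1:
            ns = ns[:, None]
        cols.append(ns)
    return np.hstack(cols)


def regress_nuisance(timeseries: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Replace each ROI column by its OLS residual against the regressors.

    Collinear regressor columns are dropped with a warning; residuals are
    orthogonal to every retained regressor column.
    """
    ts = np.asarray(timeseries, dtype=float)
    x = np.asarray(regressors, dtype=float)
    if x.shape[0] != ts.shape[0]:
        raise ValueError("regressors and timeseries must have the same number of rows")
    if x.shape[1] >= x.shape[0]:
        raise ValueError("more regressors than time points")

    q, r, piv = _qr_drop_collinear(x)
    if q.shape[1] < x.shape[1]:
        warnings.warn(
            f"dropped {x.shape[1] - q.shape[1]} collinear nuisance regressor column(s)",
            stacklevel=2,
        )
    return ts - q @ (q.T @ ts)


def _qr_drop_collinear(x: np.ndarray, rtol: float = 1e-10):
    """Pivoted-QR basis of the column space, dropping rank-deficient columns."""
    from scipy.linalg import qr

    q, r, piv = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > rtol * (diag[0] if diag.size else 1.0)))
    return q[:, :rank], r[:rank], piv[:rank]


def bandpass(
    timeseries: np.ndarray,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
    tr_seconds: float = 2.0,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis.

    Defaults pass 0.01-0.08 Hz at TR = 2 s; the band must sit strictly inside
    (0, Nyquist).
    """
    nyq = 0.5 / tr_seconds
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(f"band ({low_hz}, {high_hz}) Hz outside (0, {nyq}) Hz")
    sos = signal.butter(order, [low_hz / nyq, high_hz / nyq], btype="bandpass", output="sos")
    return signal.sosfiltfilt(sos, np.asarray(timeseries, dtype=float), axis=0)


@dataclass
class PreprocessResult:
    timeseries: np.ndarray  # cleaned series (censored rows removed), T' x R
    report: QcReport


def preprocess_subject(
    timeseries: np.ndarray,
    motion: np.ndarray,
    nuisance_signals: np.ndarray | None = None,
    n_discard: int = DEFAULT_N_DISCARD,
    tr_seconds: float = 2.0,
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    global_sd_threshold: float = DEFAULT_GLOBAL_SD_THRESHOLD,
    exclusion_fraction: float = DEFAULT_EXCLUSION_FRACTION,
    sphere_radius_mm: float = DEFAULT_SPHERE_RADIUS_MM,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
) -> PreprocessResult:
    """Full per-subject QC chain in the fixed order.

    Band-pass filtering is applied to the censored residual series treated as
    contiguous; the scrub mask is applied exactly once.
    """
    ts = discard_initial(timeseries, n_discard)
    mo = np.asarray(motion)[n_discard:] if n_discard else np.asarray(motion)
    ns = (
        np.asarray(nuisance_signals)[n_discard:]
        if (nuisance_signals is not None and n_discard)
        else nuisance_signals
    )

    regressors = build_nuisance_regressors(mo, ns)
    resid = regress_nuisance(ts, regressors)

    fd = framewise_displacement(mo, sphere_radius_mm)
    report = scrub(
        resid,
        fd,
        global_sd_threshold=global_sd_threshold,
        fd_threshold_mm=fd_threshold_mm,
        exclusion_fraction=exclusion_fraction,
    )
    clean = drop_scrubbed(resid, report)
    clean = bandpass(clean, band_hz[0], band_hz[1], tr_seconds)
    return PreprocessResult(timeseries=clean, report=report)
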