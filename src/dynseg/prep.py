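"""Formula-level preprocessing of ROI time series.

Task-evoked activity is removed by regressing a Fourier basis of 14
sine-wave regressors spanning 30 s after every trial onset; slow drifts are
removed by a discrete-cosine high-pass basis (128 s cutoff) embedded in the
same GLM; arbitrary confound columns (motion parameters, tissue signals,
their expansions) can be appended. Subjects move on to connectivity
analysis only if fewer than 20% of their scans show frame-wise displacement
above 0.2 mm.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.linalg import qr

from .containers import QCReport, RoiTimeSeries

logger = logging.getLogger(__name__)

__all__ = ["build_fourier_design", "dct_highpass_basis", "regress_confounds",
           "qc_motion_exclude"]


def build_fourier_design(onsets: np.ndarray, tr: float, n_scans: int,
                         n_regressors: int = 14, span_seconds: float = 30.0) -> np.ndarray:
    """Sine-wave task regressors time-locked to trial onsets, plus a constant.

    Column ``j`` (1-based) holds ``sin(pi * j * tau / span)`` at post-onset
    lag ``tau`` seconds, summed over all events whose lag falls in
    ``[0, span)``; the last column is the constant term.
    """
    onsets = np.asarray(onsets, dtype=int)
    if onsets.size == 0:
        raise ValueError("no trial onsets: nothing to regress")
    if onsets.min() < 0 or onsets.max() >= n_scans:
        raise ValueError("onsets must lie within [0, n_scans)")
    if tr <= 0:
        raise ValueError("tr must be positive")
    X = np.zeros((n_scans, n_regressors))
    scans = np.arange(n_scans)
    for onset in onsets:
        tau = (scans - onset) * tr
        sel = (tau >= 0) & (tau < span_seconds)
        for j in range(1, n_regressors + 1):
            X[sel, j - 1] += np.sin(np.pi * j * tau[sel] / span_seconds)
    return np.column_stack([X, np.ones(n_scans)])


def dct_highpass_basis(n_scans: int, tr: float, cutoff_seconds: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift regressors for periods longer than the cutoff."""
    if cutoff_seconds <= 0:
        raise ValueError("cutoff must be positive")
    order = int(np.floor(2.0 * n_scans * tr / cutoff_seconds))
    s = np.arange(n_scans)
    cols = [np.cos(np.pi * k * (2 * s + 1) / (2 * n_scans)) for k in range(1, order + 1)]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


def _drop_collinear(X: np.ndarray) -> np.ndarray:
    """Keep a full-rank column subset (QR with pivoting), warn when dropping."""
    if X.shape[1] == 0:
        return X
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        logger.warning("design rank-deficient: dropping %d collinear column(s)",
                       X.shape[1] - rank)
        keep = np.sort(piv[:rank])
        return X[:, keep]
    return X


def regress_confounds(ts: RoiTimeSeries, design: np.ndarray,
                      confounds: np.ndarray | None = None,
                      highpass_seconds: float | None = 128.0) -> RoiTimeSeries:
    """OLS residuals of every node after projecting out design + drift basis.

    ``design`` carries the task regressors (rows = scans); ``confounds`` is
    an optional scans-by-columns nuisance matrix (the operation is agnostic
    to column meaning). A discrete-cosine high-pass basis up to
    ``highpass_seconds`` is appended unless that is None.
    """
    design = np.asarray(design, float)
    if design.ndim != 2 or design.shape[0] != ts.n_scans:
        raise ValueError("design rows must equal the number of scans")
    blocks = [design]
    if confounds is not None:
        confounds = np.asarray(confounds, float)
        if confounds.shape[0] != ts.n_scans:
            raise ValueError("confound rows must equal the number of scans")
        blocks.append(confounds)
    if highpass_seconds is not None:
        blocks.append(dct_highpass_basis(ts.n_scans, ts.tr_seconds, highpass_seconds))
    X = _drop_collinear(np.column_stack(blocks))
    Y = ts.data.T                                   # scans x nodes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return RoiTimeSeries(ts.subject_id, ts.node_ids, resid.T,
                         tr_seconds=ts.tr_seconds,
                         repetition_onsets=ts.repetition_onsets)


def qc_motion_exclude(fd_trace: np.ndarray, subject_id: str = "",
                      fd_threshold: float = 0.2,
                      max_fraction: float = 0.2) -> QCReport:
    """Exclude a subject when FD exceeds the threshold in more than 20% of scans.

    The inequality is strict: exactly ``max_fraction`` spiking scans is
    still admissible.
    """
    fd = np.asarray(fd_trace, float)
    if fd.size == 0:
        raise ValueError("empty frame-wise displacement trace")
    if (fd < 0).any():
        raise ValueError("frame-wise displacement must be non-negative")
    frac = float((fd > fd_threshold).mean())
    return QCReport(subject_id, fd, frac, excluded=frac > max_fraction)
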