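"""Tapered sliding-window functional connectivity.

A subject's scan axis is divided into 20 windows (non-overlapping, or
half-window overlapping for shorter acquisitions). Within each window,
samples are weighted by an exponential taper

    w_t = w0 * exp((t - T) / theta),   t = 1..T,
    w0  = (1 - exp(-1/theta)) / (1 - exp(-T/theta)),

which sums to 1 exactly (geometric series) and up-weights the window's late
scans, suppressing spurious correlations from distant time points. The
connectivity matrix of a window is the weighted Pearson correlation of every
node pair, Fisher z-transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import RoiTimeSeries

logger = logging.getLogger(__name__)

__all__ = ["WindowPlan", "WindowedFC", "plan_windows", "taper_weights",
           "weighted_correlation", "windowed_fc_stack"]

_R_CLIP = 1.0 - 1e-7  # Fisher z diverges at |r| = 1


@dataclass(frozen=True)
class WindowPlan:
    """Window bounds (``[start, end)`` scan indices) plus taper parameters."""

    n_scans: int
    mode: str
    bounds: tuple[tuple[int, int], ...]
    theta_override: float | None = None

    @property
    def n_windows(self) -> int:
        return len(self.bounds)

    def lengths(self) -> np.ndarray:
        return np.array([e - s for s, e in self.bounds])

    def midpoints(self) -> np.ndarray:
        """Scan index at the centre of each window."""
        return np.array([(s + e) // 2 for s, e in self.bounds])

    def theta(self, length: int) -> float:
        return float(self.theta_override) if self.theta_override is not None else length / 3.0


@dataclass
class WindowedFC:
    """Per-window Fisher-z weighted-correlation matrices for one subject."""

    subject_id: str
    matrices: np.ndarray          # n_windows x nodes x nodes
    plan: WindowPlan
    units: str = "z"
    flagged_nodes: list[tuple[int, int]] = field(default_factory=list)  # (window, node)

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]


def plan_windows(n_scans: int, n_windows: int = 20,
                 mode: str = "non_overlapping",
                 theta_override: float | None = None) -> WindowPlan:
    """Divide ``n_scans`` into exactly ``n_windows`` tapered windows.

    Non-overlapping windows have length ``n_scans // n_windows``, with the
    remainder scans given one each to the earliest windows. Half-overlap
    windows have length ``2 * n_scans // (n_windows + 1)`` and step half a
    window, the last window clamped to the end of the series.
    """
    if n_scans < 2 * n_windows:
        raise ValueError(
            f"need at least {2 * n_windows} scans for {n_windows} windows, got {n_scans}")
    if mode == "non_overlapping":
        base, rem = divmod(n_scans, n_windows)
        bounds = []
        start = 0
        for i in range(n_windows):
            length = base + (1 if i < rem else 0)
            bounds.append((start, start + length))
            start += length
    elif mode == "half_overlap":
        T = (2 * n_scans) // (n_windows + 1)
        step = T // 2
        bounds = []
        for i in range(n_windows):
            start = i * step
            end = min(start + T, n_scans)
            if i == n_windows - 1:
                end = n_scans
            bounds.append((start, end))
    else:
        raise ValueError(f"unknown window mode: {mode!r}")
    return WindowPlan(n_scans, mode, tuple(bounds), theta_override)


def taper_weights(T: int, theta: float | None = None) -> np.ndarray:
    """Exponential taper weights for a window of ``T`` scans.

    ``theta`` defaults to ``T / 3``. The weights increase towards the window
    end and sum to 1 exactly.
    """
    if T < 2:
        raise ValueError("window length must be >= 2")
    theta = T / 3.0 if theta is None else float(theta)
    if theta <= 0:
        raise ValueError("theta must be positive")
    t = np.arange(1, T + 1, dtype=float)
    w0 = (1.0 - np.exp(-1.0 / theta)) / (1.0 - np.exp(-T / theta))
    return w0 * np.exp((t - T) / theta)


def weighted_correlation(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Pearson correlation of two equal-length series.

    Means and (co)variances are weighted by ``w`` (normalized internally).
    Returns NaN, with a log message, if either series has zero weighted
    variance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if not (x.shape == y.shape == w.shape):
        raise ValueError("x, y, w must have equal length")
    w = w / w.sum()
    xm = x - np.sum(w * x)
    ym = y - np.sum(w * y)
    vx = np.sum(w * xm * xm)
    vy = np.sum(w * ym * ym)
    if vx <= 0 or vy <= 0:
        logger.warning("weighted_correlation undefined: zero weighted variance")
        return float("nan")
    r = np.sum(w * xm * ym) / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def _window_matrix(X: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-correlation matrix of ``nodes x T`` data; returns (r, bad-node mask)."""
    w = w / w.sum()
    Xc = X - (X @ w)[:, None]
    Xw = Xc * np.sqrt(w)
    cov = Xw @ Xw.T
    var = np.diag(cov).copy()
    bad = var <= 0
    denom = np.sqrt(np.where(bad, 1.0, var))
    r = cov / denom[:, None] / denom[None, :]
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    np.fill_diagonal(r, 1.0)
    return r, bad


def windowed_fc_stack(ts: RoiTimeSeries, plan: WindowPlan) -> WindowedFC:
    """Fisher-z weighted-correlation matrix for every window of one subject."""
    if plan.n_scans != ts.n_scans:
        raise ValueError("window plan was made for a different number of scans")
    mats = np.empty((plan.n_windows, ts.n_nodes, ts.n_nodes))
    flagged: list[tuple[int, int]] = []
    for wi, (s, e) in enumerate(plan.bounds):
        T = e - s
        w = taper_weights(T, plan.theta(T))
        r, bad = _window_matrix(ts.data[:, s:e], w)
        if bad.any():
            for node in np.flatnonzero(bad):
                flagged.append((wi, int(node)))
            logger.warning("subject %s window %d: %d zero-variance node(s) flagged",
                           ts.subject_id, wi, int(bad.sum()))
        z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
        np.fill_diagonal(z, 0.0)
        mats[wi] = z
    return WindowedFC(ts.subject_id, mats, plan, flagged_nodes=flagged)
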