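"""Drift-diffusion behavior: simulation, closed-form fitting, learning curves.

Two-choice trials are modelled by a drift-diffusion process with drift ``v``
(evidence/s), boundary separation ``a``, relative starting point ``z``
(fraction of ``a``), non-decision time ``t_er`` and unit diffusion scale.
Data are accuracy-coded: absorption at the upper bound ``a`` is a correct
response, at 0 an error.

Parameters are recovered per repetition bin by closed-form moment inversion
(EZ-diffusion style, unit diffusion scale): accuracy plus the mean and
variance of correct response times determine (v, a, t_er). The subject's
learning rate is minus the exponent of a one-term power function
``v = alpha * x**b`` fitted (robustly, least-absolute-residuals by default)
to the drift-by-repetition curve with ``x = log(repetition + 1)``; habit
strength is the compatible-minus-incompatible drift difference in the
post-training test phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = ["DDMParams", "LearningCurve", "simulate_ddm_trials", "ez_fit",
           "drift_curve", "fit_learning_rate", "habit_strength",
           "flag_habit_outliers", "hit_probability"]

_DT = 1e-3       # Euler step (s)
_CUTOFF = 10.0   # trials exceeding this decision time are omissions


@dataclass(frozen=True)
class DDMParams:
    """Drift-diffusion parameters (diffusion scale fixed at 1)."""

    v: float
    a: float
    t_er: float
    z: float = 0.5

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("threshold a must be positive")
        if self.t_er < 0:
            raise ValueError("non-decision time must be non-negative")
        if not 0 < self.z < 1:
            raise ValueError("starting point z must lie in (0, 1)")


@dataclass
class LearningCurve:
    """Estimated drift per repetition bin plus the fitted power law."""

    bin_centers: np.ndarray
    drifts: np.ndarray
    alpha: float = float("nan")
    exponent: float = float("nan")
    learning_rate: float = float("nan")   # = -exponent
    fit_method: str = ""


def hit_probability(params: DDMParams) -> float:
    """Closed-form probability of upper-bound (correct) absorption.

    ``(1 - exp(-2 v z a)) / (1 - exp(-2 v a))`` for unit diffusion scale;
    at z = 0.5 this equals ``1 / (1 + exp(-v a))``.
    """
    v, a, z = params.v, params.a, params.z
    if v == 0:
        return z
    return float((1.0 - np.exp(-2.0 * v * z * a)) / (1.0 - np.exp(-2.0 * v * a)))


def _first_passage(v: np.ndarray, a: float, z: float, rng: np.random.Generator,
                   dt: float = _DT, cutoff: float = _CUTOFF,
                   chunk: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama first-passage times; returns (decision time, upper-hit flag).

    Within-step boundary crossings are detected with the exact Brownian-
    bridge crossing probability, removing the discretization bias of a
    plain endpoint check. Unabsorbed walkers at ``cutoff`` get NaN decision
    times (omissions).
    """
    n = len(v)
    pos = np.full(n, z * a)
    dtime = np.full(n, np.nan)
    upper = np.zeros(n, dtype=bool)
    active = np.arange(n)
    sqdt = np.sqrt(dt)
    steps_done = 0
    max_steps = int(round(cutoff / dt))
    while active.size and steps_done < max_steps:
        m = min(chunk, max_steps - steps_done)
        incr = v[active, None] * dt + sqdt * rng.standard_normal((active.size, m))
        paths = pos[active, None] + np.cumsum(incr, axis=1)
        x0 = np.concatenate([pos[active, None], paths[:, :-1]], axis=1)
        # bridge crossing probability is 1 whenever an endpoint lies outside
        p_up = np.exp(-2.0 * np.clip(a - x0, 0.0, None)
                      * np.clip(a - paths, 0.0, None) / dt)
        p_lo = np.exp(-2.0 * np.clip(x0, 0.0, None)
                      * np.clip(paths, 0.0, None) / dt)
        hit_up = rng.random((active.size, m)) < p_up
        hit_lo = rng.random((active.size, m)) < p_lo
        hit_any = hit_up | hit_lo
        first = np.where(hit_any.any(axis=1), hit_any.argmax(axis=1), -1)
        absorbed = first >= 0
        idx = active[absorbed]
        step_idx = first[absorbed]
        dtime[idx] = (steps_done + step_idx + 1) * dt
        upper[idx] = hit_up[absorbed, step_idx]
        pos[active[~absorbed]] = paths[~absorbed, -1]
        active = active[~absorbed]
        steps_done += m
    return dtime, upper


def simulate_ddm_trials(params: DDMParams, n_trials: int,
                        seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Simulate accuracy-coded trials; omissions (> 10 s) are excluded and logged."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dtime, upper = _first_passage(np.full(n_trials, float(params.v)),
                                  params.a, params.z, rng)
    ok = np.isfinite(dtime)
    if (~ok).any():
        logger.warning("%d trial(s) exceeded the %.0f s cutoff; recorded as omissions",
                       int((~ok).sum()), _CUTOFF)
    return pd.DataFrame({
        "accuracy": upper[ok].astype(int),
        "rt": dtime[ok] + params.t_er,
    })


def ez_fit(trials: pd.DataFrame) -> DDMParams:
    """Closed-form moment inversion from (accuracy, correct-RT mean/variance).

    Requires at least 20 trials. Edge accuracies (0, 0.5, 1) are shifted to
    ``p* = (x + 0.5) / (n + 1)``. Unit diffusion scale.
    """
    n = len(trials)
    if n < 20:
        raise ValueError(f"ez_fit needs >= 20 trials, got {n}")
    acc = trials["accuracy"].to_numpy(float)
    rt = trials["rt"].to_numpy(float)
    x = acc.sum()
    p = x / n
    if p in (0.0, 0.5, 1.0):
        p = (x + 0.5) / (n + 1)
    # correct-RT moments; for below-chance subsets use the (recoded) error RTs
    sel = acc == 1 if p > 0.5 else acc == 0
    mrt = rt[sel].mean()
    vrt = rt[sel].var(ddof=1)
    if not np.isfinite(vrt) or vrt <= 0:
        logger.warning("ez_fit: degenerate RT variance; parameters flagged missing")
        return DDMParams(float("nan"), 1.0, 0.0)
    L = np.log(p / (1.0 - p))
    x4 = L * (L * p**2 - L * p + p - 0.5) / vrt
    v = float(np.sign(p - 0.5) * x4**0.25)
    a = float(L / v)
    y = -v * a
    mdt = (a / (2.0 * v)) * (1.0 - np.exp(y)) / (1.0 + np.exp(y))
    t_er = float(mrt - mdt)
    return DDMParams(v, a, max(t_er, 0.0))


def drift_curve(trials: pd.DataFrame, bin_width: int = 7,
                min_trials_per_bin: int = 20,
                n_repetitions: int = 98) -> LearningCurve:
    """Estimate drift per repetition bin, pooling trials across stimuli.

    ``trials`` must carry ``repetition``, ``accuracy`` and ``rt`` columns
    (phase-2 learning trials). Bins with fewer than ``min_trials_per_bin``
    trials are dropped with a warning.
    """
    reps = trials["repetition"].to_numpy(int)
    present = np.unique(reps)
    expected = np.arange(1, n_repetitions + 1)
    gaps = np.setdiff1d(expected, present)
    if gaps.size:
        logger.warning("missing repetitions (tolerated): %s ...", gaps[:5])
    edges = np.arange(1, n_repetitions + 1 + bin_width, bin_width)
    centers, drifts = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (reps >= lo) & (reps < hi)
        if sel.sum() < min_trials_per_bin:
            logger.warning("bin [%d, %d) has %d trials (< %d); dropped",
                           lo, hi, int(sel.sum()), min_trials_per_bin)
            continue
        params = ez_fit(trials.loc[sel])
        centers.append(reps[sel].mean())
        drifts.append(params.v)
    return LearningCurve(np.asarray(centers), np.asarray(drifts))


def _power_fit(x: np.ndarray, y: np.ndarray, robust: bool) -> tuple[float, float]:
    """Fit ``y = alpha * x**b``; robust = iteratively reweighted L1 (LAR)."""
    pos = (y > 0) & (x > 0)
    if pos.sum() >= 2:
        b0, loga = np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)
        p0 = np.array([np.exp(loga), b0])
    else:
        p0 = np.array([max(y.mean(), 0.1), 0.1])

    def resid(p: np.ndarray, w: np.ndarray) -> np.ndarray:
        return w * (p[0] * x ** p[1] - y)

    w = np.ones_like(y)
    sol = least_squares(resid, p0, args=(w,), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if robust:
        for _ in range(30):
            r = sol.x[0] * x ** sol.x[1] - y
            w_new = 1.0 / np.sqrt(np.maximum(np.abs(r), 1e-8))
            sol_new = least_squares(resid, sol.x, args=(w_new,),
                                    xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if np.allclose(sol_new.x, sol.x, rtol=1e-10, atol=1e-12):
                sol = sol_new
                break
            sol = sol_new
    if not sol.success:
        logger.warning("power fit did not converge; falling back to log-log least squares")
        b, loga = np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)
        return float(np.exp(loga)), float(b)
    return float(sol.x[0]), float(sol.x[1])


def fit_learning_rate(curve: LearningCurve, method: str = "lar") -> float:
    """Learning rate = minus the power-law exponent of the drift curve.

    The independent variable is ``x = log(k + 1)`` for bin-centre repetition
    ``k``; ``method`` is ``"lar"`` (least absolute residuals via IRLS) or
    ``"ls"``. The fitted parameters are stored on ``curve``.
    """
    if len(curve.drifts) < 3:
        raise ValueError("learning-rate fit needs at least 3 curve points")
    if method not in ("lar", "ls"):
        raise ValueError("method must be 'lar' or 'ls'")
    x = np.log(curve.bin_centers + 1.0)
    alpha, b = _power_fit(x, curve.drifts, robust=(method == "lar"))
    curve.alpha, curve.exponent = alpha, b
    curve.learning_rate = -b
    curve.fit_method = method
    return -b


def habit_strength(trials: pd.DataFrame) -> float:
    """Compatible-minus-incompatible drift difference in the phase-3 test.

    ``trials`` must carry a ``condition`` column with both ``compatible``
    and ``incompatible`` rows. A condition with fewer than 20 trials is
    flagged missing (NaN).
    """
    out = {}
    for cond in ("compatible", "incompatible"):
        sub = trials[trials["condition"] == cond]
        if len(sub) == 0:
            raise ValueError(f"condition {cond!r} missing from trial table")
        if len(sub) < 20:
            logger.warning("condition %s has %d trials (< 20); habit flagged missing",
                           cond, len(sub))
            return float("nan")
        out[cond] = ez_fit(sub).v
    return float(out["compatible"] - out["incompatible"])


def flag_habit_outliers(values: np.ndarray | pd.Series) -> np.ndarray:
    """Cohort-level 3-standard-deviation outlier flag for habit strength."""
    v = np.asarray(values, float)
    mu, sd = np.nanmean(v), np.nanstd(v)
    if sd == 0:
        return np.zeros(len(v), dtype=bool)
    return np.abs(v - mu) > 3.0 * sd
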