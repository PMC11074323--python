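"""Synthetic cohort with known ground truth.

Each subject's ROI time series switches between two latent covariance
states: an *integrated* state (moderate within-network correlation, positive
between-network correlation) and a *segregated* state (strong within-network
correlation, near-zero/negative between-network correlation). The
probability of occupying the segregated state rises along a logistic in
scan time with a subject-specific transition rate, emulating the shift from
an integrated towards a segregated brain state across learning.

Behavior is generated from a drift-diffusion forward model whose drift
rises with stimulus repetition along a one-term power law in
``x = log(repetition + 1)`` — exactly the model family the fitter assumes —
with subject exponent ``b``. The subject's true learning rate is ``-b``.
Across subjects, (transition rate, learning rate) are drawn with correlation
``coupling_rho``, while the true habit effect (compatible - incompatible
drift in the test phase) is coupled with correlation ``habit_rho``
(default 0), so both the positive and the null cohort-level finding have a
known ground truth.

All distributional choices are synthetic stand-ins: the acquisition process
of real task fMRI (hemodynamics, scanner noise spectra, motion) is not
modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import CohortConfig
from .containers import NetworkAtlas, RoiTimeSeries
from .windows import plan_windows

logger = logging.getLogger(__name__)

__all__ = ["SyntheticCohort", "make_atlas", "draw_subject_parameters",
           "build_state_covariances", "simulate_subject",
           "simulate_behavior_cohort", "simulate_cohort", "write_cohort"]

_NETWORK_NAMES = ("DMN", "FPN", "CON", "SMN", "VIS", "AUD", "DAN", "VAN", "SN", "SUB")


@dataclass
class SyntheticCohort:
    """Everything the generator knows: data plus ground truth."""

    config: CohortConfig
    atlas: NetworkAtlas
    ground_truth: pd.DataFrame
    timeseries: list[RoiTimeSeries]
    state_sequences: dict[str, np.ndarray]   # per-segment state (0=integrated, 1=segregated)
    segment_bounds: tuple[tuple[int, int], ...]
    trials: pd.DataFrame
    cov_integrated: np.ndarray
    cov_segregated: np.ndarray


def make_atlas(n_nodes: int, n_networks: int) -> NetworkAtlas:
    """Contiguous near-equal-size network assignment with canonical names."""
    if n_networks > len(_NETWORK_NAMES):
        names = tuple(f"NET{i + 1:02d}" for i in range(n_networks))
    else:
        names = _NETWORK_NAMES[:n_networks]
    edges = np.linspace(0, n_nodes, n_networks + 1).astype(int)
    node_ids = tuple(f"node{i + 1:03d}" for i in range(n_nodes))
    mapping = {}
    for k, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        for i in range(lo, hi):
            mapping[node_ids[i]] = names[k]
    return NetworkAtlas(node_ids, mapping)


def draw_subject_parameters(config: CohortConfig,
                            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-subject ground-truth parameters.

    (transition_rate, learning_rate) come from a bivariate normal with
    correlation ``coupling_rho``; the habit effect is drawn with correlation
    ``habit_rho`` to both. The drift power-law exponent is
    ``b = -learning_rate`` (floored at 0.05 so the drift curve rises).
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_subjects
    rho_c, rho_h = config.coupling_rho, config.habit_rho
    corr = np.array([[1.0, rho_c, rho_h],
                     [rho_c, 1.0, rho_h],
                     [rho_h, rho_h, 1.0]])
    # guard the joint correlation structure itself
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValueError("coupling_rho/habit_rho do not form a valid correlation matrix")
    cols = ["transition_rate", "learning_rate", "habit_effect"]
    if n == 0:
        gt = pd.DataFrame(columns=["subject_id", *cols, "learning_exponent",
                                   "ddm_a", "ddm_ter", "ddm_z"])
        return gt
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(3))
    z = rng.standard_normal((n, 3)) @ L.T
    transition = np.maximum(config.transition_rate_mean
                            + config.transition_rate_sd * z[:, 0], 0.5)
    learning_rate = config.learning_rate_mean + config.learning_rate_sd * z[:, 1]
    habit = config.habit_mean + config.habit_sd * z[:, 2]
    b = np.maximum(-learning_rate, 0.05)
    a = np.maximum(config.ddm_a_mean + config.ddm_a_sd * rng.standard_normal(n), 0.4)
    t_er = np.maximum(config.ddm_ter_mean + config.ddm_ter_sd * rng.standard_normal(n), 0.05)
    return pd.DataFrame({
        "subject_id": [f"sub{i + 1:03d}" for i in range(n)],
        "transition_rate": transition,
        "learning_rate": learning_rate,
        "habit_effect": habit,
        "learning_exponent": b,
        "ddm_a": a,
        "ddm_ter": t_er,
        "ddm_z": config.ddm_z,
    })


def _block_correlation(labels: np.ndarray, within_r: float, between_r: float) -> np.ndarray:
    same = labels[:, None] == labels[None, :]
    C = np.where(same, within_r, between_r)
    np.fill_diagonal(C, 1.0)
    return C


def _nearest_psd(C: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue clipping, then rescaling back to a unit diagonal."""
    vals, vecs = np.linalg.eigh(C)
    if vals.min() >= floor:
        return C
    vals = np.maximum(vals, floor)
    A = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(A))
    if np.any(d <= 0) or not np.all(np.isfinite(A)):
        raise FloatingPointError(f"PSD repair failed for matrix:\n{C}")
    return A / np.outer(d, d)


def build_state_covariances(atlas: NetworkAtlas,
                            config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Block-structured correlation matrices for the two latent states."""
    labels = atlas.labels()
    cov_int = _nearest_psd(_block_correlation(
        labels, config.within_r_integrated, config.between_r_integrated))
    cov_seg = _nearest_psd(_block_correlation(
        labels, config.within_r_segregated, config.between_r_segregated))
    return cov_int, cov_seg


def _even_onsets(n_trials: int, n_scans: int) -> np.ndarray:
    return (np.arange(n_trials) * n_scans // max(n_trials, 1)).astype(int)


def simulate_subject(gt_row: pd.Series, cov_int: np.ndarray, cov_seg: np.ndarray,
                     config: CohortConfig,
                     rng: np.random.Generator) -> tuple[RoiTimeSeries, np.ndarray]:
    """State-switching multivariate time series for one subject.

    Scans are partitioned into ``config.n_segments`` segments; each segment
    occupies the segregated state with probability
    ``logistic(rate * (mid / n_scans - midpoint))`` evaluated at the segment
    midpoint. Returns the series and the per-segment state sequence
    (0 = integrated, 1 = segregated).
    """
    plan = plan_windows(config.scans_per_subject, config.n_segments, "non_overlapping")
    L_int = np.linalg.cholesky(cov_int + 1e-10 * np.eye(len(cov_int)))
    L_seg = np.linalg.cholesky(cov_seg + 1e-10 * np.eye(len(cov_seg)))
    n_nodes = cov_int.shape[0]
    data = np.empty((n_nodes, config.scans_per_subject))
    states = np.empty(plan.n_windows, dtype=int)
    rate = float(gt_row["transition_rate"])
    for si, (s, e) in enumerate(plan.bounds):
        mid = (s + e) / 2.0
        p_seg = expit(rate * (mid / config.scans_per_subject - config.transition_midpoint))
        state = int(rng.random() < p_seg)
        states[si] = state
        L = L_seg if state else L_int
        latent = L @ rng.standard_normal((n_nodes, e - s))
        data[:, s:e] = latent + config.noise_sd * rng.standard_normal((n_nodes, e - s))
    onsets = _even_onsets(config.trials_per_subject, config.scans_per_subject)
    ts = RoiTimeSeries(str(gt_row["subject_id"]),
                       tuple(f"node{i + 1:03d}" for i in range(n_nodes)),
                       data, tr_seconds=config.tr_seconds, repetition_onsets=onsets)
    return ts, states


def drift_schedule(b: float, config: CohortConfig) -> np.ndarray:
    """True drift for repetitions 1..n: ``v_max * min(1, alpha * log(k+1)**b)``."""
    k = np.arange(1, config.n_repetitions + 1)
    x = np.log(k + 1.0)
    return config.drift_vmax * np.minimum(1.0, config.drift_alpha * x**b)


def _simulate_trial_block(v: np.ndarray, a: float, z: float, t_er: float,
                          rng: np.random.Generator) -> pd.DataFrame:
    from .behavior import _first_passage
    dtime, upper = _first_passage(v, a, z, rng)
    ok = np.isfinite(dtime)
    if (~ok).any():
        logger.warning("%d omission trial(s) dropped", int((~ok).sum()))
    return pd.DataFrame({"index": np.flatnonzero(ok),
                         "accuracy": upper[ok].astype(int),
                         "rt": dtime[ok] + t_er})


def simulate_behavior_cohort(ground_truth: pd.DataFrame, config: CohortConfig,
                             rng: np.random.Generator | None = None) -> pd.DataFrame:
    """DDM trial table for the whole cohort (phase-2 learning + phase-3 test)."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n_stimuli = max(config.trials_per_subject // config.n_repetitions, 1)
    frames = []
    for _, row in ground_truth.iterrows():
        a, t_er, z = float(row["ddm_a"]), float(row["ddm_ter"]), float(row["ddm_z"])
        if a <= 0 or t_er <= 0:
            raise ValueError("non-positive DDM baseline (a, t_er) in ground truth")
        v_by_rep = drift_schedule(float(row["learning_exponent"]), config)
        # phase 2: n_stimuli trials at every repetition
        reps = np.repeat(np.arange(1, config.n_repetitions + 1), n_stimuli)
        stims = np.tile(np.arange(1, n_stimuli + 1), config.n_repetitions)
        conds = np.where(stims <= n_stimuli // 2, "approach", "avoidance")
        if n_stimuli == 1:
            conds = np.full_like(stims, "approach", dtype=object)
        sim = _simulate_trial_block(v_by_rep[reps - 1], a, z, t_er, rng)
        idx = sim["index"].to_numpy()
        frames.append(pd.DataFrame({
            "subject_id": row["subject_id"], "phase": 2,
            "stimulus": stims[idx], "repetition": reps[idx],
            "condition": conds[idx], "response": sim["accuracy"],
            "accuracy": sim["accuracy"], "rt_seconds": sim["rt"],
        }))
        # phase 3: compatible vs incompatible around the end-of-learning drift
        v_base = v_by_rep[-1]
        habit = float(row["habit_effect"])
        m = config.phase3_trials_per_condition
        v3 = np.concatenate([np.full(m, v_base + habit / 2.0),
                             np.full(m, v_base - habit / 2.0)])
        cond3 = np.array(["compatible"] * m + ["incompatible"] * m, dtype=object)
        sim3 = _simulate_trial_block(v3, a, z, t_er, rng)
        idx3 = sim3["index"].to_numpy()
        frames.append(pd.DataFrame({
            "subject_id": row["subject_id"], "phase": 3,
            "stimulus": 0, "repetition": 0,
            "condition": cond3[idx3], "response": sim3["accuracy"],
            "accuracy": sim3["accuracy"], "rt_seconds": sim3["rt"],
        }))
    if not frames:
        return pd.DataFrame(columns=["subject_id", "phase", "stimulus", "repetition",
                                     "condition", "response", "accuracy", "rt_seconds"])
    return pd.concat(frames, ignore_index=True)


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full cohort: atlas, parameters, time series, trials."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_params, ss_ts, ss_beh = root.spawn(3)
    atlas = make_atlas(config.n_nodes, config.n_networks)
    gt = draw_subject_parameters(config, np.random.default_rng(ss_params))
    cov_int, cov_seg = build_state_covariances(atlas, config)
    ts_seeds = ss_ts.spawn(max(config.n_subjects, 1))
    series, states = [], {}
    plan = plan_windows(config.scans_per_subject, config.n_segments, "non_overlapping")
    for i, (_, row) in enumerate(gt.iterrows()):
        ts, st = simulate_subject(row, cov_int, cov_seg, config,
                                  np.random.default_rng(ts_seeds[i]))
        series.append(ts)
        states[str(row["subject_id"])] = st
    trials = simulate_behavior_cohort(gt, config, np.random.default_rng(ss_beh))
    return SyntheticCohort(config, atlas, gt, series, states, plan.bounds,
                           trials, cov_int, cov_seg)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write the cohort as delimited text files (bit-identical per seed)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.atlas.write(out / "atlas.tsv")
    cohort.ground_truth.to_csv(out / "ground_truth.csv", index=False,
                               float_format="%.10g")
    cohort.trials.to_csv(out / "trials.csv", index=False, float_format="%.10g")
    ts_dir = out / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    for ts in cohort.timeseries:
        ts.write(ts_dir / f"{ts.subject_id}.tsv")
    seq = pd.DataFrame(
        [(sid, si, int(s)) for sid, st in cohort.state_sequences.items()
         for si, s in enumerate(st)],
        columns=["subject_id", "segment", "state"])
    seq.to_csv(out / "state_sequence.csv", index=False)
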