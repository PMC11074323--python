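"""Subject trajectory features, cohort statistics, and the end-to-end pipeline.

Each subject's 20 per-window modularity-Q values are reduced to a slope on
the logarithm of the cumulative trial count at each window midpoint (the
segregation transition rate) and an early-segregation level (mean Q over
windows 1-3). The cohort battery then mirrors the study's statistics: a
one-sample t test on the Q slopes, Pearson correlations of Q slope and
early Q with learning rate and habit strength, a paired t test of
compatible vs incompatible drift, a learning-rate median split with group
mean Q curves, and per-network one-sample t tests on PC/MDZ slopes with
Bonferroni family-wise-error correction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__ as _pkg_version
from .behavior import drift_curve, fit_learning_rate, flag_habit_outliers, habit_strength
from .config import PipelineConfig
from .containers import NetworkAtlas
from .graph import consensus_partition, louvain_signed, network_summarize, node_cartography
from .prep import build_fourier_design, regress_confounds
from .states import StatePrevalence, cluster_states, label_and_prevalence
from .synthetic import SyntheticCohort, simulate_cohort, write_cohort
from .windows import WindowPlan, plan_windows, windowed_fc_stack

logger = logging.getLogger(__name__)

__all__ = ["StudyResult", "window_trial_counts", "trajectory_features",
           "compute_windowed_fc", "modularity_trajectories", "behavioral_summaries",
           "cohort_statistics", "cartography_profile", "welch_between",
           "run_study", "run_pipeline"]


@dataclass
class StudyResult:
    """All artifacts of one end-to-end study run."""

    config: PipelineConfig
    cohort: SyntheticCohort
    q_table: pd.DataFrame                      # subject_id, window, q
    network_slopes: pd.DataFrame               # subject_id, network, pc_slope, mdz_slope
    summaries: pd.DataFrame                    # one row per subject
    prevalence: StatePrevalence | None
    report: dict = field(default_factory=dict)


def window_trial_counts(plan: WindowPlan, onsets: np.ndarray) -> np.ndarray:
    """Cumulative number of trials whose onset precedes each window midpoint."""
    onsets = np.sort(np.asarray(onsets, int))
    counts = np.searchsorted(onsets, plan.midpoints(), side="right")
    if (counts <= 0).any():
        raise ValueError("a window midpoint precedes the first trial onset")
    return counts


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))


def trajectory_features(q_by_window: np.ndarray,
                        trial_counts: np.ndarray) -> tuple[float, float]:
    """(slope of Q on log trial count, mean Q over windows 1-3)."""
    q = np.asarray(q_by_window, float)
    counts = np.asarray(trial_counts, float)
    if len(q) < 4:
        raise ValueError("need at least 4 windows")
    missing = np.flatnonzero(~np.isfinite(q))
    if missing.size:
        raise ValueError(f"missing Q values in windows {missing.tolist()}")
    slope = _ols_slope(np.log(counts), q)
    return slope, float(q[:3].mean())


def compute_windowed_fc(cohort: SyntheticCohort, config: PipelineConfig) -> list:
    """Preprocess every subject (task + drift regression) and window the FC."""
    stacks = []
    for ts in cohort.timeseries:
        design = build_fourier_design(ts.repetition_onsets, ts.tr_seconds, ts.n_scans)
        resid = regress_confounds(ts, design, highpass_seconds=config.highpass_seconds)
        plan = plan_windows(resid.n_scans, config.windows.n_windows,
                            config.windows.mode, config.windows.theta_override)
        stacks.append(windowed_fc_stack(resid, plan))
    return stacks


def modularity_trajectories(stacks: list, atlas: NetworkAtlas,
                            config: PipelineConfig,
                            seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-window Q and per-network PC/MDZ for every subject.

    Returns ``(q_table, cartography_table)`` with one row per
    (subject, window) and (subject, window, network) respectively.
    """
    mcfg = config.modularity
    rng = np.random.default_rng(seed)
    q_rows, carto_rows = [], []
    for fc in stacks:
        for wi in range(fc.n_windows):
            W = fc.matrices[wi].copy()
            np.fill_diagonal(W, 0.0)
            if mcfg.consensus:
                part = consensus_partition(W, n_runs=mcfg.n_runs, tau=mcfg.tau,
                                           gamma=mcfg.gamma, seed=rng)
            else:
                part = None
                for _ in range(mcfg.n_runs):
                    cand = louvain_signed(W, mcfg.gamma, rng)
                    if part is None or cand.q > part.q:
                        part = cand
            q_rows.append((fc.subject_id, wi, part.q))
            carto = node_cartography(W, part)
            net = network_summarize(carto, atlas)
            for _, r in net.iterrows():
                carto_rows.append((fc.subject_id, wi, r["network"],
                                   r["mean_pc"], r["mean_mdz"]))
    q_table = pd.DataFrame(q_rows, columns=["subject_id", "window", "q"])
    carto_table = pd.DataFrame(
        carto_rows, columns=["subject_id", "window", "network", "mean_pc", "mean_mdz"])
    return q_table, carto_table


def _network_slopes(carto_table: pd.DataFrame, log_counts: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for (sid, net), grp in carto_table.groupby(["subject_id", "network"], sort=False):
        grp = grp.sort_values("window")
        x = log_counts[sid]
        rows.append((sid, net,
                     _ols_slope(x, grp["mean_pc"].to_numpy()),
                     _ols_slope(x, grp["mean_mdz"].to_numpy())))
    return pd.DataFrame(rows, columns=["subject_id", "network", "pc_slope", "mdz_slope"])


def behavioral_summaries(trials: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Learning rate and habit strength per subject from the trial table."""
    bcfg = config.behavior
    rows = []
    for sid, grp in trials.groupby("subject_id", sort=False):
        p2 = grp[grp["phase"] == 2].rename(columns={"rt_seconds": "rt"})
        curve = drift_curve(p2, bin_width=bcfg.bin_width,
                            min_trials_per_bin=bcfg.min_trials_per_bin)
        lr = fit_learning_rate(curve, method=bcfg.fit_method)
        p3 = grp[grp["phase"] == 3].rename(columns={"rt_seconds": "rt"})
        habit = habit_strength(p3)
        from .behavior import ez_fit
        v_comp = ez_fit(p3[p3["condition"] == "compatible"]).v
        v_incomp = ez_fit(p3[p3["condition"] == "incompatible"]).v
        rows.append((sid, lr, habit, v_comp, v_incomp))
    df = pd.DataFrame(rows, columns=["subject_id", "learning_rate", "habit_strength",
                                     "v_compatible", "v_incompatible"])
    df["habit_outlier"] = flag_habit_outliers(df["habit_strength"])
    return df


def _pearson(x: pd.Series, y: pd.Series, alternative: str = "two-sided") -> dict:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        logger.warning("correlation flagged: degenerate input")
        return {"r": float("nan"), "p": float("nan"), "n": int(ok.sum())}
    res = stats.pearsonr(x[ok], y[ok], alternative=alternative)
    return {"r": float(res.statistic), "p": float(res.pvalue), "n": int(ok.sum())}


def cohort_statistics(summaries: pd.DataFrame, q_table: pd.DataFrame,
                      network_slopes: pd.DataFrame,
                      include_behavior: bool = True) -> dict:
    """The cohort-level battery; excludes flagged habit outliers first."""
    retained = summaries[~summaries.get("habit_outlier", False)].copy() \
        if include_behavior and "habit_outlier" in summaries else summaries.copy()
    if len(retained) < 5:
        raise ValueError("need at least 5 subjects after exclusions")
    report: dict = {"n_subjects": int(len(retained)),
                    "excluded_habit_outliers":
                        int(len(summaries) - len(retained))}
    t, p = stats.ttest_1samp(retained["q_slope"], 0.0)
    report["q_slope"] = {"mean": float(retained["q_slope"].mean()),
                        "t": float(t), "p": float(p), "df": int(len(retained) - 1)}
    if include_behavior:
        report["r_q_slope_learning_rate"] = _pearson(
            retained["q_slope"], retained["learning_rate"])
        report["r_q_slope_habit"] = _pearson(
            retained["q_slope"], retained["habit_strength"])
        report["r_early_q_learning_rate"] = _pearson(
            retained["early_q"], retained["learning_rate"], alternative="greater")
        report["r_early_q_habit"] = _pearson(
            retained["early_q"], retained["habit_strength"])
        report["r_learning_rate_habit"] = _pearson(
            retained["learning_rate"], retained["habit_strength"])
        tt = stats.ttest_rel(retained["v_compatible"], retained["v_incompatible"])
        report["paired_t_compatible_incompatible"] = {
            "t": float(tt.statistic), "p": float(tt.pvalue),
            "df": int(len(retained) - 1),
            "mean_compatible": float(retained["v_compatible"].mean()),
            "mean_incompatible": float(retained["v_incompatible"].mean())}
        # median split by learning rate: group sizes differ by at most one
        order = retained.sort_values("learning_rate", kind="mergesort")
        half = len(order) // 2
        slow = order.iloc[:half]["subject_id"]
        fast = order.iloc[half:]["subject_id"]
        qt = q_table[q_table["subject_id"].isin(retained["subject_id"])]
        curves = {}
        for name, ids in (("slow_learners", slow), ("fast_learners", fast)):
            sub = qt[qt["subject_id"].isin(ids)]
            curves[name] = sub.groupby("window")["q"].mean().tolist()
        report["median_split_mean_q"] = curves
    # per-network one-sample t tests on cartography slopes, Bonferroni FWE
    nets = list(dict.fromkeys(network_slopes["network"]))
    m = 2 * len(nets)
    per_net = {}
    ns = network_slopes[network_slopes["subject_id"].isin(retained["subject_id"])]
    for net in nets:
        grp = ns[ns["network"] == net]
        entry = {}
        for metric in ("pc_slope", "mdz_slope"):
            vals = grp[metric].to_numpy(float)
            if len(vals) < 2 or np.std(vals) == 0:
                if np.allclose(vals, 0.0):
                    entry[metric] = {"mean": 0.0, "t": 0.0, "p": 1.0, "p_fwe": 1.0}
                else:
                    entry[metric] = {"mean": float(np.mean(vals)), "t": float("nan"),
                                     "p": float("nan"), "p_fwe": float("nan")}
                continue
            t, p = stats.ttest_1samp(vals, 0.0)
            entry[metric] = {"mean": float(np.mean(vals)), "t": float(t),
                             "p": float(p), "p_fwe": float(min(1.0, m * p))}
        per_net[net] = entry
    report["network_slope_tests"] = per_net
    return report


def cartography_profile(network_slopes: pd.DataFrame) -> pd.DataFrame:
    """Two-dimensional (PC slope, MDZ slope) profile per network with FWE t tests."""
    nets = list(dict.fromkeys(network_slopes["network"]))
    m = 2 * len(nets)
    rows = []
    for net in nets:
        grp = network_slopes[network_slopes["network"] == net]
        row: dict = {"network": net}
        for metric, short in (("pc_slope", "pc"), ("mdz_slope", "mdz")):
            vals = grp[metric].to_numpy(float)
            row[f"mean_{short}_slope"] = float(np.mean(vals))
            if len(vals) < 2:
                logger.warning("single-subject cohort: t undefined for %s", net)
                row[f"t_{short}"] = float("nan")
                row[f"p_fwe_{short}"] = float("nan")
            elif np.std(vals) == 0:
                row[f"t_{short}"] = 0.0 if np.allclose(vals, 0.0) else float("nan")
                row[f"p_fwe_{short}"] = 1.0 if np.allclose(vals, 0.0) else float("nan")
            else:
                t, p = stats.ttest_1samp(vals, 0.0)
                row[f"t_{short}"] = float(t)
                row[f"p_fwe_{short}"] = float(min(1.0, m * p))
        rows.append(row)
    return pd.DataFrame(rows)


def welch_between(summaries_a: pd.DataFrame, summaries_b: pd.DataFrame,
                  column: str) -> dict:
    """Welch's t test of one summary column between two cohorts."""
    t, p = stats.ttest_ind(summaries_a[column], summaries_b[column], equal_var=False)
    return {"t": float(t), "p": float(p)}


def run_study(config: PipelineConfig) -> StudyResult:
    """Simulate a cohort and run every stage in memory."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    seeds = root.generate_state(4) % (2**31)
    cohort = simulate_cohort(config.cohort)
    stacks = compute_windowed_fc(cohort, config)
    prevalence = None
    if not config.skip_states and stacks:
        model = cluster_states(stacks, k=config.states.k,
                               replicates=config.states.replicates,
                               seed=int(seeds[0]))
        prevalence = label_and_prevalence(model, cohort.atlas)
    q_table, carto_table = modularity_trajectories(
        stacks, cohort.atlas, config, seed=int(seeds[1]))
    log_counts = {}
    for ts in cohort.timeseries:
        plan = plan_windows(ts.n_scans, config.windows.n_windows, config.windows.mode)
        log_counts[ts.subject_id] = np.log(
            window_trial_counts(plan, ts.repetition_onsets).astype(float))
    feats = []
    for sid, grp in q_table.groupby("subject_id", sort=False):
        q = grp.sort_values("window")["q"].to_numpy()
        slope, early = trajectory_features(q, np.exp(log_counts[sid]))
        feats.append((sid, slope, early))
    summaries = pd.DataFrame(feats, columns=["subject_id", "q_slope", "early_q"])
    network_slopes = _network_slopes(carto_table, log_counts)
    if not config.skip_behavior:
        beh = behavioral_summaries(cohort.trials, config)
        summaries = summaries.merge(beh, on="subject_id")
    report = cohort_statistics(summaries, q_table, network_slopes,
                               include_behavior=not config.skip_behavior)
    if prevalence is not None:
        report["centroid_segregation"] = {
            prevalence.state_labels[c]: float(v)
            for c, v in prevalence.centroid_segregation.items()}
        seg = prevalence.prevalence["segregated"].to_numpy()
        rho, p = stats.spearmanr(np.arange(len(seg)), seg)
        report["segregated_prevalence_trend"] = {"spearman_rho": float(rho),
                                                 "p": float(p)}
    return StudyResult(config, cohort, q_table, network_slopes, summaries,
                       prevalence, report)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> StudyResult:
    """Run the study and write all tables, the JSON report, and a log."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result = run_study(config)
    write_cohort(result.cohort, out / "cohort")
    result.q_table.to_csv(out / "q_by_window.csv", index=False, float_format="%.10g")
    result.summaries.to_csv(out / "subject_summaries.csv", index=False,
                            float_format="%.10g")
    result.network_slopes.to_csv(out / "network_slopes.csv", index=False,
                                 float_format="%.10g")
    cartography_profile(result.network_slopes).to_csv(
        out / "cartography_profile.csv", index=False, float_format="%.10g")
    if result.prevalence is not None:
        result.prevalence.prevalence.to_csv(out / "state_prevalence.csv",
                                            index=False, float_format="%.10g")
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True, allow_nan=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"dynseg version: {_pkg_version}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"subjects: {config.cohort.n_subjects}\n")
        fh.write(f"nodes: {config.cohort.n_nodes}\n")
        fh.write(f"scans: {config.cohort.scans_per_subject}\n")
        fh.write(f"windows: {config.windows.n_windows} ({config.windows.mode})\n")
    return result
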