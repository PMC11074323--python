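"""DDM simulation, EZ-style closed-form fitting, learning curves, habit."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from dynseg.behavior import (DDMParams, LearningCurve, drift_curve, ez_fit,
                             fit_learning_rate, flag_habit_outliers,
                             habit_strength, hit_probability,
                             simulate_ddm_trials)
from dynseg.config import CohortConfig
from dynseg.synthetic import drift_schedule


class TestSimulateDdm:
    def test_drift_dominated_limit(self):
        t = simulate_ddm_trials(DDMParams(50.0, 1.2, 0.3), 200, seed=0)
        assert t.accuracy.mean() > 0.99
        assert t.rt.mean() == pytest.approx(0.3, abs=0.05)

    def test_symmetric_random_walk(self):
        t = simulate_ddm_trials(DDMParams(0.0, 1.2, 0.3), 10000, seed=1)
        assert t.accuracy.mean() == pytest.approx(0.5, abs=0.02)

    def test_hit_probability_closed_form(self):
        p = DDMParams(1.5, 1.2, 0.3)
        t = simulate_ddm_trials(p, 10000, seed=2)
        assert t.accuracy.mean() == pytest.approx(hit_probability(p), rel=0.01)

    def test_biased_start_hit_probability(self):
        p = DDMParams(0.8, 1.5, 0.2, z=0.3)
        t = simulate_ddm_trials(p, 20000, seed=3)
        assert t.accuracy.mean() == pytest.approx(hit_probability(p), abs=0.015)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DDMParams(1.0, -1.0, 0.3)
        with pytest.raises(ValueError):
            DDMParams(1.0, 1.0, -0.1)


class TestEzFit:
    def test_parameter_recovery(self):
        true = DDMParams(1.5, 1.2, 0.3)
        fit = ez_fit(simulate_ddm_trials(true, 2000, seed=4))
        assert fit.v == pytest.approx(true.v, rel=0.05)
        assert fit.a == pytest.approx(true.a, rel=0.05)
        assert fit.t_er == pytest.approx(true.t_er, rel=0.10)

    def test_drift_ordering_preserved(self):
        lo = ez_fit(simulate_ddm_trials(DDMParams(0.8, 1.2, 0.3), 1500, seed=5))
        hi = ez_fit(simulate_ddm_trials(DDMParams(2.0, 1.2, 0.3), 1500, seed=6))
        assert lo.v < hi.v

    def test_perfect_accuracy_edge_correction(self, rng):
        trials = pd.DataFrame({"accuracy": np.ones(100, dtype=int),
                               "rt": 0.5 + 0.1 * rng.random(100)})
        fit = ez_fit(trials)
        assert np.isfinite(fit.v) and fit.v > 0

    def test_below_chance_gives_negative_drift(self, rng):
        trials = pd.DataFrame({"accuracy": np.zeros(60, dtype=int),
                               "rt": 0.6 + 0.1 * rng.random(60)})
        assert ez_fit(trials).v < 0

    def test_too_few_trials_rejected(self, rng):
        trials = pd.DataFrame({"accuracy": [1] * 10, "rt": rng.random(10) + 0.3})
        with pytest.raises(ValueError):
            ez_fit(trials)

    def test_bias_shrinks_with_sample_size(self):
        true = DDMParams(1.2, 1.4, 0.3)
        errs = []
        for n, seed in [(200, 7), (2000, 8), (20000, 9)]:
            reps = [abs(ez_fit(simulate_ddm_trials(true, n, seed=seed * 100 + i)).v - true.v)
                    for i in range(3)]
            errs.append(np.mean(reps))
        assert errs[2] < errs[0]


class TestDriftCurve:
    def _phase2_trials(self, b, n_stimuli=8, seed=0):
        cfg = CohortConfig(seed=seed)
        v = drift_schedule(b, cfg)
        rng = np.random.default_rng(seed)
        rows = []
        for k in range(1, 99):
            t = simulate_ddm_trials(DDMParams(v[k - 1], 1.6, 0.3), n_stimuli, seed=rng)
            for _, r in t.iterrows():
                rows.append((k, r.accuracy, r.rt))
        return pd.DataFrame(rows, columns=["repetition", "accuracy", "rt"])

    def test_rising_generator_gives_rising_curve(self):
        # study-scale trial counts: global rise is clear, local ranks noisy
        trials = self._phase2_trials(b=0.5)
        curve = drift_curve(trials, bin_width=7)
        rho, p = spearmanr(curve.bin_centers, curve.drifts)
        assert rho > 0 and p < 0.05

    def test_curve_tracks_generating_schedule(self):
        # generator oracle: binned true drifts vs fitted drifts
        trials = self._phase2_trials(b=0.5, n_stimuli=45, seed=1)
        curve = drift_curve(trials, bin_width=7)
        cfg = CohortConfig(seed=0)
        v_true = drift_schedule(0.5, cfg)
        true_binned = [v_true[int(lo) - 1:int(lo) + 6].mean()
                       for lo in np.arange(1, 99, 7)]
        r = np.corrcoef(true_binned, curve.drifts)[0, 1]
        assert r > 0.9

    def test_degenerate_binning_refused_by_fit(self):
        trials = self._phase2_trials(b=0.3)
        curve = drift_curve(trials, bin_width=98)
        assert len(curve.drifts) == 1
        with pytest.raises(ValueError):
            fit_learning_rate(curve)

    def test_sparse_bins_dropped(self, caplog):
        trials = self._phase2_trials(b=0.3, n_stimuli=8)
        trials = trials[trials.repetition > 7]  # empty first bin
        with caplog.at_level("WARNING"):
            curve = drift_curve(trials, bin_width=7)
        assert len(curve.drifts) == 13


class TestFitLearningRate:
    def _noiseless_curve(self, b, alpha=0.8):
        k = np.arange(4, 99, 7).astype(float)
        x = np.log(k + 1.0)
        return LearningCurve(k, alpha * x**b)

    @pytest.mark.parametrize("method", ["lar", "ls"])
    def test_model_identity(self, method):
        lr = fit_learning_rate(self._noiseless_curve(0.3), method=method)
        assert lr == pytest.approx(-0.3, abs=1e-6)

    def test_flat_curve_zero_rate(self):
        k = np.arange(4, 99, 7).astype(float)
        lr = fit_learning_rate(LearningCurve(k, np.full(len(k), 1.3)))
        assert lr == pytest.approx(0.0, abs=1e-6)

    def test_lar_resists_gross_outlier(self):
        wins = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            curve = self._noiseless_curve(0.3)
            y = curve.drifts + 0.02 * r.standard_normal(len(curve.drifts))
            y[r.integers(len(y))] += 1.5
            e_lar = abs(fit_learning_rate(LearningCurve(curve.bin_centers, y.copy()),
                                          "lar") + 0.3)
            e_ls = abs(fit_learning_rate(LearningCurve(curve.bin_centers, y.copy()),
                                         "ls") + 0.3)
            wins += e_lar < e_ls
        assert wins >= 0.8 * 40

    def test_monotone_over_exponent_grid(self):
        rates = [fit_learning_rate(self._noiseless_curve(b))
                 for b in (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)]
        assert all(np.diff(rates) < 0)   # steeper exponent -> more negative rate

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            fit_learning_rate(self._noiseless_curve(0.3), method="huber")


class TestHabitStrength:
    def _trials(self, v_comp, v_incomp, n=400, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for cond, v in (("compatible", v_comp), ("incompatible", v_incomp)):
            t = simulate_ddm_trials(DDMParams(v, 1.6, 0.3), n, seed=rng)
            t["condition"] = cond
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def test_recovers_injected_difference(self):
        est = np.mean([habit_strength(self._trials(1.33, 1.20, n=2000, seed=s))
                       for s in range(4)])
        assert est == pytest.approx(0.13, abs=0.05)

    def test_antisymmetric_under_label_swap(self):
        trials = self._trials(1.5, 1.1, seed=3)
        swapped = trials.replace({"condition": {"compatible": "incompatible",
                                                "incompatible": "compatible"}})
        assert habit_strength(swapped) == pytest.approx(-habit_strength(trials))

    def test_sparse_condition_flagged(self):
        trials = self._trials(1.4, 1.2, n=25, seed=4)
        trials = pd.concat([trials[trials.condition == "compatible"],
                            trials[trials.condition == "incompatible"].head(5)])
        assert np.isnan(habit_strength(trials))

    def test_missing_condition_rejected(self):
        trials = self._trials(1.4, 1.2, seed=5)
        with pytest.raises(ValueError):
            habit_strength(trials[trials.condition == "compatible"])

    def test_cohort_outlier_flagging(self, rng):
        values = rng.normal(0.1, 0.2, 40)
        values[7] = values.mean() + 4.5 * values.std()
        flags = flag_habit_outliers(values)
        assert flags[7]
        assert flags.sum() == 1
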