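# dynseg

Dynamic functional brain-network segregation analysis for feedback-driven
learning.

During trial-and-error learning, whole-brain functional networks shift from
an *integrated* state (strong coupling across systems) towards a
*segregated* state (strong within-network coupling, anticorrelated
networks). `dynseg` quantifies that shift from region-level fMRI time
series and relates it to behavior, for researchers studying learning,
habit formation, and large-scale network dynamics:

- **Tapered windowed connectivity** — 20 sliding windows (non-overlapping
  or half-overlapping) with exponential taper
  `w_t = w0 e^{(t-T)/θ}`, `θ = T/3`, and Fisher-z weighted Pearson
  correlation per node pair.
- **Brain states** — city-block k-means (k = 2) over all subjects' windowed
  matrices; centroids scored by system segregation
  `S = 1 − z̄_between / z̄_within` and labelled integrated/segregated;
  per-window state prevalence.
- **Modularity trajectories** — signed weighted Louvain with consensus
  (`Q = Q⁺/v⁺ − Q⁻/(v⁺+v⁻)`, γ = 1), per-window Q, participation
  coefficient and module-degree Z per node, summarized per network.
- **Behavior** — drift-diffusion trials (accuracy-coded, unit diffusion);
  per-repetition-bin drift via closed-form moment inversion; learning rate
  as minus the exponent of a robust one-term power fit
  `v = α·x^b`, `x = log(repetition+1)`; habit strength as the
  compatible−incompatible drift difference.
- **Cohort statistics** — Q-slope on log cumulative trials, early-Q,
  one-sample/paired/Welch t tests, Pearson brain–behavior battery,
  learning-rate median split, per-network slope tests with Bonferroni
  family-wise correction.
- **Synthetic cohort** — a generator with known ground truth (two latent
  covariance states with rising segregated prevalence; DDM behavior whose
  learning rate is coupled to the transition rate, habit uncoupled) so the
  whole chain is testable end to end.

## Worked example

Run the default synthetic study (40 subjects, 60 nodes in 4 networks,
700 scans, 784 learning trials) end to end:

```python
from dynseg.config import PipelineConfig, ModularityConfig
from dynseg.pipeline import run_study

cfg = PipelineConfig(seed=1)
cfg.cohort.seed = 1
cfg.modularity = ModularityConfig(n_runs=5, consensus=False)
res = run_study(cfg)
r = res.report
print(f"mean Q slope      {r['q_slope']['mean']:.3f}  (t = {r['q_slope']['t']:.1f})")
print(f"r(Q slope, LR)    {r['r_q_slope_learning_rate']['r']:.3f}")
print(f"r(Q slope, habit) {r['r_q_slope_habit']['r']:.3f}")
print(f"centroid segregation  integrated {r['centroid_segregation']['integrated']:.2f}"
      f"  segregated {r['centroid_segregation']['segregated']:.2f}")
```

prints

```
mean Q slope      0.159  (t = 19.7)
r(Q slope, LR)    -0.317
r(Q slope, habit) -0.029
centroid segregation  integrated 0.63  segregated 1.07
```

Read: modularity-Q rises with learning in every subject (strongly positive
mean slope); subjects with a higher learning rate show a *smaller*
additional Q increase (negative correlation — they reach the segregated
state earlier), while habit strength is unrelated to the Q trajectory; and
the two k-means centroids separate cleanly on system segregation, so state
2 is the segregated state.

The same run from the shell, writing all tables plus a JSON report:

```bash
dynseg run --seed 1 --out results/
```

Per-stage subcommands (`simulate`, `prep`, `fc`, `states`, `modularity`,
`behavior`) expose each step on delimited text files; see `dynseg --help`.

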