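# pulsechase

Analysis of pulse-chase proteomics experiments that measure **protein
degradation in vivo**: metabolically labeled (BONCAT-style) proteins are
quantified by multiplexed LC-MS at several chase timepoints, and the decline
of the labeled pool per protein yields degradation kinetics, half-lives, and
how both change with age across brain regions.

`pulsechase` turns protein-level abundance tables into:

- **enrichment-over-background hit calls** — log2 transform, valid-value
  filtering, down-shifted Gaussian imputation, and per-protein two-tailed
  t-tests of labeled vs wildtype background channels;
- **degradation trajectories** — percent remaining per chase timepoint
  (TP1 ≡ 100%), gated on TP1 enrichment over background (log2 FC > 1.5) and
  on monotonicity (no rise > 5 percentage points between timepoints);
- **kinetic fits and half-lives** — least-squares fits of a one-level model
  Λ₁(t) = e^(−k_A t) and a two-level (precursor-pool) model
  Λ₂(t) = (G(t) − G(T+tp)) / (G(0) − G(T+tp)) with
  G(t) = k_AB/(k_AB+k_A)·e^(−k_B t) + k_B/(k_A−k_B)·e^(−(k_AB+k_A)t),
  selected per protein by AIC = n·ln(RSS/n) + 2k; half-life from ln 2 / k_A
  (one-level) or linear interpolation of the fitted curve (two-level), plus a
  model-free interpolated half-life straight from the trajectory;
- **trajectory clustering** — fuzzy c-means on young trajectory shapes with
  the cluster number chosen from the minimum-centroid-distance elbow, older
  ages projected onto young clusters, and aging scored per cluster by
  trapezoidal **delta integrals** (aged minus young area under the curve) and
  trajectory slopes, with one-way ANOVA + Tukey HSD;
- **protein-set overlap statistics** — Venn partitions, exact upper-tail
  hypergeometric enrichment against a labeled-proteome background
  (default N = 3787), and multi-aberration burden summaries;
- a **synthetic plex generator** with full ground truth (true rates,
  half-lives, planted clusters, aged/young pairing) for validating every
  stage.

## Worked example

Simulate a paired young/aged cohort whose half-lives double with age, build
trajectories, fit kinetics, and recover the planted fold change:

```python
from pulsechase import (SimConfig, simulate_plex, build_trajectories, passing,
                        fit_trajectory, fit_one_level, half_life_fold_changes)

cfg = SimConfig(n_proteins=200, noise_cv=0.1, aged_halflife_fold=2.0, seed=42)
young, truth = simulate_plex(cfg, "young")
aged, _ = simulate_plex(cfg, "aged")

trajs = passing(build_trajectories(young, tp1_log2fc_gate=1.5, max_rise=5.0))
print(f"{len(trajs)} of {cfg.n_proteins} proteins pass the TP1 gate and rise filter")

fit = fit_trajectory(trajs[0])
true_hl = truth.loc[fit.protein_id, "half_life_days"]
print(f"{fit.protein_id}: model={fit.model}, kA={fit.k_a:.4f}/day, "
      f"half-life={fit.half_life_days:.2f} d (true {true_hl:.2f} d)")

fits_y = [fit_one_level(t) for t in trajs]
fits_a = [fit_one_level(t) for t in passing(build_trajectories(aged))]
table, summary = half_life_fold_changes(fits_y, fits_a)
print(f"mean log2 half-life fold change (aged/young) over {summary['n']} proteins: "
      f"{summary['mean_log2fc']:.3f}")
```

Output:

```
200 of 200 proteins pass the TP1 gate and rise filter
P00000: model=one_level, kA=0.1049/day, half-life=6.61 d (true 5.82 d)
mean log2 half-life fold change (aged/young) over 200 proteins: 0.990
```

The first protein decays as a single exponential with a fitted rate of
0.105/day, i.e. a 6.6-day half-life against a ground truth of 5.8 days; and
the cohort-level mean log2 fold change of 0.990 recovers the planted
doubling (log2 2 = 1) to within measurement noise. A mean log2 FC of 1
corresponds to a 100% increase in half-life
(`fold_change_to_percent(1.0) == 100.0`).

A `pulsechase` console script exposes each stage
(`simulate`, `enrich`, `turnover`, `cluster`, `overlap`, `run-all`); see
`pulsechase --help`.

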