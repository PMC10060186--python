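# cx3track

Longitudinal blood-biomarker analysis for chemo-immunotherapy response in
non–small cell lung cancer (NSCLC), built around the **CX3CR1 score**: the
change, in percentage points, of the CX3CR1⁺ fraction of circulating CD8⁺
T cells from the pretreatment baseline. CX3CR1 marks terminally
differentiated effector CD8⁺ T cells that remain in circulation, so an
early on-treatment rise in this subset is a candidate blood-based predictor
of objective response where pretreatment PD-L1 tumor proportion score (TPS)
performs poorly.

The package is aimed at biostatisticians and translational immunologists
who want the complete analysis chain as tested, reusable code:

- **Scoring** — per-patient score at each follow-up week and the windowed
  maximum `S(t) = max{ x(w) − x(0) : 0 < w ≤ t }`, dichotomized at a cutoff
  θ (default 10 percentage points). Patients with no on-treatment draw in a
  window are *not evaluable* for it, never imputed.
- **Diagnostics** — empirical ROC with AUC as the Mann–Whitney probability
  (ties ½), DeLong variance from placement values, the Youden-optimal
  cutoff **band** (all cutoffs attaining max J = sens + spec − 1);
  sensitivity/specificity/PPV/NPV/accuracy with Jeffreys
  (Beta(x+½, n−x+½)) 95% intervals; Fisher's exact test with the
  conditional-MLE odds ratio and exact CI; Mann–Whitney group comparison;
  overall response rate (CR+PR)/n × 100.
- **Survival** — Kaplan–Meier with Greenwood errors, the log-rank
  (Mantel–Cox) test, and Cox proportional hazards fit by Newton–Raphson on
  the Efron-approximated partial likelihood (Breslow optional), plus a
  univariate screen → multivariable model workflow.
- **Repertoire** — tumor↔blood TCRβ clonotype tracking: frequent TIL-TCR
  selection (≥ 5 templates), blood matching, combined circulating
  frequency, Morisita–Horn repertoire similarity, per-clonotype expansion
  testing (Fisher exact, Benjamini–Hochberg) and CX3CR1 labelling of
  expanded clones.
- **Synthetic cohorts** — a generator producing biomarker trajectories,
  clinical outcomes with group-indexed exponential survival, and paired
  power-law repertoires with planted expansion, so every stage is testable
  without patient data.

## Worked example

```sh
cx3track all --demo --out demo_out --seed 29
```

runs the full chain on a simulated 29-patient cohort. From `demo_out/`:

```text
$ head -4 demo_out/performance_table.csv
metric,wk3 (n=28),wk4 (n=29),wk6 (n=29),wk9 (n=29)
PPV,100.0% (2/2),100.0% (6/6),100.0% (8/8),100.0% (8/8)
NPV,76.9% (20/26),91.3% (21/23),100.0% (21/21),100.0% (21/21)
Sensitivity,25.0% (2/8),75.0% (6/8),100.0% (8/8),100.0% (8/8)
```

Each column is one evaluation window; `n` is the number of patients with at
least one on-treatment draw inside it (missed draws shrink early windows).
Sensitivity rises with the window because responders' CX3CR1⁺ fractions
climb over the first ~6 weeks of treatment. `survival_table.csv` holds the
per-covariate hazard ratios (score-high vs low) with Wald CIs, and
`venn_counts.json` the repertoire overlap: for this seed, 280/2000 (14.0%)
tumor clonotypes are frequent TIL-TCRs, 31 (11.1%) of them are found in
blood, and their combined circulating frequency rises from 2.6% before
treatment to 15.9% at 6 weeks as the 8 detected expanded clones grow out
(`tracking_table.tsv` carries each clone's CX3CR1⁺ cell fraction).

The same analyses are available as library calls
(`cx3track.confusion_metrics`, `cx3track.roc`, `cx3track.cox_fit`,
`cx3track.morisita_horn`, …); see the module docstrings.

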