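# Methods

## The score and its windowed maximum

Each patient contributes a longitudinal series x(w): the CX3CR1⁺ fraction
(percent) of peripheral-blood CD8⁺ T cells at week w, with exactly one
pretreatment baseline at w = 0. The score at a follow-up week is
x(w) − x(0), a **percentage-point difference**. We deliberately do not use
relative change ((x(w) − x(0))/x(0)): the fixed 10- and 20-point cutoffs
are applied across baselines spanning roughly 4–85%, which is only coherent
on the additive scale, and published cutoff bands of ~9.4–10.4 "%" are
additive-scale magnitudes. A relative-change mode remains available
(`relative=True`) for sensitivity analysis.

The windowed score S(t) is the maximum over on-treatment weeks in the
closed window (0, t]; weeks are compared exactly as recorded. A patient
with no on-treatment draw inside a window is flagged not-evaluable — never
scored zero and never imputed — which is what makes the evaluable n vary
across windows in a cohort with missed draws. S(t) is monotone
non-decreasing in t, and the high set at a stricter cutoff is nested inside
the high set at a looser one; both properties are enforced by tests.

## Diagnostic evaluation

**ROC/AUC.** The ROC is the empirical curve over observed score thresholds
(positive iff score ≥ t, with ±∞ sentinels). The AUC is the Mann–Whitney
probability with ties counted ½ — invariant under any strictly increasing
transform of the scores, hence identical to the ROC of a univariable
logistic model on the same scores. The DeLong variance uses the
placement-value decomposition S₁₀/m + S₀₁/n with midranks; the 95% CI is
Wald, clipped to [0, 1].

**Youden band.** J = sens + spec − 1 is evaluated at observed thresholds.
Because every θ between two adjacent observed scores induces the same
classification, the optimum is reported as the band (low, high]: high is
the smallest observed score called positive at the optimum (or the largest
of several J-tied thresholds), low the largest observed score below the
attaining set. Any cutoff inside the band is equally optimal on the data.

**Proportion intervals.** All proportions (sensitivity, specificity, PPV,
NPV, accuracy, ORR) carry Jeffreys 95% intervals — the central interval of
the Beta(x+½, n−x+½) posterior, with the conventional endpoint fix (lower
bound 0 at x = 0, upper bound 1 at x = n). Empirical coverage at n = 17 is
≥ 93% across p = 0.1…0.9 (tested). A metric whose margin is empty (e.g.
PPV with no positive calls) is reported as undefined, not 0.

**Exact tests.** The two-sided Fisher p uses probability-mass ordering
(sum of tables with the observed margins no more probable than the observed
one), verified against full hypergeometric enumeration to 1e-12. The odds
ratio is reported two ways, because they can differ several-fold in small
tables: the conditional MLE under the noncentral hypergeometric likelihood
with an exact test-inversion CI (primary), and the plain cross-product
ad/bc (secondary). Mann–Whitney uses exact enumeration for pooled n ≤ 12
without ties, otherwise the tie- and continuity-corrected normal
approximation. ORR = (CR+PR)/n × 100 is reported at full precision and
rounded half-even to one decimal; note 12/29 rounds to 41.4, whereas some
reports print 41.3 for the same counts — a 0.04-point rounding discrepancy
we document rather than reproduce.

## Survival

Kaplan–Meier uses the product-limit estimator with Greenwood standard
errors; the median is the earliest event time with S ≤ 0.5 (undefined when
S never reaches it). The log-rank test sums observed-minus-expected event
counts over event times with the hypergeometric covariance; k groups give a
(k−1)-df chi-square via the pseudo-inverse.

The Cox model is maximized directly on the partial likelihood by
Newton–Raphson with step-halving (the log-likelihood never decreases across
iterations), converging when the relative change is < 1e-9 or after 100
iterations. Efron's tie approximation is the default — more accurate than
Breslow under moderate ties and identical on tie-free data (tested);
Breslow is available by flag. Inference is Wald (HR, 95% CI, p per
covariate), matching the usual presentation; a likelihood-ratio p for the
whole model is included. The score test at β = 0 is exposed and equals the
log-rank chi-square for a single tie-free binary covariate to 1e-8
(tested). Zero-variance covariates raise; collinearity is detected from the
conditioning of the baseline information matrix and raises naming the
offending pair; monotone likelihood (perfect separation) is flagged
non-converged with a warning rather than silently reported.

`univariate_screen` fits each covariate alone, retains those with Wald
p < α_keep, and fits the joint model on the retained set. α_keep defaults
to 0.10, the permissive convention for hypothesis-generating screens in
small cohorts; it is a parameter precisely because conventions differ
(0.01–0.10) and the choice materially changes which covariates reach the
multivariable model. The implementation cross-checks against lifelines in
the test suite; lifelines is never on the analysis path.

## Repertoire analytics

Clonotype identity for tumor↔blood matching is amino-acid CDR3β plus the
V gene collapsed to gene level (alleles stripped), since bulk immunoSEQ and
single-cell V(D)J pipelines annotate alleles inconsistently; within-platform
work can use stricter keys. Frequent TIL-TCRs are tumor clonotypes with
≥ 5 template counts (template counts, not estimated clones). Morisita–Horn
similarity is computed on raw template/cell counts over the union support,
without rarefaction; it is symmetric, scale-invariant, 1 iff relative
abundances are proportional, 0 iff supports are disjoint (property-tested).

Expansion between two blood timepoints tests each union clonotype with a
two-sided Fisher exact test on (count, rest) × (t₁, t₂), adjusts across
all clonotypes of that comparison by Benjamini–Hochberg, and calls a clone
expanded only when adjusted p < 0.05 **and** its frequency increased —
the test is direction-blind, the biology is not. Each timepoint comparison
is adjusted as its own BH family; pooling contrasts into one family is
possible by running them jointly, but separate families are the default so
a 6-week and a 9-week contrast remain individually interpretable.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes,
at the scale of the motivating study:

- **Cohort**: 29 patients by default, responder probability 0.414.
  Baselines are Beta(2, 3.7) scaled to [4, 85.1] (median ≈ 31%, matching
  the observed median and range). Responder deltas are N(20, 8) percentage
  points, nonresponders N(0, 6), reached linearly over 6 weeks
  (measurements at weeks 0, 3, 4, 6, 9 with 2-point measurement noise);
  these defaults put ~85–90% of responders and < 10% of nonresponders
  above the 10-point cutoff, the observed separation. Each on-treatment
  draw is missing independently with probability 0.1, reproducing evaluable
  n that grows with the window.
- **Survival**: group-indexed exponentials — the score-high group's hazard
  is hr_pfs (default 0.28) resp. hr_os (0.25) times the score-low group's
  (low-group medians 6 and 12 months), with independent exponential
  censoring (rate 0.02/month) truncated at 43.4 months of follow-up. PFS
  and OS are drawn independently so each endpoint's generating hazard
  ratio is exactly recoverable; Cox recovery at n = 500 shows < 0.05 mean
  log-HR bias and ≥ 90% CI coverage (tested).
- **Repertoires**: tumor template counts are iid discrete power law
  (Zipf, exponent 2.0, capped at 10⁴), so singletons dominate and a
  ~13% minority passes the frequent-TIL threshold — the rank-abundance
  shape of bulk tumor repertoires. A random 10% of tumor clones is seeded
  into blood at a combined 15% baseline frequency; the 10 shared clones
  most abundant in the tumor are planted as expanders (×20 frequency from
  week 6), so expanded clones are predominantly frequent TIL-TCRs, as
  observed. The blood background is 2,000 skewed (Dirichlet-weighted)
  clones — mostly rare, like real single-cell repertoires, which is what
  keeps null Fisher fluctuations below the BH threshold. Cells carry
  CX3CR1⁺ labels with probability 0.9 (expanding clones) vs 0.3
  (background).
- All randomness flows from one integer seed through
  `numpy.random.SeedSequence.spawn`, so the cohort and repertoire arms are
  independently reproducible and byte-identical across reruns.

Not emulated: assay drift and batch effects in cytometry gating,
correlation between baseline level and response, informative dropout,
non-proportional hazards, sequencing depth variation across timepoints, and
clonotype sharing between patients. Passing tests therefore demonstrate
that the statistical machinery is correct under the stated model, not that
the biomarker generalizes to data violating these assumptions.

## Numerical choices and problem sizes

Acceptance-style simulations use n = 500 patients × 100 replicates for
hazard-ratio recovery and 50 replicates at 10,000 cells/timepoint for
planted-expansion recovery — sizes at which the Monte-Carlo error of the
checked quantities is comfortably below the asserted bounds while the full
suite runs in about two minutes. Newton–Raphson tolerances (1e-9 relative
log-likelihood), the collinearity condition-number bound (1e10), the
separation coefficient bound (|β| > 15) and the Youden J tie tolerance
(1e-12) are fixed in code. Ties in the windowed maximum are irrelevant
(max of a finite set); classification at θ is closed (score ≥ θ is high).

## Known limitations

- The Cox implementation supports right censoring only — no delayed entry,
  time-varying covariates, stratification, frailty or competing risks.
- DeLong CIs are Wald-type and can be anti-conservative for AUC near 1 at
  small n; the curve object exposes the SE for alternative constructions.
- The exact Fisher CI inverts one-sided tests at 2.5% each, which is
  conservative in small tables.
- Expansion testing treats cells/templates as independent draws; UMI or
  template duplication structure is not modelled.
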