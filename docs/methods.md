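# Methods

## The analytical problem

A thrombotic (type 1) myocardial infarction is caused by plaque disruption
with occlusive coronary thrombus; a non-thrombotic (type 2) MI produces the
same necrosis marker profile without thrombus, and stable coronary artery
disease shares the underlying atherosclerosis without an acute event.  The
analysis implemented here asks, metabolite by metabolite, whether the change
in plasma abundance from a subject's own quiescent state to the acute state
is *specific* to thrombotic MI — distinct from the change in both control
groups over the same time course — and whether baseline (presentation-time)
abundances of the qualifying metabolites can classify thrombotic MI against
the pooled controls.

## Intra-subject fold-change model

For subject *s* and metabolite *m*, the analysis unit is
`r[s,m] = log2(x[s,m,acute] / x[s,m,Q])` with acute ∈ {T0, T6} analyzed in
entirely separate runs.  Because `r` is a within-subject contrast, every
time-invariant subject attribute (age, sex, chronic medication, baseline
metabotype) cancels exactly; subjects are their own controls.

Per metabolite, `r` is regressed on group indicators (a cell-means one-way
layout over thrombotic / non-thrombotic / stable), giving:

- the omnibus F test of equal group mean changes (df 2, N−3);
- pairwise contrasts by pooled-variance t (unadjusted two-sided p);
- a one-sample t of the thrombotic mean change against 0 using the
  thrombotic group's own variance (pooling here would leak control-group
  noise into a within-group question).

Reported "fold change" is `2^mean(r)` — the back-transformed mean of log2
ratios (geometric mean of ratios) — because that is the quantity the
log2-scale model estimates.  The arithmetic mean of raw ratios is available
behind a flag (`summarize_group_fc(method="arithmetic")`); it is never
smaller (AM–GM) and does not correspond to the fitted model.

Degenerate metabolites (zero pooled residual variance) are flagged,
reported with p = 1 (equal means) or p = 0 plus a warning (unequal means),
and excluded from all q-value families.

## False-discovery control and the dual gate

Two Storey q-value families are computed per acute time point, one over the
ANOVA p's and one over the within-thrombotic p's, each across all
non-degenerate metabolites.  π0 is estimated on the λ grid 0, 0.05, …, 0.90
via `#{p > λ} / (m(1−λ))`, smoothed by a cubic least-squares polynomial and
read at λ = 0.90, clamped to [1/m, 1].  (The classical smoother is a
df-3 smoothing spline; the cubic polynomial is this package's deterministic,
dependency-free equivalent.)  With `pi0_method="fixed_1"` the estimator
reduces *exactly* to Benjamini–Hochberg adjusted p-values, which is the
oracle-checked path in the tests.

Gates:

- **candidate** — `q_within < 0.10` and `q_ANOVA < 0.10`; feeds all
  multivariate analyses (PLS-DA, classifier);
- **specific** — both q's `< 0.05` plus both thrombotic-vs-control
  post-hoc contrasts at α = 0.05.  Specific ⊆ candidate by construction.

The across-group (ANOVA) gate is what rejects procedural artifacts: a
metabolite that rises acutely in *every* group — the peri-catheterization
lidocaine pattern — shows a large within-group change but no group
difference, and cannot qualify.

## PLS-DA

NIPALS PLS2 of the autoscaled candidate fold-change matrix on the centered
group-indicator matrix (one column per group).  Deterministic
initialization (the Y-residual column of largest variance), tolerance
1e-10, ≤500 inner iterations, X and Y deflation per component; scores are
therefore mutually orthogonal and R²Y = 1 − SS(Y−Ŷ)/SS(Y) is nondecreasing
in the number of components.  Two components are fit by default because the
score plots are two-dimensional.  Autoscaling (unit variance) is the
metabolomics-standard choice.  Group ellipses are drawn at squared
Mahalanobis radius χ²₂(0.90) under the group's sample covariance (n−1); a
Hotelling-T² radius is available behind `method="hotelling"` for
small-sample coverage.

## Baseline classifier and recursive halving

Because a patient's quiescent baseline is unknown at presentation, the
classifier consumes log2 T0 abundances of **all** baseline subjects (paired
and unpaired, 11 vs 27 pooled controls), restricted to the screen's
candidate metabolites.  Random forests (scikit-learn; Gini splits, √p
features per split, bootstrap, default 2000 trees — desk-scale studies use
200–500) are combined with recursive halving: each round drops the
⌊n/2⌋ lowest-importance features, so 65 starting features give the schedule
65, 33, 17, 9, 5, 3, 2, 1.  Stratified 10-fold CV scores every size by
pooled out-of-fold misclassification; the minimizing size is chosen, ties
to the smaller panel.  AUC is the midrank (Mann–Whitney) statistic of
pooled out-of-fold positive-class probabilities; sensitivity/specificity
come from pooled majority-vote predictions with thrombotic positive.

Ranking scope: with the default `per_fold`, importances are recomputed
inside every training fold, so the reported CV performance never sees
test-fold labels (a leakage test asserts this).  `global` ranks once on all
data — the optimistic variant some published workflows use; it inflates
CV AUC and is provided for comparison only.

Variable importance: `permutation_oob` (Breiman's mean decrease in
out-of-bag accuracy under per-feature permutation, computed per tree from
re-derived bootstrap draws) is the reported measure, max-normalized to 100.
`impurity` (mean Gini decrease) is available and is used for *ranking*
inside the desk-scale elimination studies: at n = 38 each tree holds only
~14 OOB samples, making per-tree permutation accuracy a high-variance
ranking signal, and impurity ranking is an order of magnitude cheaper.

## Exact contingency tests

The Freeman–Halton r×c test enumerates every table with the observed
margins (depth-first over row compositions; guarded at 10⁷ tables with a
seeded Patefield Monte-Carlo fallback) and sums the multivariate
hypergeometric probabilities of tables no more probable than the observed
one, with relative tie tolerance 1e-7.  On 2×2 inputs this is exactly the
two-sided Fisher test (probability-mass definition — the definition that
reproduces the published within-group medication p-values 0.002 and 0.03;
tail-doubling does not and is not offered).  Within-group
enrollment-vs-follow-up tests treat the two time points as independent
samples because that convention reproduces the published values; the exact
McNemar test (`paired=True`) is provided as the statistically correct
alternative for paired data.  Continuous variables: one-way ANOVA and
Kruskal–Wallis via scipy, Welch's ANOVA by the standard closed form
(cross-checked against pingouin).

## Synthetic cohort

Log2 abundance of metabolite *m* in sample (*s*, *t*):

    mu_m + u_{s,m} + delta(group_s, m, t) + eps_{s,m,t}

- `mu_m ~ N(20, 2)` — baseline log2 ion intensities;
- `u` — time-invariant subject effect, sd **1.6**;
- `eps` — within-subject residual, sd **0.5**;
- `delta` — planted acute (T0 and T6) log2 effect: thrombotic-only for
  *specific* metabolites, identical in all groups for *procedural* ones,
  magnitude uniform in [1, 4] (sign random) by default;
- both `u` and `eps` share a latent factor per 8-metabolite annotation
  block with correlation ρ = 0.4, so biochemical families co-move;
- per metabolite, the lowest 5% of values are left-censored to missing
  (stable-rank ties), emulating detection limits; minimum imputation
  restores a complete matrix downstream.

Default sizes are the study's: 11/12/15 subjects with 9/9/14 paired;
1,032 metabolites (desk-scale studies use 200).

Calibration rationale: fold-change noise is `sqrt(2)·0.5 ≈ 0.7` log2 units,
so a Table-5-magnitude effect (|log2FC| = 2) is detected at n = 9 with
near-certainty — the regime the screen's published tables imply.  The
subject-level sd 1.6 places single-feature baseline separation at AUC ≈
0.8 (between-subject biological variation dominating within-subject
variation, the premise of the within-subject design), so that the baseline
classifier needs a multivariate panel yet reaches CV AUC ≈ 0.94 — the
published classifier's regime.  The generator does **not** reproduce:
non-normal abundance distributions, batch/drift structure, missingness
informative beyond the detection limit, or realistic inter-family
correlation topology; passing tests therefore certify the statistical
machinery under the stated model, not performance on real LC-MS data.

## Simulation studies (desk scale)

All studies use study-sized groups and 200 metabolites, seeded end to end:

- **Null FDR calibration** (200 cohorts, no effects): specific-gate flags
  per cohort and empirical FDR.
- **Screen recovery** (20 cohorts, 10 thrombotic-specific effects at
  |log2FC| = 2): planted metabolites flagged specific, false-flag FDR.
- **Procedural rejection** (200 cohorts, 10 all-group effects): rate at
  which procedural metabolites leak through the specific gate.
- **Classifier recovery** (20 cohorts, panels of 10 planted + 55 null
  features, mirroring the published 65-candidate panel): planted features
  in the chosen panel, pooled CV AUC.  A structural caveat: with
  exchangeable strong effects the CV-error minimum frequently sits at
  panels of 2–5 features, and the smallest-size tie-break then caps the
  number of planted features the chosen panel can contain; the honest
  per-fold pipeline reports mean pooled CV AUC ≈ 0.94 while recovering
  ≈ 6 of 10 planted features on average.
- **Null classifier calibration** (100 label permutations): pooled CV AUC
  distribution centers on 0.5.

## Numerical conventions

Sample standard deviations (n−1) throughout; stable sorts and
column-order tie-breaks everywhere a ranking is cut; one global seed fans
out to stage seeds via `numpy.random.SeedSequence`; q-values clipped at 1;
midrank tie handling in AUC; enumeration probabilities checked to sum to 1.

## Known limitations

- π0 smoothing differs in detail from the reference spline smoother
  (identical behavior at π0 = 1 is oracle-tested; differences appear only
  in the third decimal of q-values on mixed p distributions).
- The R²Y values printed by the study (0.80/0.77) and Table 4–6 contents
  are functions of the undeposited dataset and are not reproducible from
  any synthetic cohort; the pipeline reproduces the *procedure* and the
  desk-computable numbers.
- Exact r×c enumeration is exponential in table size; the guard plus
  Monte-Carlo fallback covers larger tables at reduced precision.
- The classifier's sensitivity/specificity use the 0.5 majority-vote
  threshold; no threshold optimization or probability calibration is done.
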