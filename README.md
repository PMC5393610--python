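# thrombomet

Screening and classification pipeline for plasma metabolomic signatures of
**thrombotic myocardial infarction**.  The scientific question: which
metabolites change from a patient's own quiescent state to the acute state
*specifically* in thrombotic (type 1) MI — distinct from the change seen in
non-thrombotic (type 2) MI and stable CAD controls undergoing the same
catheterization — and can baseline abundances of those metabolites classify
thrombotic MI at presentation, before necrosis markers rise?

The pipeline implements, as a tested library plus numbered analysis
scripts:

- **Intra-subject fold-change screen** — per metabolite, subject-level
  `r = log2(acute/quiescent)` regressed on group indicators; omnibus ANOVA,
  pooled-variance post-hoc contrasts, within-thrombotic one-sample test;
  Storey q-values with a dual FDR gate (candidates at q < 0.10 feeding
  multivariate analyses, thrombotic-specific metabolites at q < 0.05 plus
  both thrombotic-vs-control contrasts at α = 0.05).
- **PLS-DA** (NIPALS PLS2) of candidate fold changes, with R²Y and 90%
  Mahalanobis confidence ellipses (χ²₂ radius) on the score plane.
- **Baseline random-forest classifier** with recursive halving elimination
  (65 → 33 → 17 → … → 1), stratified 10-fold CV, pooled out-of-fold AUC /
  sensitivity / specificity, and permutation-OOB relative importances.
- **Exact cohort statistics** — two-sided Fisher 2×2 and Freeman–Halton
  r×c tests (full enumeration with a Monte-Carlo fallback), ANOVA / Welch /
  Kruskal–Wallis group tests, and medication-change summaries.
- **Synthetic cohort generator** with planted ground truth (thrombotic-
  specific, procedural, and null metabolites; subject random effects,
  correlated biochemical families, left-censoring), since the study's
  plasma dataset is not publicly deposited.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_screen_fold_changes.py
python analysis/03_plsda.py
python analysis/04_classifier_rfe.py
python analysis/05_cohort_tables.py
```

The first script generates a study-shaped cohort (11/12/15 subjects, 9/9/14
paired, 200 metabolites, 10 planted thrombotic-specific and 5 procedural
effects).  The screen then reports:

```
T0: 10 candidates, 10 specific (10/10 planted recovered, 0 false)
T0: procedural metabolites flagged specific: 0/5
```

— all planted thrombotic-specific metabolites pass the dual FDR gate, and
none of the procedural (all-group, lidocaine-like) effects leak through,
because they fail the across-group ANOVA gate.  PLS-DA separates the groups
(`R2Y(2)=0.53` vs a permutation-null 95th percentile of 0.30), and the
classifier on baseline abundances of the 10 candidates reaches

```
pooled CV AUC 1.000, sensitivity 1.00, specificity 1.00
```

(at the planted effect sizes of 2–3 log2 units the baseline task is easy;
the calibration studies below quantify the harder |log2FC| = 2 regime).
The cohort-table script reproduces the published exact-test values from the
printed counts, e.g. heparin use within thrombotic MI (7/9 → 0/9)
`p = 0.0023`, statin use (4/9 → 9/9) `p = 0.0294`, the across-group heparin
change pattern `p = 0.0002`, and history of stroke (0/9, 3/9, 0/14)
`p = 0.0339`.

Library use:

```python
from thrombomet import SimConfig, generate_cohort, run_screen

cohort = generate_cohort(SimConfig(n_metabolites=200, n_specific=10, seed=1))
table = run_screen(cohort.abundance, cohort.subjects, acute="T0")
print(table[table.is_specific].filter(regex="fold_change|q_"))
```

A `thrombomet` CLI wraps the same stages (`simulate`, `screen`, `plsda`,
`classify`, `cohort-stats`, `run`, `export`); `thrombomet run config.yaml
--out run/` executes the full pipeline from a YAML/JSON config and writes a
digest manifest for byte-reproducible re-runs.

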