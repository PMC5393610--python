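#!/usr/bin/env python
"""Baseline (T0) random-forest classifier with recursive halving RFE.

Features are the T0 screen's candidate metabolites; inputs are log2 T0
abundances of all 38 baseline subjects (a patient's own quiescent baseline
is unknown at presentation).  Reports the CV misclassification per panel
size, the chosen panel, pooled out-of-fold AUC / sensitivity / specificity,
and permutation-OOB relative importances; writes results under results/.
"""

import json
from pathlib import Path

import pandas as pd

from thrombomet import ClassifierConfig, baseline_feature_matrix, run_rfe
from thrombomet.preprocess import impute_minimum
from thrombomet.readwrite import read_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"

cohort = read_cohort(RESULTS / "cohort")
screen = pd.read_csv(RESULTS / "screen_T0.csv", index_col=0)
candidates = list(screen.index[screen["is_candidate"]])
planted = set(cohort.truth.index[cohort.truth["effect_class"] == "specific"])

X, y = baseline_feature_matrix(
    impute_minimum(cohort.abundance), cohort.subjects, features=candidates
)
config = ClassifierConfig(n_trees=500, importance="impurity", seed=1)
result = run_rfe(X, y, config=config)

print(f"starting panel: {len(candidates)} candidate metabolites")
print(f"schedule: {result.schedule}")
for size in result.schedule:
    marker = " <- chosen" if size == result.chosen_size else ""
    print(f"  size {size:3d}: CV misclassification {result.cv_misclassification[size]:.3f}, "
          f"AUC {result.cv_auc[size]:.3f}{marker}")
print(f"chosen panel ({result.chosen_size}): {sorted(result.selected_features)}")
print(f"planted metabolites in panel: {len(set(result.selected_features) & planted)}")
print(f"pooled CV AUC {result.auc:.3f}, sensitivity {result.sensitivity:.2f}, "
      f"specificity {result.specificity:.2f}")

(RESULTS / "classifier.json").write_text(json.dumps(result.to_dict(), indent=2) + "\n")
imp = result.importances.rename("relative_importance").to_frame().join(
    cohort.annotation, how="left"
)
imp.to_csv(RESULTS / "classifier_importances.csv")
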