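#!/usr/bin/env python
"""PLS-DA of candidate fold changes with 90% Mahalanobis ellipses.

Supervised projection of the candidate metabolites' intra-subject changes:
reports cumulative R2Y per component, a label-permutation check of the
observed R2Y, and writes scores + ellipse parameters under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from thrombomet import fit_plsda, group_ellipses
from thrombomet.preprocess import compute_fold_changes, impute_minimum, subject_groups
from thrombomet.readwrite import read_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"

cohort = read_cohort(RESULTS / "cohort")
filled = impute_minimum(cohort.abundance)

for acute in ("T0", "T6"):
    screen = pd.read_csv(RESULTS / f"screen_{acute}.csv", index_col=0)
    candidates = screen.index[screen["is_candidate"]]
    fc = compute_fold_changes(filled, cohort.subjects, acute=acute)
    groups = subject_groups(fc, cohort.subjects)
    model = fit_plsda(fc[candidates], groups, n_components=2)

    rng = np.random.default_rng(0)
    null_r2y = [
        fit_plsda(fc[candidates], rng.permutation(groups.to_numpy())).r2y
        for _ in range(50)
    ]
    print(
        f"{acute}: {len(candidates)} candidates, R2Y(1)={model.r2y_cum[0]:.2f}, "
        f"R2Y(2)={model.r2y_cum[1]:.2f} "
        f"(permutation null 95th pct {np.percentile(null_r2y, 95):.2f})"
    )

    scores = pd.DataFrame(model.scores, index=fc.index, columns=["comp_1", "comp_2"])
    scores.insert(0, "group", groups.to_numpy())
    scores.to_csv(RESULTS / f"plsda_scores_{acute}.csv")
    for e in group_ellipses(model, groups.to_numpy(), level=0.90):
        inside = e.contains(model.scores[groups.to_numpy() == e.group]).mean()
        print(f"  {e.group}: ellipse radius {e.radius:.3f}, own-group coverage {inside:.2f}")
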