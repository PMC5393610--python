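"""Calibration and recovery simulation studies over the synthetic cohort.

Each function runs a self-contained Monte-Carlo study at desk scale
(200 metabolites, study-sized groups 11/12/15 with 9/9/14 paired) and
returns a small dict of summaries.  They are the package's evidence that
the screen's dual-FDR gates are calibrated, that planted thrombotic-specific
effects are recovered, that procedural (all-group) artifacts are rejected,
and that the classifier's cross-validated AUC is honest under label
permutation.
"""

from __future__ import annotations

import numpy as np

from .classifier import baseline_feature_matrix, cross_validated_performance, run_rfe
from .config import ClassifierConfig, ScreenConfig, SimConfig
from .screen import run_screen
from .synthetic import generate_cohort

DESK_METABOLITES = 200


def desk_config(seed: int, **overrides) -> SimConfig:
    """Study-sized cohort at the 200-metabolite desk scale."""
    kw = dict(
        n_metabolites=DESK_METABOLITES,
        n_specific=0,
        n_procedural=0,
        seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def _rep_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def null_fdr_calibration(n_reps: int = 200, seed: int = 0, acute: str = "T0") -> dict:
    """Specific-gate false discovery behavior on all-null cohorts.

    With no planted effects every specific flag is a false discovery;
    reports the mean flag count per replicate and the empirical FDR
    (per-replicate FP / max(flags, 1), averaged).
    """
    cfg = ScreenConfig()
    flags, fdrs = [], []
    for s in _rep_seeds(seed, n_reps):
        cohort = generate_cohort(desk_config(s))
        table = run_screen(cohort.abundance, cohort.subjects, acute=acute, config=cfg)
        n_spec = int(table["is_specific"].sum())
        flags.append(n_spec)
        fdrs.append(1.0 if n_spec > 0 else 0.0)
    return {
        "n_reps": n_reps,
        "mean_specific_flags": float(np.mean(flags)),
        "empirical_fdr": float(np.mean(fdrs)),
    }


def screen_recovery(
    n_reps: int = 20,
    seed: int = 0,
    n_specific: int = 10,
    effect_log2fc: float = 2.0,
    acute: str = "T0",
) -> dict:
    """Power/FDR of the specific gate with planted thrombotic-only effects."""
    cfg = ScreenConfig()
    recovered, fdrs = [], []
    for s in _rep_seeds(seed, n_reps):
        cohort = generate_cohort(desk_config(
            s, n_specific=n_specific,
            effect_log2fc_range=(effect_log2fc, effect_log2fc),
        ))
        truth_specific = set(cohort.truth.index[cohort.truth["effect_class"] == "specific"])
        table = run_screen(cohort.abundance, cohort.subjects, acute=acute, config=cfg)
        flagged = set(table.index[table["is_specific"]])
        tp = len(flagged & truth_specific)
        recovered.append(tp)
        fdrs.append((len(flagged) - tp) / max(len(flagged), 1))
    return {
        "n_reps": n_reps,
        "n_planted": n_specific,
        "mean_recovered": float(np.mean(recovered)),
        "empirical_fdr": float(np.mean(fdrs)),
    }


def procedural_rejection(
    n_reps: int = 200,
    seed: int = 0,
    n_procedural: int = 10,
    effect_log2fc: float = 2.0,
    acute: str = "T0",
) -> dict:
    """How often an all-group (procedural) effect leaks through the gate.

    Mirrors the peri-catheterization lidocaine pattern: a large acute change
    shared by every group must fail the across-group ANOVA gate.  Reports
    the per-metabolite specific-flag rate over replicates.
    """
    cfg = ScreenConfig()
    flagged = total = 0
    for s in _rep_seeds(seed, n_reps):
        cohort = generate_cohort(desk_config(
            s, n_procedural=n_procedural,
            effect_log2fc_range=(effect_log2fc, effect_log2fc),
        ))
        proc = cohort.truth.index[cohort.truth["effect_class"] == "procedural"]
        table = run_screen(cohort.abundance, cohort.subjects, acute=acute, config=cfg)
        flagged += int(table.loc[proc, "is_specific"].sum())
        total += len(proc)
    return {
        "n_reps": n_reps,
        "n_procedural_per_rep": n_procedural,
        "specific_flag_rate": flagged / total,
    }


def classifier_recovery(
    n_reps: int = 20,
    seed: int = 0,
    n_specific: int = 10,
    effect_log2fc: float = 2.0,
    panel_size: int = 65,
    n_trees: int = 200,
    importance: str = "impurity",
) -> dict:
    """Feature recovery and CV AUC of the RFE classifier on planted cohorts.

    The starting panel mirrors the published candidate-panel size: the
    planted thrombotic-specific metabolites plus nulls up to ``panel_size``.
    The classifier sees only log2 T0 abundances of all 38 baseline subjects.
    """
    recovered, aucs, chosen_sizes = [], [], []
    for s in _rep_seeds(seed, n_reps):
        cohort = generate_cohort(desk_config(
            s, n_specific=n_specific,
            effect_log2fc_range=(effect_log2fc, effect_log2fc),
        ))
        truth = cohort.truth
        planted = list(truth.index[truth["effect_class"] == "specific"])
        nulls = list(truth.index[truth["effect_class"] == "null"])
        rng = np.random.default_rng(s)
        panel = planted + list(rng.choice(nulls, panel_size - len(planted), replace=False))
        from .preprocess import impute_minimum

        X, y = baseline_feature_matrix(
            impute_minimum(cohort.abundance), cohort.subjects, features=panel
        )
        cfg = ClassifierConfig(n_trees=n_trees, importance=importance, seed=s)
        result = run_rfe(X, y, config=cfg)
        tp = len(set(result.selected_features) & set(planted))
        recovered.append(tp)
        aucs.append(result.auc)
        chosen_sizes.append(result.chosen_size)
    return {
        "n_reps": n_reps,
        "n_planted": n_specific,
        "panel_size": panel_size,
        "mean_recovered": float(np.mean(recovered)),
        "mean_cv_auc": float(np.mean(aucs)),
        "mean_chosen_size": float(np.mean(chosen_sizes)),
    }


def null_classifier_calibration(
    n_reps: int = 100,
    seed: int = 0,
    n_features: int = 20,
    n_trees: int = 100,
) -> dict:
    """Pooled CV AUC under label permutation (must straddle 0.5).

    One null cohort provides the T0 feature matrix; each replicate permutes
    the class labels and re-runs the full cross-validation.
    """
    seeds = _rep_seeds(seed, n_reps + 1)
    cohort = generate_cohort(desk_config(seeds[-1]))
    from .preprocess import impute_minimum

    X, y = baseline_feature_matrix(impute_minimum(cohort.abundance), cohort.subjects)
    X = X.iloc[:, :n_features]
    feats = np.arange(n_features)
    aucs = []
    for s in seeds[:-1]:
        rng = np.random.default_rng(s)
        y_perm = rng.permutation(y)
        cfg = ClassifierConfig(n_trees=n_trees, seed=s)
        perf = cross_validated_performance(X.to_numpy(), y_perm, feats, cfg)
        aucs.append(perf.auc)
    return {"n_reps": n_reps, "mean_auc": float(np.mean(aucs))}
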