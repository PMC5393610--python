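"""Baseline-abundance random-forest classifier with recursive halving RFE.

The clinical question is prospective: at presentation only the enrollment
(T0) abundances exist — a patient's own quiescent baseline is unknowable —
so the classifier consumes log2 T0 abundances of all baseline subjects
(paired and unpaired) and discriminates thrombotic MI from the pooled
controls (non-thrombotic MI + stable CAD).

Feature selection halves the panel recursively: each round drops the
floor(n/2) features with the lowest relative variable importance, giving the
schedule p0, ceil(p0/2), ..., 1.  Stratified 10-fold cross-validation scores
every schedule size; the size minimizing the pooled out-of-fold
misclassification rate (ties to the smaller panel) is chosen.  With the
default ``ranking_scope='per_fold'`` the importance ranking is recomputed
inside each training fold, so the reported performance never sees test-fold
labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold


def rfe_schedule(p0: int) -> list[int]:
    """Panel sizes under recursive halving: p0, ceil(p0/2), ..., 1.

    Each round removes the floor(n/2) lowest-importance features (keeps
    ceil(n/2)); 65 features reach 17 after two rounds.
    """
    if p0 < 1:
        raise ValueError("starting feature count must be >= 1")
    sizes = [int(p0)]
    while sizes[-1] > 1:
        sizes.append((sizes[-1] + 1) // 2)
    return sizes


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def train_rf(X, y, config, seed: int | None = None) -> RandomForestClassifier:
    """Fit a seeded random forest (Gini splits, sqrt features per split)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        criterion="gini",
        bootstrap=True,
        random_state=config.seed if seed is None else seed,
        n_jobs=1,
    )
    model.fit(np.asarray(X, dtype=float), y)
    return model


def oob_indices(tree, n_samples: int) -> np.ndarray:
    """Out-of-bag row indices for one tree of a fitted forest.

    Re-derives the bootstrap draw from the tree's random_state (a uniform
    draw of n indices with replacement), which is exactly how the forest
    sampled it; verified in tests against ``oob_decision_function_``.
    """
    rs = np.random.RandomState(tree.random_state)
    sampled = rs.randint(0, n_samples, n_samples)
    mask = np.ones(n_samples, dtype=bool)
    mask[sampled] = False
    return np.flatnonzero(mask)


def variable_importance(
    model: RandomForestClassifier,
    X,
    y,
    config,
    seed: int | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Per-feature importance scores.

    ``permutation_oob`` (default): mean over trees of the decrease in
    out-of-bag accuracy when the feature is permuted within the OOB rows —
    Breiman's original measure.  ``impurity``: the forest's mean decrease in
    Gini impurity.  Scores are max-normalized to 100 when ``normalize``
    (the conventional "relative importance" scale).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if config.importance == "impurity":
        raw = model.feature_importances_.copy()
    else:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        raw = np.zeros(p)
        n_used = 0
        X32 = X.astype(np.float32)
        classes = model.classes_
        for tree in model.estimators_:
            oob = oob_indices(tree, n)
            if oob.size == 0:
                continue
            n_used += 1
            X_oob = X32[oob]
            y_oob = y[oob]

            def _acc(mat):
                value = tree.tree_.predict(mat).reshape(len(mat), -1)  # class counts
                return (classes[value.argmax(axis=1)] == y_oob).sum()

            base_correct = _acc(X_oob)
            # features never split on in this tree cannot change its output
            used = np.unique(tree.tree_.feature)
            used = used[used >= 0]
            work = X_oob.copy()
            for j in used:
                perm = rng.permutation(oob.size)
                work[:, j] = X_oob[perm, j]
                raw[j] += (base_correct - _acc(work)) / oob.size
                work[:, j] = X_oob[:, j]
        if n_used:
            raw /= n_used
    if not normalize:
        return raw
    top = raw.max()
    return (raw / top * 100.0) if top > 0 else np.zeros(p)


def auc_from_scores(scores, labels) -> float:
    """Midrank (Mann-Whitney) AUC of scores for binary labels (1 = positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required to compute AUC")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class CVPerformance:
    auc: float
    sensitivity: float
    specificity: float
    misclassification: float
    oof_prob: np.ndarray
    oof_pred: np.ndarray
    fold_of: np.ndarray


def _make_folds(y: np.ndarray, config, seed: int):
    classes, counts = np.unique(y, return_counts=True)
    if config.stratified:
        if counts.min() < config.cv_folds:
            raise ValueError(
                f"smallest class has {counts.min()} samples < {config.cv_folds} "
                "folds; use fewer folds"
            )
        kf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    else:
        kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    return list(kf.split(np.zeros_like(y), y))


def cross_validated_performance(X, y, features, config, seed: int | None = None) -> CVPerformance:
    """Pooled out-of-fold CV metrics for a fixed feature subset.

    AUC is computed by midrank from the pooled out-of-fold positive-class
    probabilities; sensitivity/specificity come from the pooled majority-vote
    class predictions (thrombotic = positive).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    feats = np.asarray(features, dtype=int)
    base_seed = config.seed if seed is None else seed
    fold_seed, *fit_seeds = _child_seeds(base_seed, 1 + config.cv_folds)
    folds = _make_folds(y, config, fold_seed)
    prob = np.full(y.size, np.nan)
    pred = np.zeros(y.size, dtype=int)
    fold_of = np.zeros(y.size, dtype=int)
    for k, (train, test) in enumerate(folds):
        model = train_rf(X[np.ix_(train, feats)], y[train], config, seed=fit_seeds[k])
        pos = int(np.flatnonzero(model.classes_ == 1)[0])
        prob[test] = model.predict_proba(X[np.ix_(test, feats)])[:, pos]
        pred[test] = model.predict(X[np.ix_(test, feats)])
        fold_of[test] = k
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    return CVPerformance(
        auc=auc_from_scores(prob, y),
        sensitivity=tp / max(int((y == 1).sum()), 1),
        specificity=tn / max(int((y == 0).sum()), 1),
        misclassification=float((pred != y).mean()),
        oof_prob=prob,
        oof_pred=pred,
        fold_of=fold_of,
    )


def _eliminate(X, y, feats, target_size, config, seed) -> np.ndarray:
    """Drop lowest-importance features until ``target_size`` remain."""
    feats = np.asarray(feats, dtype=int)
    seeds = iter(_child_seeds(seed, 64))
    while feats.size > target_size:
        model = train_rf(X[:, feats], y, config, seed=next(seeds))
        imp = variable_importance(model, X[:, feats], y, config,
                                  seed=next(seeds), normalize=False)
        keep = (feats.size + 1) // 2 if (feats.size + 1) // 2 >= target_size else target_size
        order = np.argsort(-imp, kind="stable")  # ties keep column order
        feats = np.sort(feats[order[:keep]])
    return feats


@dataclass
class ClassifierResult:
    schedule: list
    cv_misclassification: dict  # size -> pooled OOF error
    cv_auc: dict  # size -> pooled OOF AUC
    chosen_size: int
    selected_features: list
    auc: float
    sensitivity: float
    specificity: float
    importances: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def to_dict(self) -> dict:
        return {
            "schedule": list(self.schedule),
            "cv_misclassification": {int(k): float(v) for k, v in self.cv_misclassification.items()},
            "cv_auc": {int(k): float(v) for k, v in self.cv_auc.items()},
            "chosen_size": int(self.chosen_size),
            "selected_features": list(self.selected_features),
            "auc": float(self.auc),
            "sensitivity": float(self.sensitivity),
            "specificity": float(self.specificity),
            "importances": {str(k): float(v) for k, v in self.importances.items()},
        }


def run_rfe(X, y, feature_names=None, config=None) -> ClassifierResult:
    """Recursive halving elimination with cross-validated size selection.

    For each schedule size, every training fold re-ranks and eliminates its
    own features (``per_fold``; ``global`` ranks once on all data), fits a
    forest on the surviving subset, and predicts its test fold; pooled
    out-of-fold misclassification selects the panel size.  The reported
    feature panel is the whole-data elimination at the chosen size, with
    permutation-OOB relative importances from a forest refit on that panel.
    """
    from .config import ClassifierConfig

    config = config or ClassifierConfig()
    Xdf = X if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    config.validate(n_samples=y.size)
    if feature_names is None:
        feature_names = list(Xdf.columns) if Xdf is not None else [
            f"x{j}" for j in range(X.shape[1])
        ]
    feature_names = list(feature_names)
    p0 = X.shape[1]
    schedule = rfe_schedule(p0)

    fold_seed, global_seed, final_seed, *fold_seeds = _child_seeds(
        config.seed, 3 + config.cv_folds
    )
    folds = _make_folds(y, config, fold_seed)

    oof_prob = {size: np.full(y.size, np.nan) for size in schedule}
    oof_pred = {size: np.zeros(y.size, dtype=int) for size in schedule}

    if config.ranking_scope == "global":
        # leakage-prone variant: one whole-data elimination path
        feats = np.arange(p0)
        path = {}
        for size in schedule:
            feats = _eliminate(X, y, feats, size, config, global_seed)
            path[size] = feats
        fit_seeds = _child_seeds(final_seed, len(folds) * len(schedule))
        si = 0
        for k, (train, test) in enumerate(folds):
            for size in schedule:
                feats = path[size]
                model = train_rf(X[np.ix_(train, feats)], y[train], config,
                                 seed=fit_seeds[si])
                si += 1
                pos = int(np.flatnonzero(model.classes_ == 1)[0])
                oof_prob[size][test] = model.predict_proba(X[np.ix_(test, feats)])[:, pos]
                oof_pred[size][test] = model.predict(X[np.ix_(test, feats)])
    else:
        # honest variant: each training fold ranks and eliminates on its own;
        # the per-size fit both predicts the test fold and ranks the next cut
        for k, (train, test) in enumerate(folds):
            seeds = iter(_child_seeds(fold_seeds[k], 2 * len(schedule)))
            feats = np.arange(p0)
            Xtr, ytr = X[train], y[train]
            for i, size in enumerate(schedule):
                model = train_rf(Xtr[:, feats], ytr, config, seed=next(seeds))
                pos = int(np.flatnonzero(model.classes_ == 1)[0])
                oof_prob[size][test] = model.predict_proba(X[np.ix_(test, feats)])[:, pos]
                oof_pred[size][test] = model.predict(X[np.ix_(test, feats)])
                if i + 1 < len(schedule):
                    imp = variable_importance(model, Xtr[:, feats], ytr, config,
                                              seed=next(seeds), normalize=False)
                    order = np.argsort(-imp, kind="stable")  # ties keep column order
                    feats = np.sort(feats[order[: schedule[i + 1]]])

    mis = {s: float((oof_pred[s] != y).mean()) for s in schedule}
    aucs = {s: auc_from_scores(oof_prob[s], y) for s in schedule}
    oof = {s: (oof_prob[s], oof_pred[s]) for s in schedule}
    fit_seeds = _child_seeds(final_seed, 1)
    si = 0

    chosen = min(schedule, key=lambda s: (mis[s], s))
    prob, pred = oof[chosen]
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())

    selected = _eliminate(X, y, np.arange(p0), chosen, config, global_seed)
    final_model = train_rf(X[:, selected], y, config, seed=fit_seeds[si])
    imp_cfg = config
    if config.importance != "permutation_oob":
        from dataclasses import replace
        imp_cfg = replace(config, importance="permutation_oob")
    imp = variable_importance(final_model, X[:, selected], y, imp_cfg, seed=final_seed)
    importances = pd.Series(imp, index=[feature_names[j] for j in selected]).sort_values(
        ascending=False
    )

    return ClassifierResult(
        schedule=schedule,
        cv_misclassification=mis,
        cv_auc=aucs,
        chosen_size=chosen,
        selected_features=[feature_names[j] for j in selected],
        auc=aucs[chosen],
        sensitivity=tp / max(int((y == 1).sum()), 1),
        specificity=tn / max(int((y == 0).sum()), 1),
        importances=importances,
    )


def baseline_feature_matrix(abundance, subjects, features=None) -> tuple[pd.DataFrame, np.ndarray]:
    """Log2 T0 abundances of all baseline subjects, plus binary labels.

    Labels: 1 = thrombotic, 0 = pooled controls.  ``features`` restricts the
    columns (typically the screen's candidate set).
    """
    rows, labels, index = [], [], []
    for _, row in subjects.iterrows():
        sid = row["T0"]
        if pd.isna(sid) or sid not in abundance.index:
            continue
        rows.append(abundance.loc[sid])
        labels.append(1 if row["group"] == "thrombotic" else 0)
        index.append(row["subject_id"])
    Xdf = pd.DataFrame(rows, index=index)
    if features is not None:
        Xdf = Xdf[list(features)]
    return np.log2(Xdf), np.asarray(labels)
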