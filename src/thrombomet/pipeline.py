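"""End-to-end orchestration: simulate/load -> validate -> screen -> PLS-DA ->
classifier -> figure-ready exports, with a reproducible run manifest.

One global seed fans out to per-stage child seeds by a fixed derivation, so
re-running with the same configuration reproduces every output byte for
byte, and disabling a stage never changes upstream outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import baseline_feature_matrix, run_rfe
from .config import ACUTE_TIMEPOINTS, ClassifierConfig, ScreenConfig, SimConfig
from .plsda import fit_plsda, group_ellipses
from .preprocess import compute_fold_changes, impute_minimum, subject_groups, summarize_group_fc
from .readwrite import read_cohort, validate_cohort, write_cohort
from .screen import run_screen
from .synthetic import generate_cohort

log = logging.getLogger(__name__)

STAGES = ("simulate", "validate", "screen", "plsda", "classifier", "export")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunManifest:
    seed: int
    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)  # name -> {outputs, seconds}

    def add_stage(self, name: str, outputs: dict, seconds: float) -> None:
        self.stages[name] = {
            "outputs": {str(p): _sha256(p) for p in outputs.values()},
            "seconds": round(seconds, 3),
        }

    def to_json(self) -> str:
        return json.dumps(
            {"version": self.version, "seed": self.seed,
             "config": self.config, "stages": self.stages},
            indent=2, sort_keys=True,
        )


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage_seeds(seed: int) -> dict:
    state = np.random.SeedSequence(seed).generate_state(len(STAGES)) % (2**31)
    return {name: int(s) for name, s in zip(STAGES, state)}


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    return json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)


def _build_configs(config: dict):
    seed = int(config.get("seed", 0))
    sim_kw = dict(config.get("simulate", {}) or {})
    for key in ("n_per_group", "n_paired", "effect_log2fc_range"):
        if key in sim_kw:
            sim_kw[key] = tuple(sim_kw[key])
    screen_cfg = ScreenConfig(**(config.get("screen", {}) or {}))
    clf_kw = dict(config.get("classifier", {}) or {})
    return seed, sim_kw, screen_cfg, clf_kw


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> RunManifest:
    """Execute the enabled stages of the configuration; write all artifacts.

    ``config`` may be a dict or a path to a YAML/JSON file with blocks
    ``simulate`` / ``input`` / ``screen`` / ``plsda`` / ``classifier`` /
    ``stages`` and a global ``seed``.  Returns the manifest (also written as
    ``manifest.json``).  A failing stage aborts with the stage named; the
    partially written manifest is retained with a ``.partial`` suffix.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = {s: bool(config.get("stages", {}).get(s, True)) for s in STAGES}
    seed, sim_kw, screen_cfg, clf_kw = _build_configs(config)
    seeds = _stage_seeds(seed)
    manifest = RunManifest(seed=seed, config=config)

    current = "simulate"
    try:
        # --- simulate or load --------------------------------------------
        t0 = time.perf_counter()
        if config.get("input"):
            cohort = read_cohort(config["input"])
            sim_config = None
        else:
            sim_kw.setdefault("seed", seeds["simulate"])
            sim_config = SimConfig(**sim_kw)
            cohort = generate_cohort(sim_config)
        if enabled["simulate"]:
            paths = write_cohort(cohort, outdir / "cohort", sim_config)
            manifest.add_stage("simulate", paths, time.perf_counter() - t0)

        # --- validate -----------------------------------------------------
        current = "validate"
        if enabled["validate"]:
            t0 = time.perf_counter()
            report = validate_cohort(cohort.abundance, cohort.subjects, cohort.annotation)
            path = outdir / "validation.json"
            path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
            manifest.add_stage("validate", {"report": path}, time.perf_counter() - t0)

        # --- screen (both acute time points, independent runs) ------------
        current = "screen"
        screens: dict[str, pd.DataFrame] = {}
        filled = impute_minimum(cohort.abundance)
        if enabled["screen"]:
            t0 = time.perf_counter()
            paths = {}
            for acute in ACUTE_TIMEPOINTS:
                table = run_screen(
                    cohort.abundance, cohort.subjects, acute=acute,
                    config=screen_cfg,
                    annotation=cohort.annotation if len(cohort.annotation) else None,
                )
                screens[acute] = table
                path = outdir / f"screen_{acute}.csv"
                table.to_csv(path)
                paths[f"screen_{acute}"] = path
                fc = compute_fold_changes(filled, cohort.subjects, acute=acute)
                fc_path = outdir / f"fold_changes_{acute}.csv"
                fc.to_csv(fc_path)
                paths[f"fold_changes_{acute}"] = fc_path
            manifest.add_stage("screen", paths, time.perf_counter() - t0)

        # --- PLS-DA on the candidate set ----------------------------------
        current = "plsda"
        if enabled["plsda"] and screens:
            t0 = time.perf_counter()
            plsda_cfg = config.get("plsda", {}) or {}
            paths = {}
            for acute, table in screens.items():
                candidates = table.index[table["is_candidate"]]
                if len(candidates) < 2:
                    log.warning("plsda(%s): <2 candidate metabolites, skipped", acute)
                    continue
                fc = compute_fold_changes(filled, cohort.subjects, acute=acute)
                groups = subject_groups(fc, cohort.subjects)
                model = fit_plsda(
                    fc[candidates], groups,
                    n_components=int(plsda_cfg.get("n_components", 2)),
                )
                scores = pd.DataFrame(
                    model.scores, index=fc.index,
                    columns=[f"comp_{a + 1}" for a in range(model.n_components)],
                )
                scores.insert(0, "group", groups.to_numpy())
                path = outdir / f"plsda_scores_{acute}.csv"
                scores.to_csv(path)
                paths[f"plsda_scores_{acute}"] = path
                ellipses = group_ellipses(model, groups, level=float(plsda_cfg.get("level", 0.90)))
                edf = pd.DataFrame([
                    {"group": e.group, "level": e.level, "radius": e.radius,
                     "center_1": e.center[0], "center_2": e.center[1],
                     "cov_11": e.covariance[0, 0], "cov_12": e.covariance[0, 1],
                     "cov_22": e.covariance[1, 1]}
                    for e in ellipses
                ])
                epath = outdir / f"plsda_ellipses_{acute}.csv"
                edf.to_csv(epath, index=False)
                paths[f"plsda_ellipses_{acute}"] = epath
                (outdir / f"plsda_r2y_{acute}.json").write_text(
                    json.dumps({"r2y_cum": list(map(float, model.r2y_cum))}) + "\n"
                )
                paths[f"plsda_r2y_{acute}"] = outdir / f"plsda_r2y_{acute}.json"
            manifest.add_stage("plsda", paths, time.perf_counter() - t0)

        # --- classifier on T0 abundances of candidates --------------------
        current = "classifier"
        if enabled["classifier"] and "T0" in screens:
            t0 = time.perf_counter()
            candidates = list(screens["T0"].index[screens["T0"]["is_candidate"]])
            if len(candidates) >= 2:
                clf_kw.setdefault("seed", seeds["classifier"])
                clf_cfg = ClassifierConfig(**clf_kw)
                X, y = baseline_feature_matrix(filled, cohort.subjects, features=candidates)
                result = run_rfe(X, y, config=clf_cfg)
                path = outdir / "classifier.json"
                path.write_text(json.dumps(result.to_dict(), indent=2) + "\n")
                cv = pd.DataFrame({
                    "size": result.schedule,
                    "cv_misclassification": [result.cv_misclassification[s] for s in result.schedule],
                    "cv_auc": [result.cv_auc[s] for s in result.schedule],
                })
                cv_path = outdir / "classifier_cv.csv"
                cv.to_csv(cv_path, index=False)
                imp = result.importances.rename("relative_importance").to_frame()
                if len(cohort.annotation):
                    imp = imp.join(cohort.annotation, how="left")
                imp_path = outdir / "classifier_importances.csv"
                imp.to_csv(imp_path)
                manifest.add_stage(
                    "classifier",
                    {"classifier": path, "cv": cv_path, "importances": imp_path},
                    time.perf_counter() - t0,
                )
            else:
                log.warning("classifier: <2 candidate metabolites, skipped")

        # --- figure-ready exports -----------------------------------------
        current = "export"
        if enabled["export"] and screens:
            t0 = time.perf_counter()
            paths = {}
            for acute, table in screens.items():
                fc = compute_fold_changes(filled, cohort.subjects, acute=acute)
                for kind in ("radar", "dotplot"):
                    out = export_figure_data(table, fc, cohort.subjects, kind=kind)
                    path = outdir / f"{kind}_{acute}.csv"
                    out.to_csv(path, index=False)
                    paths[f"{kind}_{acute}"] = path
            manifest.add_stage("export", paths, time.perf_counter() - t0)
    except Exception as exc:  # noqa: BLE001 - abort naming the stage
        (outdir / "manifest.json.partial").write_text(manifest.to_json() + "\n")
        raise StageError(current, exc) from exc

    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


def export_figure_data(
    screen: pd.DataFrame,
    fc: pd.DataFrame,
    subjects: pd.DataFrame,
    kind: str = "radar",
) -> pd.DataFrame:
    """Figure-ready CSV exports from screen results.

    ``radar``: per candidate metabolite, each group's mean log2 fold change
    expressed relative to the stable-CAD group (stable is 0 by
    construction).  ``dotplot``: subject-level fold changes for the specific
    metabolites (one row per subject x metabolite).
    """
    if kind == "radar":
        candidates = screen.index[screen["is_candidate"]]
        if len(candidates) == 0:
            return pd.DataFrame(columns=["metabolite_id", "group", "log2_fc_vs_stable"])
        summary = summarize_group_fc(fc[candidates], subjects)
        stable = summary[summary["group"] == "stable"].set_index("metabolite_id")["mean_log2_fc"]
        summary["log2_fc_vs_stable"] = (
            summary["mean_log2_fc"] - summary["metabolite_id"].map(stable).to_numpy()
        )
        return summary[["metabolite_id", "group", "log2_fc_vs_stable"]]
    if kind == "dotplot":
        specific = screen.index[screen["is_specific"]]
        rows = []
        groups = subject_groups(fc, subjects)
        for m in specific:
            for sid, value in fc[m].items():
                rows.append({
                    "metabolite_id": m, "subject_id": sid,
                    "group": groups[sid], "log2_fc": value,
                })
        return pd.DataFrame(rows, columns=["metabolite_id", "subject_id", "group", "log2_fc"])
    raise ValueError("kind must be 'radar' or 'dotplot'")
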