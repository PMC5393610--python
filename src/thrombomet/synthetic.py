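"""Synthetic plasma-metabolomics cohort with planted ground truth.

The generator emulates the statistical skeleton of a three-group cardiac
cohort (thrombotic MI, non-thrombotic MI, stable CAD) sampled at enrollment
(T0), six hours (T6), and a quiescent follow-up (Q).  Metabolites fall into
three effect classes:

* ``specific``   — acute log2 shift planted in the thrombotic group only
  (the biology the screen is built to find);
* ``procedural`` — identical acute shift in all three groups (the
  lidocaine-like catheterization artifact the across-group gate must reject);
* ``null``       — no planted effect.

Every random draw flows from a single :class:`~thrombomet.config.SimConfig`
seed, so identical configs give byte-identical tables.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import ACUTE_TIMEPOINTS, GROUPS, TIMEPOINTS, SimConfig

log = logging.getLogger(__name__)

EFFECT_CLASSES = ("specific", "procedural", "null")


class Cohort(NamedTuple):
    """Bundle of the four generated tables."""

    abundance: pd.DataFrame  # samples x metabolites, natural scale, NaN = censored
    subjects: pd.DataFrame  # subject_id, group, T0/T6/Q sample ids
    annotation: pd.DataFrame  # metabolite annotation incl. family block
    truth: pd.DataFrame  # planted effect class and per-group delta


def _metabolite_ids(p: int) -> list[str]:
    width = max(4, len(str(p)))
    return [f"M{i + 1:0{width}d}" for i in range(p)]


def generate_cohort(config: SimConfig) -> Cohort:
    """Draw a full cohort; see the module docstring for the abundance model.

    Returns abundance on the natural (anti-logged) scale with left-censored
    values as NaN, a subject table mapping subjects to their available sample
    ids, a minimal annotation table (family blocks double as "sub pathway"),
    and the truth table of planted per-group log2 effects.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    p = config.n_metabolites
    met_ids = _metabolite_ids(p)
    n_families = -(-p // config.family_block_size)
    family = np.arange(p) // config.family_block_size

    # --- planted effects -------------------------------------------------
    lo, hi = config.effect_log2fc_range
    n_eff = config.n_specific + config.n_procedural
    eff_idx = rng.choice(p, size=n_eff, replace=False)
    spec_idx = eff_idx[: config.n_specific]
    proc_idx = eff_idx[config.n_specific :]
    magnitude = rng.uniform(lo, hi, size=n_eff)
    sign = rng.choice([-1.0, 1.0], size=n_eff)
    delta = np.zeros((p, len(GROUPS)))  # per metabolite, per group, log2
    delta[spec_idx, 0] = (sign * magnitude)[: config.n_specific]
    for g in range(len(GROUPS)):
        delta[proc_idx, g] = (sign * magnitude)[config.n_specific :]

    effect_class = np.full(p, "null", dtype=object)
    # zero-magnitude "effects" (e.g. effect range forced to (0, 0)) are nulls
    planted = np.abs(delta).sum(axis=1) > 0
    effect_class[spec_idx[planted[spec_idx]]] = "specific"
    effect_class[proc_idx[planted[proc_idx]]] = "procedural"

    truth = pd.DataFrame(
        {
            "metabolite_id": met_ids,
            "effect_class": effect_class,
            **{f"delta_{g}": delta[:, gi] for gi, g in enumerate(GROUPS)},
        }
    ).set_index("metabolite_id")

    mu = rng.normal(config.baseline_log2_mean, config.sigma_metabolite, size=p)

    # --- subjects and samples --------------------------------------------
    subj_rows = []
    for gi, group in enumerate(GROUPS):
        for i in range(config.n_per_group[gi]):
            sid = f"{group}_{i + 1:02d}"
            paired = i < config.n_paired[gi]
            tps = TIMEPOINTS if paired else ACUTE_TIMEPOINTS
            subj_rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    **{t: (f"{sid}_{t}" if t in tps else pd.NA) for t in TIMEPOINTS},
                }
            )
    subjects = pd.DataFrame(subj_rows)

    rho = config.family_rho
    sq_rho, sq_one = np.sqrt(rho), np.sqrt(1.0 - rho)

    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    for row in subj_rows:
        gi = GROUPS.index(row["group"])
        # time-invariant subject effect, family-correlated
        fam_u = rng.standard_normal(n_families)
        u = config.sigma_subject * (sq_rho * fam_u[family] + sq_one * rng.standard_normal(p))
        for t in TIMEPOINTS:
            if pd.isna(row[t]):
                continue
            fam_e = rng.standard_normal(n_families)
            eps = config.sigma_residual * (
                sq_rho * fam_e[family] + sq_one * rng.standard_normal(p)
            )
            log2x = mu + u + eps
            if t in ACUTE_TIMEPOINTS:
                log2x = log2x + delta[:, gi]
            sample_ids.append(row[t])
            rows.append(np.exp2(log2x))

    abundance = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=met_ids)
    abundance.index.name = "sample_id"
    abundance.columns.name = "metabolite_id"

    annotation = pd.DataFrame(
        {
            "metabolite_id": met_ids,
            "biochemical_name": [f"synthetic metabolite {m}" for m in met_ids],
            "super_pathway": "Synthetic",
            "sub_pathway": [f"family_{f:03d}" for f in family],
            "platform": "SIM",
            "retention_index": np.round(np.linspace(500, 7000, p), 1),
            "mass": np.round(mu * 20.0, 4),  # arbitrary but deterministic
        }
    ).set_index("metabolite_id")

    if config.censor_quantile > 0:
        abundance = censor_below_lod(abundance, config.censor_quantile)

    return Cohort(abundance, subjects, annotation, truth)


def censor_below_lod(table: pd.DataFrame, quantile: float) -> pd.DataFrame:
    """Left-censor each metabolite at its empirical detection-limit quantile.

    For a metabolite with ``n`` observed values, the ``floor(quantile * n)``
    lowest observations are replaced by NaN; ties are broken by stable rank
    (row order), so an all-equal column still censors exactly that count.
    The input is not modified.
    """
    if not 0.0 <= quantile < 1.0:
        raise ValueError("quantile must be in [0, 1)")
    out = table.copy()
    if quantile == 0.0:
        return out
    values = out.to_numpy(dtype=float, copy=True)
    for j in range(values.shape[1]):
        col = values[:, j]
        obs = np.flatnonzero(~np.isnan(col))
        k = int(np.floor(quantile * obs.size))
        if k == 0:
            continue
        order = obs[np.argsort(col[obs], kind="stable")]
        col[order[:k]] = np.nan
    out.iloc[:, :] = values
    return out
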