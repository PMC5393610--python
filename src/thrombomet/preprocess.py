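"""Imputation, QC summaries, and intra-subject fold changes.

The fold-change matrix ``r[s, m] = log2(x[s, m, acute] / x[s, m, Q])`` is the
quantity every downstream stage consumes: each subject serves as their own
control, which removes time-invariant subject effects (age, sex, chronic
medication, baseline metabotype) by construction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import GROUPS

log = logging.getLogger(__name__)


def impute_minimum(abundance: pd.DataFrame) -> pd.DataFrame:
    """Replace missing cells with that metabolite's minimum observed value.

    Conventional detection-limit imputation for LC/GC-MS abundance tables:
    a non-detect is assumed to sit at or below the lowest detected level.
    Raises if a metabolite has no observed value at all.
    """
    all_missing = abundance.columns[abundance.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(
            f"metabolite(s) with no observed values: {list(all_missing[:5])}"
        )
    return abundance.fillna(abundance.min(axis=0))


def compute_fold_changes(
    abundance: pd.DataFrame,
    subjects: pd.DataFrame,
    acute: str = "T0",
) -> pd.DataFrame:
    """Per-subject log2(acute / quiescent) ratios for one acute time point.

    Only subjects with both the acute and the Q sample contribute a row;
    excluded subjects are logged.  Requires a fully imputed, strictly
    positive abundance table (log2 of zero is undefined).
    """
    if acute not in ("T0", "T6"):
        raise ValueError(f"acute time point must be 'T0' or 'T6', got {acute!r}")
    if abundance.isna().any().any():
        raise ValueError("abundance contains missing values; impute first")
    if (abundance.to_numpy() <= 0).any():
        raise ValueError("abundance must be strictly positive to take log2")

    rows, index, skipped = [], [], []
    for _, row in subjects.iterrows():
        sid_a, sid_q = row[acute], row["Q"]
        if pd.isna(sid_a) or pd.isna(sid_q) or sid_a not in abundance.index or sid_q not in abundance.index:
            skipped.append(row["subject_id"])
            continue
        rows.append(
            np.log2(abundance.loc[sid_a].to_numpy() / abundance.loc[sid_q].to_numpy())
        )
        index.append(row["subject_id"])
    if skipped:
        log.info("%d subject(s) lack a paired %s/Q sample: %s", len(skipped), acute, skipped)
    fc = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, abundance.shape[1])),
                      index=index, columns=abundance.columns)
    fc.index.name = "subject_id"
    fc.attrs["acute"] = acute
    return fc


def subject_groups(fc: pd.DataFrame, subjects: pd.DataFrame) -> pd.Series:
    """Group label for each fold-change row, in row order."""
    lookup = subjects.set_index("subject_id")["group"]
    return lookup.reindex(fc.index)


def summarize_group_fc(
    fc: pd.DataFrame,
    subjects: pd.DataFrame,
    method: str = "geometric",
) -> pd.DataFrame:
    """Per-metabolite, per-group mean fold change on the ratio scale.

    ``geometric`` (default) back-transforms the mean of log2 ratios,
    2**mean(r) — the estimate the log2-scale linear model actually fits.
    ``arithmetic`` averages the raw ratios instead.  The standard error is
    always that of the mean log2 change (sample sd, n-1).
    """
    if method not in ("geometric", "arithmetic"):
        raise ValueError("method must be 'geometric' or 'arithmetic'")
    groups = subject_groups(fc, subjects)
    out = []
    for g in GROUPS:
        sub = fc.loc[(groups == g).to_numpy()]
        n = len(sub)
        if 0 < n < 2:
            raise ValueError(f"group {g!r} has fewer than 2 paired subjects")
        if n == 0:
            continue
        mean_log2 = sub.mean(axis=0)
        ratio = (
            np.exp2(mean_log2) if method == "geometric"
            else np.exp2(sub).mean(axis=0)
        )
        out.append(pd.DataFrame({
            "metabolite_id": fc.columns,
            "group": g,
            "n": n,
            "mean_log2_fc": mean_log2.to_numpy(),
            "fold_change": ratio.to_numpy(),
            "se_log2_fc": (sub.std(axis=0, ddof=1) / np.sqrt(n)).to_numpy(),
        }))
    return pd.concat(out, ignore_index=True)


def median_rsd(abundance: pd.DataFrame, metabolites=None) -> float:
    """Median over metabolites of sd/mean (raw scale, observed values only).

    The standard QC summary: computed over internal standards it measures
    instrument variability, over endogenous metabolites total process
    variability.
    """
    sub = abundance if metabolites is None else abundance[list(metabolites)]
    if sub.shape[1] == 0:
        raise ValueError("empty metabolite subset")
    counts = sub.notna().sum(axis=0)
    means = sub.mean(axis=0)
    if (counts < 2).any() or (means <= 0).any():
        bad = sub.columns[(counts < 2) | (means <= 0)][0]
        raise ValueError(f"metabolite {bad!r} needs >=2 observed values with positive mean")
    rsd = sub.std(axis=0, ddof=1) / means
    return float(rsd.median())
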