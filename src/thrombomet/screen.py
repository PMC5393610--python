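"""Per-metabolite differential-change statistics and dual-FDR qualification.

For each metabolite the subject-level log2 fold changes are regressed on
study-group indicators (a cell-means one-way layout), giving

* the omnibus ANOVA F test of equal group mean changes,
* pooled-variance pairwise contrasts (unadjusted post-hoc t tests), and
* a one-sample t test of the thrombotic mean change against zero, using the
  thrombotic group's own variance.

Two Storey q-value families (ANOVA and within-thrombotic, each across all
non-degenerate metabolites) feed the gates:

* candidate — both q-values < 10% (the set feeding multivariate analyses);
* specific  — both q-values < 5% and both thrombotic-vs-control post-hoc
  contrasts significant at alpha = 5%.

A metabolite with equal planted change in every group (a procedural artifact
such as peri-catheterization lidocaine) fails the ANOVA gate no matter how
large its within-group change — that is the design's confounder rejection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import GROUPS, ScreenConfig
from .preprocess import compute_fold_changes, impute_minimum, subject_groups

log = logging.getLogger(__name__)

#: post-hoc contrast columns, in report order
CONTRASTS = (
    ("thrombotic", "non_thrombotic"),
    ("thrombotic", "stable"),
    ("non_thrombotic", "stable"),
)


@dataclass
class GroupModelFit:
    """Vectorized one-way fit across all metabolites."""

    metabolite_ids: np.ndarray
    group_order: tuple
    n_per_group: np.ndarray  # (G,)
    group_means: np.ndarray  # (G, p)
    mse: np.ndarray  # pooled residual variance, (p,)
    f_stat: np.ndarray
    p_anova: np.ndarray
    p_contrast: dict  # (a, b) -> (p,) two-sided pooled-variance t
    p_within: np.ndarray  # thrombotic one-sample t vs 0
    zero_variance: np.ndarray  # bool mask, degenerate fits


def fit_group_model(fc: pd.DataFrame, groups: pd.Series | np.ndarray) -> GroupModelFit:
    """Cell-means linear model of log2 fold change on group indicators.

    Vectorized over metabolites.  Degenerate metabolites (zero pooled
    residual variance) get p = 1 when the means also agree, p = 0 with a
    warning otherwise, and are flagged for exclusion from q-value families.
    """
    groups = np.asarray(groups)
    R = fc.to_numpy(dtype=float)
    n, p = R.shape
    present = [g for g in GROUPS if (groups == g).sum() > 0]
    if len(present) < 2:
        raise ValueError("need at least two study groups")
    masks = {g: groups == g for g in present}
    sizes = np.array([masks[g].sum() for g in present])
    if (sizes < 2).any():
        small = [g for g, s in zip(present, sizes) if s < 2]
        raise ValueError(f"group(s) with fewer than 2 subjects: {small}")

    means = np.vstack([R[masks[g]].mean(axis=0) for g in present])  # (G, p)
    ssw = np.zeros(p)
    for gi, g in enumerate(present):
        ssw += ((R[masks[g]] - means[gi]) ** 2).sum(axis=0)
    dfw = n - len(present)
    dfb = len(present) - 1
    grand = R.mean(axis=0)
    ssb = (sizes[:, None] * (means - grand) ** 2).sum(axis=0)
    mse = ssw / dfw
    zero_var = np.isclose(ssw, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ssb / dfb) / mse
    p_anova = np.empty(p)
    ok = ~zero_var
    p_anova[ok] = stats.f.sf(f_stat[ok], dfb, dfw)
    # degenerate: all residuals zero
    deg_equal = zero_var & np.isclose(ssb, 0.0)
    deg_diff = zero_var & ~np.isclose(ssb, 0.0)
    f_stat[deg_equal] = 0.0
    p_anova[deg_equal] = 1.0
    f_stat[deg_diff] = np.inf
    p_anova[deg_diff] = 0.0
    if deg_diff.any():
        warnings.warn(
            f"{int(deg_diff.sum())} metabolite(s) with zero residual variance "
            "but unequal group means; p reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )

    gi_of = {g: i for i, g in enumerate(present)}
    p_contrast = {}
    for a, b in CONTRASTS:
        if a not in gi_of or b not in gi_of:
            continue
        na, nb = sizes[gi_of[a]], sizes[gi_of[b]]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (means[gi_of[a]] - means[gi_of[b]]) / np.sqrt(mse * (1 / na + 1 / nb))
        pc = np.empty(p)
        pc[ok] = 2 * stats.t.sf(np.abs(t[ok]), dfw)
        diff0 = np.isclose(means[gi_of[a]], means[gi_of[b]])
        pc[zero_var] = np.where(diff0[zero_var], 1.0, 0.0)
        p_contrast[(a, b)] = pc

    # within-thrombotic one-sample test, own variance
    if "thrombotic" in masks:
        T = R[masks["thrombotic"]]
        nt = T.shape[0]
        m_t = T.mean(axis=0)
        sd_t = T.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_w = m_t / (sd_t / np.sqrt(nt))
        p_within = 2 * stats.t.sf(np.abs(t_w), nt - 1)
        sd0 = np.isclose(sd_t, 0.0)
        p_within[sd0] = np.where(np.isclose(m_t[sd0], 0.0), 1.0, 0.0)
    else:
        p_within = np.full(p, np.nan)

    return GroupModelFit(
        metabolite_ids=fc.columns.to_numpy(),
        group_order=tuple(present),
        n_per_group=sizes,
        group_means=means,
        mse=mse,
        f_stat=f_stat,
        p_anova=p_anova,
        p_contrast=p_contrast,
        p_within=p_within,
        zero_variance=zero_var,
    )


def estimate_pi0(p: np.ndarray, lam: np.ndarray) -> float:
    """Storey's proportion of true nulls, smoothed over the lambda grid.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)); the trend is smoothed by
    a cubic least-squares polynomial and read off at the largest lambda, then
    clamped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    lam = np.asarray(sorted(set(np.asarray(lam, dtype=float))))
    if lam.size == 1:
        pi0 = (p > lam[0]).sum() / (m * (1.0 - lam[0]))
        return float(min(max(pi0, 1.0 / m), 1.0))
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    deg = min(3, lam.size - 1)
    coef = np.polynomial.polynomial.polyfit(lam, pi0_lam, deg)
    pi0 = float(np.polynomial.polynomial.polyval(lam.max(), coef))
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalues(
    p,
    config: ScreenConfig | None = None,
    pi0: float | None = None,
) -> np.ndarray:
    """Storey q-values: q_i = min_{p_j >= p_i} pi0 * m * p_j / rank_j.

    With ``pi0_method='fixed_1'`` (or pi0=1) this is exactly the
    Benjamini-Hochberg adjusted p-value.
    """
    config = config or ScreenConfig()
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        if config.pi0_method == "fixed_1":
            pi0 = 1.0
        else:
            pi0 = estimate_pi0(p, np.asarray(config.qvalue_lambda))
    if not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def qualify(screen: pd.DataFrame, config: ScreenConfig | None = None) -> pd.DataFrame:
    """Attach is_candidate / is_specific flags from the dual-FDR gates."""
    config = config or ScreenConfig()
    config.validate()
    out = screen.copy()
    q_a, q_w = out["q_anova"], out["q_within"]
    out["is_candidate"] = (
        (q_a < config.candidate_fdr) & (q_w < config.candidate_fdr)
    ).fillna(False)
    out["is_specific"] = (
        (q_a < config.specific_fdr)
        & (q_w < config.specific_fdr)
        & (out["p_thrombotic_vs_non_thrombotic"] < config.posthoc_alpha)
        & (out["p_thrombotic_vs_stable"] < config.posthoc_alpha)
    ).fillna(False)
    return out


def screen_fold_changes(
    fc: pd.DataFrame,
    groups,
    config: ScreenConfig | None = None,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Screen an already-computed fold-change matrix; see module docstring."""
    config = config or ScreenConfig()
    config.validate()
    fit = fit_group_model(fc, groups)
    rows = {"metabolite_id": fit.metabolite_ids}
    for gi, g in enumerate(fit.group_order):
        rows[f"mean_log2_fc_{g}"] = fit.group_means[gi]
        rows[f"fold_change_{g}"] = np.exp2(fit.group_means[gi])
    rows["f_anova"] = fit.f_stat
    rows["p_anova"] = fit.p_anova
    for (a, b), pc in fit.p_contrast.items():
        rows[f"p_{a}_vs_{b}"] = pc
    rows["p_within"] = fit.p_within
    rows["zero_variance"] = fit.zero_variance
    table = pd.DataFrame(rows).set_index("metabolite_id")

    # q-value families over non-degenerate metabolites only
    ok = ~fit.zero_variance
    for src, dst in (("p_anova", "q_anova"), ("p_within", "q_within")):
        q = np.full(len(table), np.nan)
        q[ok] = storey_qvalues(table[src].to_numpy()[ok], config)
        table[dst] = q

    table = qualify(table, config)
    if annotation is not None:
        table = table.join(annotation, how="left")
    table = table.sort_values("p_anova", kind="stable")
    log.info(
        "screen: %d metabolites, %d candidates, %d specific",
        len(table), int(table["is_candidate"].sum()), int(table["is_specific"].sum()),
    )
    return table


def run_screen(
    abundance: pd.DataFrame,
    subjects: pd.DataFrame,
    acute: str = "T0",
    config: ScreenConfig | None = None,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Impute, form intra-subject fold changes, and screen (one acute point).

    Returns one row per metabolite with the group mean fold changes
    (ratio scale and log2), ANOVA F/p/q, unadjusted post-hoc contrast p's,
    the within-thrombotic p/q, and the candidate/specific flags, sorted by
    ANOVA p.
    """
    filled = impute_minimum(abundance)
    fc = compute_fold_changes(filled, subjects, acute=acute)
    groups = subject_groups(fc, subjects)
    table = screen_fold_changes(fc, groups, config, annotation)
    table.attrs["acute"] = acute
    return table
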