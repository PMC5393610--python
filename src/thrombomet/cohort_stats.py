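"""Exact contingency-table tests and group comparisons for cohort tables.

The exact r x c test (Freeman-Halton extension of Fisher's test) enumerates
every table with the observed margins and sums the multivariate
hypergeometric probability of those no more probable than the observed table
(the probability-mass two-sided definition).  A 2 x 2 input reduces to the
classical Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

#: relative tolerance absorbing float noise when comparing table probabilities
TIE_RTOL = 1e-7

#: enumeration guard; beyond this many tables, request Monte Carlo explicitly
MAX_TABLES = 10_000_000


def _as_int_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded):
            raise ValueError("contingency table entries must be integers")
        arr = rounded.astype(np.int64)
    if (arr < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    if arr.sum() == 0:
        raise ValueError("contingency table total must be positive")
    return arr.astype(np.int64)


class _Enumerator:
    """Depth-first enumeration of tables with fixed margins."""

    def __init__(self, row_sums, col_sums, log_const, logp_cut, max_tables):
        self.row_sums = row_sums
        self.col_sums = col_sums
        self.log_const = log_const
        self.logp_cut = logp_cut
        self.max_tables = max_tables
        self.n_tables = 0
        self.p_tail = 0.0
        self.p_total = 0.0

    def run(self):
        self._rec(0, self.col_sums.copy(), 0.0)

    def _rec(self, r, col_rem, log_fact_acc):
        rows_left = len(self.row_sums) - r
        if rows_left == 1:
            # last row forced by the column remainders
            logp = self.log_const - log_fact_acc - gammaln(col_rem + 1).sum()
            self.n_tables += 1
            if self.n_tables > self.max_tables:
                raise ValueError(
                    f"more than {self.max_tables} tables with these margins; "
                    "use method='monte_carlo'"
                )
            prob = np.exp(logp)
            self.p_total += prob
            if logp <= self.logp_cut:
                self.p_tail += prob
            return
        target = self.row_sums[r]
        c = len(col_rem)

        def fill(j, remaining, acc):
            if j == c - 1:
                if remaining <= col_rem[j]:
                    col_rem[j] -= remaining
                    self._rec(r + 1, col_rem, acc + gammaln(remaining + 1))
                    col_rem[j] += remaining
                return
            hi = min(remaining, col_rem[j])
            for v in range(hi + 1):
                col_rem[j] -= v
                fill(j + 1, remaining - v, acc + gammaln(v + 1))
                col_rem[j] += v

        fill(0, target, log_fact_acc)


@dataclass
class ExactTestResult:
    p_value: float
    p_observed: float
    n_tables: int
    p_total: float  # sanity: sums to 1 over the enumeration

    def __float__(self) -> float:
        return self.p_value


def _log_prob_table(arr, log_const) -> float:
    return float(log_const - gammaln(arr + 1).sum())


def fisher_exact_rxc(
    table,
    method: str = "exact",
    n_mc: int = 100_000,
    seed: int = 0,
    max_tables: int = MAX_TABLES,
) -> ExactTestResult:
    """Freeman-Halton exact test for an r x c table.

    ``exact`` enumerates all tables with the observed margins (guarded at
    ``max_tables``); ``monte_carlo`` estimates the same tail by sampling
    tables from the margins-fixed null with Patefield's algorithm.
    """
    arr = _as_int_table(table)
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    N = arr.sum()
    log_const = (
        gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum() - gammaln(N + 1)
    )
    logp_obs = _log_prob_table(arr, log_const)
    logp_cut = logp_obs + np.log1p(TIE_RTOL)

    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        sampler = stats.random_table(row_sums, col_sums)
        samples = sampler.rvs(n_mc, random_state=rng)
        logps = log_const - gammaln(samples + 1).sum(axis=(1, 2))
        p = float((logps <= logp_cut).mean())
        return ExactTestResult(p, float(np.exp(logp_obs)), n_mc, float("nan"))
    if method != "exact":
        raise ValueError("method must be 'exact' or 'monte_carlo'")

    enum = _Enumerator(row_sums, col_sums, log_const, logp_cut, max_tables)
    enum.run()
    return ExactTestResult(
        p_value=min(enum.p_tail, 1.0),
        p_observed=float(np.exp(logp_obs)),
        n_tables=enum.n_tables,
        p_total=enum.p_total,
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2 x 2 table (probability-mass rule)."""
    arr = _as_int_table(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2 x 2 table")
    return fisher_exact_rxc(arr).p_value


def group_continuous_test(values, groups, method: str = "anova"):
    """Across-group test of a continuous variable.

    ``anova``: one-way F test; ``welch``: Welch's heteroscedastic ANOVA;
    ``kruskal``: tie-corrected Kruskal-Wallis H with chi-square reference.
    Returns (statistic, p).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    samples = [values[groups == g] for g in levels]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    min_n = 1 if method == "kruskal" else 2
    if any(len(s) < min_n for s in samples):
        raise ValueError(f"each group needs >= {min_n} values for {method}")
    if method == "anova":
        res = stats.f_oneway(*samples)
        return float(res.statistic), float(res.pvalue)
    if method == "kruskal":
        res = stats.kruskal(*samples)
        return float(res.statistic), float(res.pvalue)
    if method == "welch":
        n = np.array([len(s) for s in samples], dtype=float)
        v = np.array([np.var(s, ddof=1) for s in samples])
        if (v <= 0).any():
            raise ValueError("welch ANOVA undefined with a zero-variance group")
        w = n / v
        k = len(samples)
        m = np.array([s.mean() for s in samples])
        grand = (w * m).sum() / w.sum()
        a = (w * (m - grand) ** 2).sum() / (k - 1)
        resid = ((1 - w / w.sum()) ** 2 / (n - 1)).sum()
        b = 1 + 2 * (k - 2) / (k**2 - 1) * resid
        f = a / b
        df2 = (k**2 - 1) / (3 * resid)
        return float(f), float(stats.f.sf(f, k - 1, df2))
    raise ValueError("method must be 'anova', 'welch', or 'kruskal'")


@dataclass
class MedicationChangeSummary:
    per_group: pd.DataFrame  # medication, group, n, n_before, n_after, p_within
    across_groups: pd.DataFrame  # medication, p_across
    change_tables: dict = field(default_factory=dict)  # medication -> DataFrame


def medication_change_summary(
    subjects: pd.DataFrame,
    before: pd.DataFrame,
    after: pd.DataFrame,
    paired: bool = False,
) -> MedicationChangeSummary:
    """Enrollment-vs-follow-up medication use, within and across groups.

    ``before``/``after`` are subject x medication boolean tables.  The
    within-group p contrasts the two time points' use counts with the 2 x 2
    exact test treating time points as independent samples (the convention
    that reproduces the published within-group values); ``paired=True``
    substitutes the exact McNemar test on the discordant pairs.  The
    across-group p applies the exact r x c test to the group x change
    category ({started, stopped, unchanged}) table, empty categories
    dropped.
    """
    meds = [m for m in before.columns if m in after.columns]
    group_of = subjects.set_index("subject_id")["group"]
    shared = [s for s in before.index if s in after.index and s in group_of.index]
    levels = list(pd.unique(group_of.loc[shared]))

    per_rows, across_rows, change_tables = [], [], {}
    for med in meds:
        change_counts = {}
        for g in levels:
            subs = [s for s in shared if group_of[s] == g]
            b = before.loc[subs, med].astype(bool)
            a = after.loc[subs, med].astype(bool)
            n = len(subs)
            if paired:
                b01 = int((b & ~a).sum())  # stopped
                b10 = int((~b & a).sum())  # started
                from statsmodels.stats.contingency_tables import mcnemar

                tbl = [[int((b & a).sum()), b01], [b10, int((~b & ~a).sum())]]
                p_within = float(mcnemar(tbl, exact=True).pvalue)
            else:
                tbl = [[int(b.sum()), n - int(b.sum())],
                       [int(a.sum()), n - int(a.sum())]]
                p_within = fisher_exact_2x2(tbl)
            per_rows.append({
                "medication": med, "group": g, "n": n,
                "n_before": int(b.sum()), "n_after": int(a.sum()),
                "p_within": p_within,
            })
            change_counts[g] = {
                "started": int((~b & a).sum()),
                "stopped": int((b & ~a).sum()),
                "unchanged": int((b == a).sum()),
            }
        change = pd.DataFrame(change_counts).T[["started", "stopped", "unchanged"]]
        change = change.loc[:, (change.sum(axis=0) > 0)]
        change_tables[med] = change
        if change.shape[1] >= 2:
            p_across = fisher_exact_rxc(change.to_numpy()).p_value
        else:
            p_across = 1.0  # everyone in one change category
        across_rows.append({"medication": med, "p_across": p_across})

    return MedicationChangeSummary(
        per_group=pd.DataFrame(per_rows),
        across_groups=pd.DataFrame(across_rows),
        change_tables=change_tables,
    )
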