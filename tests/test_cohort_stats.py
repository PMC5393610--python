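"""Exact contingency tests vs enumeration/scipy oracles; group tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from thrombomet import (
    fisher_exact_2x2,
    fisher_exact_rxc,
    group_continuous_test,
    medication_change_summary,
)
from thrombomet.study_tables import STROKE_HISTORY, within_group_table


class TestFisher2x2:
    def test_published_heparin_value(self):
        # 7/9 on heparin at enrollment, 0/9 at follow-up: prints as 0.002
        p = fisher_exact_2x2(within_group_table("heparin", "thrombotic"))
        assert p == pytest.approx(2 * 36 / 31824, rel=1e-9)  # 2 C(9,7)/C(18,7)
        assert round(p, 3) == 0.002

    def test_published_statin_value(self):
        p = fisher_exact_2x2(within_group_table("statins", "thrombotic"))
        assert round(p, 2) == 0.03
        assert p == pytest.approx(0.0294118, abs=5e-7)

    def test_identical_rows_give_one(self):
        assert fisher_exact_2x2(within_group_table("aspirin", "thrombotic")) == 1.0

    def test_matches_scipy_two_sided(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            table = rng.integers(0, 12, size=(2, 2))
            if table.sum() == 0 or (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
                continue
            ours = fisher_exact_2x2(table)
            ref = stats.fisher_exact(table)[1]
            assert ours == pytest.approx(ref, rel=1e-6)

    def test_symmetric_under_row_and_column_swaps(self):
        t = np.array([[7, 2], [1, 8]])
        p = fisher_exact_2x2(t)
        assert fisher_exact_2x2(t[::-1]) == pytest.approx(p, rel=1e-12)
        assert fisher_exact_2x2(t[:, ::-1]) == pytest.approx(p, rel=1e-12)
        assert fisher_exact_2x2(t.T) == pytest.approx(p, rel=1e-12)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            fisher_exact_2x2([[1.5, 2], [3, 4]])


def _brute_force_rxc(table):
    """Enumerate every non-negative matrix with the observed margins."""
    table = np.asarray(table)
    row_sums, col_sums = table.sum(1), table.sum(0)
    log_const = gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum() - gammaln(table.sum() + 1)

    def prob(cells):
        return np.exp(log_const - gammaln(np.asarray(cells) + 1).sum())

    def rows(r, cols_left):
        if r == len(row_sums) - 1:
            if all(c >= 0 for c in cols_left):
                yield (tuple(cols_left),)
            return
        for combo in itertools.product(*(range(min(row_sums[r], c) + 1) for c in cols_left)):
            if sum(combo) == row_sums[r]:
                for rest in rows(r + 1, [c - v for c, v in zip(cols_left, combo)]):
                    yield (combo,) + rest

    p_obs = prob(table)
    total = tail = 0.0
    for t in rows(0, list(col_sums)):
        pt = prob(np.array(t))
        total += pt
        if pt <= p_obs * (1 + 1e-7):
            tail += pt
    return tail, total


class TestFreemanHalton:
    def test_published_stroke_history_value(self):
        res = fisher_exact_rxc(STROKE_HISTORY)
        assert res.p_value == pytest.approx(168 / 4960, rel=1e-9)
        assert round(res.p_value, 2) == 0.03

    def test_uniform_table_is_modal(self):
        assert fisher_exact_rxc([[1, 1], [1, 1], [1, 1]]).p_value == pytest.approx(1.0)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            table = rng.integers(0, 6, size=(3, 3))
            if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
                continue
            assert fisher_exact_rxc(table).p_total == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_on_random_3x3(self):
        rng = np.random.default_rng(2)
        checked = 0
        while checked < 25:
            table = rng.integers(0, 4, size=(3, 3))
            if table.sum() > 15 or (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
                continue
            oracle_tail, oracle_total = _brute_force_rxc(table)
            res = fisher_exact_rxc(table)
            assert res.p_value == pytest.approx(min(oracle_tail, 1.0), rel=1e-9)
            assert oracle_total == pytest.approx(1.0, abs=1e-9)
            checked += 1

    def test_reduces_to_2x2_fisher(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            table = rng.integers(0, 10, size=(2, 2))
            if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
                continue
            assert fisher_exact_rxc(table).p_value == fisher_exact_2x2(table)

    def test_enumeration_guard_directs_to_monte_carlo(self):
        big = np.full((4, 4), 60)
        with pytest.raises(ValueError, match="monte_carlo"):
            fisher_exact_rxc(big, max_tables=1000)

    def test_monte_carlo_agrees_with_exact(self):
        res = fisher_exact_rxc(STROKE_HISTORY)
        mc = fisher_exact_rxc(STROKE_HISTORY, method="monte_carlo", n_mc=200_000, seed=0)
        assert mc.p_value == pytest.approx(res.p_value, abs=0.003)


class TestGroupContinuousTest:
    def test_identical_groups_kruskal_null(self):
        values = [1.0, 2.0, 3.0] * 3
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        h, p = group_continuous_test(values, groups, "kruskal")
        assert h == pytest.approx(0.0, abs=1e-12) and p > 0.99

    def test_hand_computed_anova_f(self):
        values = [0, 1, 2, 3, 4, 5, 6, 7, 8]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        f, p = group_continuous_test(values, groups, "anova")
        assert f == pytest.approx(27.0)

    def test_welch_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        values = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        f, p = group_continuous_test(values, groups, "welch")
        df = pd.DataFrame({"y": values, "g": groups})
        ref = pingouin.welch_anova(data=df, dv="y", between="g")
        assert f == pytest.approx(float(ref["F"].iloc[0]))
        assert p == pytest.approx(float(ref["p_unc"].iloc[0]))

    def test_welch_close_to_anova_when_balanced_homoscedastic(self):
        rng = np.random.default_rng(5)
        rel = []
        for _ in range(20):
            values = rng.normal(size=150)
            groups = np.repeat(["a", "b", "c"], 50)
            _, p_a = group_continuous_test(values, groups, "anova")
            _, p_w = group_continuous_test(values, groups, "welch")
            rel.append(abs(p_w - p_a) / p_a)
        assert np.median(rel) <= 0.10

    def test_welch_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            group_continuous_test([1, 1, 2, 3], ["a", "a", "b", "b"], "welch")


class TestMedicationChangeSummary:
    def _cohort(self):
        subjects = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(9)] + [f"t{i}" for i in range(9)],
            "group": ["thrombotic"] * 9 + ["non_thrombotic"] * 9,
        })
        before = pd.DataFrame(
            {"heparin": [True] * 7 + [False] * 2 + [True] * 7 + [False] * 2},
            index=subjects["subject_id"],
        )
        after = pd.DataFrame({"heparin": [False] * 18}, index=subjects["subject_id"])
        return subjects, before, after

    def test_within_group_reproduces_published_heparin_p(self):
        subjects, before, after = self._cohort()
        out = medication_change_summary(subjects, before, after)
        thromb = out.per_group.query("group == 'thrombotic'").iloc[0]
        assert thromb["p_within"] == pytest.approx(0.0022624, abs=1e-6)

    def test_never_used_medication_p_one(self):
        subjects, before, after = self._cohort()
        before["placebo"] = False
        after["placebo"] = False
        out = medication_change_summary(subjects, before, after)
        rows = out.per_group.query("medication == 'placebo'")
        assert (rows["p_within"] == 1.0).all()
        p_across = out.across_groups.query("medication == 'placebo'")["p_across"]
        assert float(p_across.iloc[0]) == 1.0

    def test_change_table_bookkeeping(self):
        subjects, before, after = self._cohort()
        out = medication_change_summary(subjects, before, after)
        change = out.change_tables["heparin"]
        assert change.loc["thrombotic", "stopped"] == 7
        assert change.loc["thrombotic", "unchanged"] == 2
        assert "started" not in change.columns  # empty category collapsed

    def test_mcnemar_option_differs_for_paired_design(self):
        subjects, before, after = self._cohort()
        unpaired = medication_change_summary(subjects, before, after, paired=False)
        paired = medication_change_summary(subjects, before, after, paired=True)
        a = unpaired.per_group.query("group == 'thrombotic'")["p_within"].iloc[0]
        b = paired.per_group.query("group == 'thrombotic'")["p_within"].iloc[0]
        assert a != b
        assert b == pytest.approx(2 * 0.5**7, rel=1e-9)  # exact binomial, 7 discordant
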