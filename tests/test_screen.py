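"""Group model, Storey q-values (vs BH oracle), and qualification gates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from thrombomet import ScreenConfig, SimConfig, generate_cohort, run_screen, storey_qvalues
from thrombomet.screen import estimate_pi0, fit_group_model, qualify


def _fc(groups_to_values):
    """Build a one-metabolite fold-change frame plus group labels."""
    values, groups = [], []
    for g, vals in groups_to_values.items():
        values.extend(vals)
        groups.extend([g] * len(vals))
    fc = pd.DataFrame({"m": values}, index=[f"s{i}" for i in range(len(values))])
    return fc, np.array(groups)


class TestFitGroupModel:
    def test_identical_groups_give_f_zero_p_one(self):
        fc, groups = _fc({"thrombotic": [1, 1, 1], "non_thrombotic": [1, 1, 1],
                          "stable": [1, 1, 1]})
        fit = fit_group_model(fc, groups)
        assert fit.f_stat[0] == 0.0 and fit.p_anova[0] == 1.0
        assert fit.zero_variance[0]

    def test_hand_computed_anova(self):
        fc, groups = _fc({"thrombotic": [0, 1, 2], "non_thrombotic": [3, 4, 5],
                          "stable": [6, 7, 8]})
        fit = fit_group_model(fc, groups)
        # between SS 54 (df 2), within SS 6 (df 6): F = 27 / 1
        assert fit.f_stat[0] == pytest.approx(27.0)
        from scipy import stats

        assert fit.p_anova[0] == pytest.approx(stats.f.sf(27.0, 2, 6))
        assert fit.mse[0] == pytest.approx(1.0)

    def test_two_group_contrast_t_squared_equals_f(self):
        """With the third group dropped, the contrast t^2 is the omnibus F."""
        fc, groups = _fc({"thrombotic": [0.1, 0.9, 0.4, 0.6],
                          "non_thrombotic": [1.2, 1.8, 1.4, 1.6]})
        fit = fit_group_model(fc, groups)
        t_sq = (fit.group_means[0, 0] - fit.group_means[1, 0]) ** 2 / (
            fit.mse[0] * (1 / 4 + 1 / 4)
        )
        assert fit.f_stat[0] == pytest.approx(t_sq)

    def test_within_thrombotic_uses_own_variance(self):
        fc, groups = _fc({"thrombotic": [1.0, 1.0, 1.0], "non_thrombotic": [0, 5, -5],
                          "stable": [0, 4, -4]})
        fit = fit_group_model(fc, groups)
        # thrombotic sd = 0 with nonzero mean: p -> 0 despite noisy controls
        assert fit.p_within[0] == 0.0

    def test_degenerate_unequal_means_warn(self):
        fc, groups = _fc({"thrombotic": [1, 1], "non_thrombotic": [2, 2],
                          "stable": [3, 3]})
        with pytest.warns(RuntimeWarning, match="zero residual variance"):
            fit = fit_group_model(fc, groups)
        assert fit.p_anova[0] == 0.0

    def test_small_group_rejected(self):
        fc, groups = _fc({"thrombotic": [1], "non_thrombotic": [1, 2], "stable": [1, 2]})
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_group_model(fc, groups)


class TestStoreyQvalues:
    def test_all_ones(self):
        np.testing.assert_allclose(storey_qvalues(np.ones(5)), np.ones(5))

    def test_hand_step_up_with_pi0_one(self):
        q = storey_qvalues([0.01, 0.02, 0.03, 0.9], pi0=1.0)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.9])

    def test_monotone_in_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        q = storey_qvalues(p, pi0=0.7)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_fixed_1_equals_bh_oracle(self):
        rng = np.random.default_rng(7)
        cfg = ScreenConfig(pi0_method="fixed_1")
        for _ in range(50):
            p = rng.uniform(size=rng.integers(5, 200))
            q = storey_qvalues(p, cfg)
            bh = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_pi0_scales_q_linearly(self):
        p = np.array([0.001, 0.01, 0.2, 0.5, 0.9])
        np.testing.assert_allclose(
            storey_qvalues(p, pi0=0.5), 0.5 * storey_qvalues(p, pi0=1.0)
        )

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            storey_qvalues([0.5, 1.5])

    def test_pi0_estimate_near_one_under_null(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=2000)
        pi0 = estimate_pi0(p, np.arange(0, 0.91, 0.05))
        assert 0.85 <= pi0 <= 1.0

    def test_pi0_estimate_drops_with_signal(self):
        rng = np.random.default_rng(4)
        p = np.concatenate([rng.uniform(size=1000), rng.beta(0.5, 50, size=1000)])
        pi0 = estimate_pi0(p, np.arange(0, 0.91, 0.05))
        assert pi0 < 0.8


class TestQualify:
    def _row(self, **kw):
        base = dict(q_anova=0.5, q_within=0.5,
                    p_thrombotic_vs_non_thrombotic=0.5,
                    p_thrombotic_vs_stable=0.5,
                    p_non_thrombotic_vs_stable=0.5)
        base.update(kw)
        return pd.DataFrame([base])

    def test_specific_requires_all_gates(self):
        out = qualify(self._row(q_anova=0.01, q_within=0.01,
                                p_thrombotic_vs_non_thrombotic=0.001,
                                p_thrombotic_vs_stable=0.002,
                                p_non_thrombotic_vs_stable=0.8))
        assert bool(out["is_specific"][0]) and bool(out["is_candidate"][0])

    def test_candidate_only_between_5_and_10_percent(self):
        out = qualify(self._row(q_anova=0.07, q_within=0.06))
        assert bool(out["is_candidate"][0]) and not bool(out["is_specific"][0])

    def test_posthoc_blocks_specific(self):
        out = qualify(self._row(q_anova=0.01, q_within=0.01,
                                p_thrombotic_vs_non_thrombotic=0.2,
                                p_thrombotic_vs_stable=0.001))
        assert not bool(out["is_specific"][0])

    def test_specific_implies_candidate_on_simulated_screens(self, study_sized_cohort):
        table = run_screen(study_sized_cohort.abundance, study_sized_cohort.subjects, "T0")
        assert (table["is_candidate"] | ~table["is_specific"]).all()


class TestRunScreen:
    def test_recovers_planted_specific_effects(self, study_sized_cohort):
        truth = study_sized_cohort.truth
        table = run_screen(study_sized_cohort.abundance, study_sized_cohort.subjects, "T0")
        planted = set(truth.index[truth["effect_class"] == "specific"])
        flagged = set(table.index[table["is_specific"]])
        assert len(flagged & planted) >= 6  # 8 planted at |log2FC| = 2

    def test_procedural_metabolites_not_candidates(self, study_sized_cohort):
        truth = study_sized_cohort.truth
        table = run_screen(study_sized_cohort.abundance, study_sized_cohort.subjects, "T0")
        proc = truth.index[truth["effect_class"] == "procedural"]
        # big within-group change but equal across groups: ANOVA gate fails
        assert not table.loc[proc, "is_specific"].any()
        assert (table.loc[proc, "q_within"] < 0.05).all()

    def test_sorted_by_anova_p_and_deterministic(self, study_sized_cohort):
        t1 = run_screen(study_sized_cohort.abundance, study_sized_cohort.subjects, "T0")
        t2 = run_screen(study_sized_cohort.abundance, study_sized_cohort.subjects, "T0")
        pd.testing.assert_frame_equal(t1, t2)
        assert (np.diff(t1["p_anova"]) >= 0).all()

    def test_permuting_groups_destroys_specific_flags(self, study_sized_cohort):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(10):
            subjects = study_sized_cohort.subjects.copy()
            subjects["group"] = rng.permutation(subjects["group"].to_numpy())
            table = run_screen(study_sized_cohort.abundance, subjects, "T0")
            hits += int(table["is_specific"].sum() > 0)
        assert hits <= 1

    def test_t0_and_t6_are_independent_runs(self, study_sized_cohort):
        t0 = run_screen(study_sized_cohort.abundance, study_sized_cohort.subjects, "T0")
        t6 = run_screen(study_sized_cohort.abundance, study_sized_cohort.subjects, "T6")
        assert not np.allclose(t0["p_anova"], t6["p_anova"])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_qvalues_never_below_bh_floor(seed):
    """q >= pi0 * BH adjusted p, since q is the BH step-up scaled by pi0."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=50)
    q = storey_qvalues(p, ScreenConfig())
    bh = multipletests(p, method="fdr_bh")[1]
    pi0 = estimate_pi0(p, np.arange(0, 0.91, 0.05))
    assert (q >= pi0 * bh - 1e-12).all()
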