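"""Configuration objects for the cohort simulator, screen, and classifier.

All tunables live in plain dataclasses with a ``validate`` method that raises
``ValueError`` naming the offending field, so CLI and YAML front-ends can
surface precise messages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence, Tuple

#: Study groups, in canonical order. ``thrombotic`` is the case group; the two
#: controls share either the acute insult (non-thrombotic MI) or the
#: underlying disease (stable CAD).
GROUPS: Tuple[str, str, str] = ("thrombotic", "non_thrombotic", "stable")

#: Sampling time points: enrollment (T0), six hours later (T6), and the
#: quiescent follow-up (Q, >3 months).
TIMEPOINTS: Tuple[str, str, str] = ("T0", "T6", "Q")
ACUTE_TIMEPOINTS: Tuple[str, str] = ("T0", "T6")


@dataclass
class SimConfig:
    """Parameters of the synthetic three-group, three-timepoint cohort.

    Log2 abundance of metabolite *m* in sample (subject *s*, time *t*) is

        mu_m + u_{s,m} + delta(group_s, m, t) + eps_{s,m,t}

    with a metabolite baseline ``mu_m ~ N(baseline_log2_mean, sigma_metabolite)``,
    a time-invariant subject effect ``u`` of scale ``sigma_subject``, a planted
    acute effect ``delta`` (nonzero only at T0/T6 and only for effect
    metabolites), and residual noise of scale ``sigma_residual``.  Both ``u``
    and ``eps`` share a latent factor per biochemical-family block with
    correlation ``family_rho``, so families co-move.
    """

    n_per_group: Tuple[int, int, int] = (11, 12, 15)
    n_paired: Tuple[int, int, int] = (9, 9, 14)
    n_metabolites: int = 1032
    n_specific: int = 19
    n_procedural: int = 10
    effect_log2fc_range: Tuple[float, float] = (1.0, 4.0)
    sigma_metabolite: float = 2.0
    sigma_subject: float = 1.6
    sigma_residual: float = 0.5
    family_block_size: int = 8
    family_rho: float = 0.4
    censor_quantile: float = 0.05
    baseline_log2_mean: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_per_group) != 3 or any(n < 0 for n in self.n_per_group):
            raise ValueError("n_per_group must be three non-negative counts")
        if len(self.n_paired) != 3 or any(n < 0 for n in self.n_paired):
            raise ValueError("n_paired must be three non-negative counts")
        if any(p > n for p, n in zip(self.n_paired, self.n_per_group)):
            raise ValueError("n_paired cannot exceed n_per_group")
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be >= 1")
        if self.n_specific < 0 or self.n_procedural < 0:
            raise ValueError("n_specific and n_procedural must be >= 0")
        if self.n_specific + self.n_procedural > self.n_metabolites:
            raise ValueError(
                "n_specific + n_procedural exceeds n_metabolites"
            )
        lo, hi = self.effect_log2fc_range
        if lo < 0 or hi < lo:
            raise ValueError("effect_log2fc_range must satisfy 0 <= lo <= hi")
        for name in ("sigma_metabolite", "sigma_subject", "sigma_residual"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.family_block_size < 1:
            raise ValueError("family_block_size must be >= 1")
        if not 0.0 <= self.family_rho < 1.0:
            raise ValueError("family_rho must be in [0, 1)")
        if not 0.0 <= self.censor_quantile < 1.0:
            raise ValueError("censor_quantile must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScreenConfig:
    """Thresholds and q-value tuning for the differential-change screen.

    ``candidate_fdr`` (10%) gates the set feeding multivariate analyses;
    ``specific_fdr`` (5%) plus both thrombotic-vs-control post-hoc contrasts at
    ``posthoc_alpha`` defines the thrombotic-specific set.
    """

    candidate_fdr: float = 0.10
    specific_fdr: float = 0.05
    posthoc_alpha: float = 0.05
    qvalue_lambda: Sequence[float] = field(
        default_factory=lambda: tuple(i * 0.05 for i in range(19))  # 0 .. 0.90
    )
    pi0_method: str = "smoother"

    def validate(self) -> None:
        for name in ("candidate_fdr", "specific_fdr", "posthoc_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.specific_fdr > self.candidate_fdr:
            raise ValueError("specific_fdr must be <= candidate_fdr")
        lam = tuple(self.qvalue_lambda)
        if len(lam) < 1 or any(not 0.0 <= x < 1.0 for x in lam):
            raise ValueError("qvalue_lambda values must lie in [0, 1)")
        if self.pi0_method not in ("smoother", "fixed_1"):
            raise ValueError("pi0_method must be 'smoother' or 'fixed_1'")


@dataclass
class ClassifierConfig:
    """Random-forest / recursive-elimination settings.

    ``ranking_scope='per_fold'`` recomputes importances inside every training
    fold (no test-fold leakage); ``'global'`` reproduces the optimistic
    whole-data ranking variant.
    """

    n_trees: int = 2000
    max_features: str = "sqrt"
    importance: str = "permutation_oob"  # or "impurity"
    cv_folds: int = 10
    stratified: bool = True
    ranking_scope: str = "per_fold"  # or "global"
    seed: int = 0
    positive_class: str = "thrombotic"

    def validate(self, n_samples: int | None = None) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if n_samples is not None and self.cv_folds > n_samples:
            raise ValueError("cv_folds cannot exceed the number of samples")
        if self.importance not in ("permutation_oob", "impurity"):
            raise ValueError("importance must be 'permutation_oob' or 'impurity'")
        if self.ranking_scope not in ("per_fold", "global"):
            raise ValueError("ranking_scope must be 'per_fold' or 'global'")
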