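"""PLS-DA via NIPALS, with R2Y and Mahalanobis confidence ellipses.

X is the candidate fold-change matrix (subjects x metabolites), autoscaled
by default; Y is a centered group-indicator matrix (one column per group,
PLS2).  Components are extracted by NIPALS with X and Y deflation, so
successive score vectors are mutually orthogonal and R2Y is nondecreasing
in the number of components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import GROUPS


def group_indicator_matrix(groups, levels=None) -> tuple[np.ndarray, tuple]:
    """Centered one-column-per-group indicator (dummy) matrix."""
    groups = np.asarray(groups)
    levels = tuple(levels) if levels is not None else tuple(
        g for g in GROUPS if g in set(groups)
    )
    Y = np.column_stack([(groups == g).astype(float) for g in levels])
    return Y - Y.mean(axis=0), levels


@dataclass
class PLSDAModel:
    n_components: int
    weights: np.ndarray  # W, (p, A)
    x_loadings: np.ndarray  # P, (p, A)
    y_loadings: np.ndarray  # Q, (G, A)
    scores: np.ndarray  # T, (n, A)
    x_mean: np.ndarray
    x_scale: np.ndarray
    r2y_cum: np.ndarray  # (A,)
    feature_names: list = field(default_factory=list)
    group_levels: tuple = ()

    @property
    def r2y(self) -> float:
        """Cumulative fraction of group-indicator variance explained."""
        return float(self.r2y_cum[-1])

    def transform(self, X) -> np.ndarray:
        """Project new observations onto the score space, T = Xs W (P'W)^-1."""
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        R = self.weights @ np.linalg.inv(self.x_loadings.T @ self.weights)
        return Xs @ R


def fit_plsda(
    X,
    groups,
    n_components: int = 2,
    scale: bool = True,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSDAModel:
    """NIPALS PLS2 of autoscaled X on centered group indicators.

    Deterministic: each component's inner loop starts from the Y-residual
    column of largest variance.  Constant X columns are rejected by name
    (they cannot be autoscaled and carry no discriminant information).
    """
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{j}" for j in range(np.asarray(X).shape[1])
    ]
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Y0, levels = group_indicator_matrix(groups)

    x_mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.isclose(sd, 0.0).any():
        bad = feature_names[int(np.flatnonzero(np.isclose(sd, 0.0))[0])]
        raise ValueError(f"constant column in X: {bad!r}")
    x_scale = sd if scale else np.ones(p)
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}"
        )

    Xr = (X - x_mean) / x_scale
    Yr = Y0.copy()
    ss_y = (Y0**2).sum()

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((Y0.shape[1], n_components))
    T = np.zeros((n, n_components))
    r2y_cum = np.zeros(n_components)

    for a in range(n_components):
        u = Yr[:, int(np.argmax(Yr.var(axis=0)))].copy()
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = Xr.T @ u / (u @ u)
            w /= np.linalg.norm(w)
            t = Xr @ w
            q = Yr.T @ t / (t @ t)
            u = Yr @ q / (q @ q)
            if np.linalg.norm(t - t_old) < tol * max(np.linalg.norm(t), 1.0):
                break
            t_old = t
        p_load = Xr.T @ t / (t @ t)
        Xr = Xr - np.outer(t, p_load)
        Yr = Yr - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_load, q, t
        r2y_cum[a] = 1.0 - (Yr**2).sum() / ss_y

    return PLSDAModel(
        n_components=n_components,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        x_mean=x_mean,
        x_scale=x_scale,
        r2y_cum=r2y_cum,
        feature_names=feature_names,
        group_levels=levels,
    )


def r2y(model: PLSDAModel, X, groups) -> float:
    """1 - SS(Y - Yhat)/SS(Y) with Y the centered indicator matrix."""
    Y, _ = group_indicator_matrix(groups, model.group_levels)
    T = model.transform(X)
    Yhat = T @ model.y_loadings.T
    return float(1.0 - ((Y - Yhat) ** 2).sum() / (Y**2).sum())


@dataclass
class EllipseSpec:
    """A group's 2-D confidence ellipse in score space.

    The boundary is the locus of points at squared Mahalanobis distance
    chi2_2(level) from the centroid under the group's sample covariance.
    """

    group: str
    center: np.ndarray  # (2,)
    covariance: np.ndarray  # (2, 2)
    level: float
    radius: float  # Mahalanobis boundary radius

    def boundary(self, n_points: int = 100) -> np.ndarray:
        """Points on the ellipse, for plotting/export."""
        theta = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        L = np.linalg.cholesky(self.covariance)
        return self.center + self.radius * circle @ L.T

    def mahalanobis_sq(self, points) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        return np.einsum("ij,jk,ik->i", d, np.linalg.inv(self.covariance), d)

    def contains(self, points) -> np.ndarray:
        return self.mahalanobis_sq(points) <= self.radius**2


def confidence_ellipse(
    scores,
    group: str = "",
    level: float = 0.90,
    method: str = "chi2",
) -> EllipseSpec:
    """Mahalanobis confidence ellipse of a group's first two scores.

    ``chi2`` (default) uses radius^2 = chi2 quantile with 2 df; ``hotelling``
    substitutes the small-sample T^2 radius 2(n-1)/(n-2) * F(level; 2, n-2).
    """
    S = np.asarray(scores, dtype=float)[:, :2]
    n = S.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for a covariance ellipse")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    center = S.mean(axis=0)
    cov = np.cov(S, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(cov) < 2 or np.linalg.det(cov) <= 0:
        raise ValueError(
            "singular score covariance; jitter the scores or add subjects"
        )
    if method == "chi2":
        r2 = stats.chi2.ppf(level, df=2)
    elif method == "hotelling":
        r2 = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(level, 2, n - 2)
    else:
        raise ValueError("method must be 'chi2' or 'hotelling'")
    return EllipseSpec(group=group, center=center, covariance=cov,
                       level=level, radius=float(np.sqrt(r2)))


def group_ellipses(model: PLSDAModel, groups, level: float = 0.90) -> list[EllipseSpec]:
    groups = np.asarray(groups)
    return [
        confidence_ellipse(model.scores[groups == g], group=g, level=level)
        for g in model.group_levels
    ]
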