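"""Centered PCA, two-table co-inertia, RV permutation test, identity regression.

Co-inertia analysis couples two multivariate descriptions of the same
samples — here, river sections described once by eDNA read abundances and
once by capture abundances.  Each table is first summarized by a centered
PCA; the co-inertia axes are the singular vectors of the cross-covariance
of the two retained score matrices, i.e. the unit directions maximizing the
covariance of the projected section coordinates.  The RV coefficient

    RV = tr(C_xy C_yx) / sqrt(tr(C_xx^2) tr(C_yy^2))

(with C the uniform-weight cross/auto-covariance of the score matrices)
measures global coupling in [0, 1] and is tested by permuting section rows
of one table.  An identity regression of one table's co-inertia scores on
the other's checks whether the two methods place sections at the same
coordinates (slope 1, intercept 0).

Everything here is built directly on the singular value decomposition; no
ordination library stands behind it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PCAResult",
    "CoinertiaResult",
    "IdentityRegressionResult",
    "log_transform",
    "centered_pca",
    "coinertia",
    "rv_coefficient",
    "rv_permutation_test",
    "identity_regression",
]


def log_transform(table: pd.DataFrame) -> pd.DataFrame:
    """log(x+1) transform for count/abundance tables prior to PCA.

    Offset 1 admits zeros (absent species) while preserving order.
    """
    if (table.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return np.log1p(table)


@dataclass
class PCAResult:
    """Centered PCA of a section × species table, uniform row weights 1/n.

    ``eigenvalues[k]`` = (singular value k)²/n is the inertia carried by
    axis k; ``scores`` are section coordinates (U·S), ``loadings`` the
    species coefficients (right singular vectors).  All axes are computed;
    ``n_axes`` marks how many are retained downstream.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    inertia_fraction: np.ndarray
    n_axes: int
    total_inertia: float

    def retained_scores(self) -> pd.DataFrame:
        return self.scores.iloc[:, : self.n_axes]


def centered_pca(table: pd.DataFrame, n_axes: int = 2) -> PCAResult:
    """Principal component analysis of a column-centered table.

    Rows (sections) carry uniform weight 1/n.  Axis k's eigenvalue is
    s_k²/n where s_k is the k-th singular value of the centered matrix, so
    the eigenvalues sum to the total inertia (mean squared deviation).  A
    constant matrix yields all-zero eigenvalues and scores.
    """
    X = np.asarray(table, dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 sections and 2 species")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / n
    total = float(eig.sum())
    frac = eig / total if total > 0 else np.zeros_like(eig)
    axes = [f"PC{k + 1}" for k in range(len(s))]
    scores = pd.DataFrame(U * s, index=table.index, columns=axes)
    loadings = pd.DataFrame(Vt.T, index=table.columns, columns=axes)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        eigenvalues=eig,
        inertia_fraction=frac,
        n_axes=min(n_axes, len(s)),
        total_inertia=total,
    )


def _score_matrices(pca_x: PCAResult, pca_y: PCAResult) -> tuple[np.ndarray, np.ndarray]:
    if not pca_x.scores.index.equals(pca_y.scores.index):
        raise ValueError("co-inertia inputs must share the same sections in the same order")
    return (
        pca_x.retained_scores().to_numpy(),
        pca_y.retained_scores().to_numpy(),
    )


def rv_coefficient(sx: np.ndarray, sy: np.ndarray) -> float:
    """RV matrix correlation of two centered score matrices (rows = samples)."""
    sx = sx - sx.mean(axis=0, keepdims=True)
    sy = sy - sy.mean(axis=0, keepdims=True)
    n = sx.shape[0]
    cxy = sx.T @ sy / n
    cxx = sx.T @ sx / n
    cyy = sy.T @ sy / n
    num = np.trace(cxy @ cxy.T)
    den = np.sqrt(np.trace(cxx @ cxx) * np.trace(cyy @ cyy))
    if den == 0:
        raise ValueError("RV undefined for a zero-variance table")
    return float(num / den)


@dataclass
class CoinertiaResult:
    rv: float
    singular_values: np.ndarray
    inertia_fraction: np.ndarray
    scores_x: pd.DataFrame
    scores_y: pd.DataFrame
    axis_correlations_x: pd.DataFrame  # co-inertia axes vs X's own PCs
    axis_correlations_y: pd.DataFrame
    permutation_p: float | None = None


def coinertia(pca_x: PCAResult, pca_y: PCAResult) -> CoinertiaResult:
    """Co-inertia analysis of two PCAs of the same sections.

    The axes are the left/right singular vectors of the cross-covariance
    C_xy = Sx'Sy/n of the retained score matrices; section scores are the
    projections of each table's scores on its side's axes.  The squared
    singular values are the co-inertia carried per axis pair; RV summarizes
    total coupling.  Axis correlations report how each co-inertia axis
    aligns with the original principal components.
    """
    sx, sy = _score_matrices(pca_x, pca_y)
    n = sx.shape[0]
    cxy = sx.T @ sy / n
    U, s, Vt = np.linalg.svd(cxy)
    axes = [f"CoPC{k + 1}" for k in range(len(s))]
    scox = pd.DataFrame(sx @ U, index=pca_x.scores.index, columns=axes)
    scoy = pd.DataFrame(sy @ Vt.T, index=pca_y.scores.index, columns=axes)
    tot = float((s**2).sum())
    frac = s**2 / tot if tot > 0 else np.zeros_like(s)

    def _corr(co_scores: pd.DataFrame, pc_scores: np.ndarray, labels) -> pd.DataFrame:
        out = np.zeros((co_scores.shape[1], pc_scores.shape[1]))
        for i in range(co_scores.shape[1]):
            for j in range(pc_scores.shape[1]):
                a, b = co_scores.iloc[:, i].to_numpy(), pc_scores[:, j]
                if a.std() == 0 or b.std() == 0:
                    out[i, j] = np.nan
                else:
                    out[i, j] = np.corrcoef(a, b)[0, 1]
        return pd.DataFrame(out, index=co_scores.columns, columns=labels)

    pc_labels_x = list(pca_x.retained_scores().columns)
    pc_labels_y = list(pca_y.retained_scores().columns)
    return CoinertiaResult(
        rv=rv_coefficient(sx, sy),
        singular_values=s,
        inertia_fraction=frac,
        scores_x=scox,
        scores_y=scoy,
        axis_correlations_x=_corr(scox, sx, pc_labels_x),
        axis_correlations_y=_corr(scoy, sy, pc_labels_y),
    )


def rv_permutation_test(
    pca_x: PCAResult, pca_y: PCAResult, n_perm: int = 999, seed: int | None = None
) -> float:
    """Monte-Carlo p-value for the observed RV coefficient.

    Rows (sections) of one score matrix are permuted; the one-tailed
    p-value is (1 + #{permuted RV >= observed}) / (1 + n_perm).
    Deterministic given ``seed``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    sx, sy = _score_matrices(pca_x, pca_y)
    observed = rv_coefficient(sx, sy)
    rng = np.random.default_rng(seed)
    n = sx.shape[0]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if rv_coefficient(sx, sy[perm]) >= observed - 1e-12:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


@dataclass(frozen=True)
class IdentityRegressionResult:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    r_squared: float
    t_slope_eq_1: float
    p_slope_eq_1: float
    t_intercept_eq_0: float
    p_intercept_eq_0: float
    n: int


def identity_regression(scores_a, scores_b) -> IdentityRegressionResult:
    """OLS of ``scores_b`` on ``scores_a`` with identity-line t-tests.

    Tests the fitted slope against 1 and the intercept against 0 (Student t
    with n−2 df) and reports R².  A zero-residual fit is reported as the
    exact identity: p = 1 when the estimate equals the hypothesized value,
    else p = 0.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    n = a.size
    if n < 3:
        raise ValueError("need >= 3 sections")
    sxx = float(((a - a.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("zero variance in predictor scores")
    sxy = float(((a - a.mean()) * (b - b.mean())).sum())
    slope = sxy / sxx
    intercept = float(b.mean() - slope * a.mean())
    resid = b - (intercept + slope * a)
    ss_res = float((resid**2).sum())
    ss_tot = float(((b - b.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if ss_res <= 1e-12 * max(ss_tot, 1.0):  # exact identity/degenerate fit
        p_slope = 1.0 if abs(slope - 1.0) < 1e-10 else 0.0
        p_inter = 1.0 if abs(intercept) < 1e-10 else 0.0
        return IdentityRegressionResult(
            slope, intercept, 0.0, 0.0, r2, 0.0, p_slope, 0.0, p_inter, n
        )
    sigma2 = ss_res / (n - 2)
    se_slope = float(np.sqrt(sigma2 / sxx))
    se_inter = float(np.sqrt(sigma2 * (1.0 / n + a.mean() ** 2 / sxx)))
    t_slope = (slope - 1.0) / se_slope
    t_inter = intercept / se_inter
    p_slope = float(2 * stats.t.sf(abs(t_slope), n - 2))
    p_inter = float(2 * stats.t.sf(abs(t_inter), n - 2))
    return IdentityRegressionResult(
        slope, intercept, se_slope, se_inter, r2, t_slope, p_slope, t_inter, p_inter, n
    )
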