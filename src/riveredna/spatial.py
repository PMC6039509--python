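"""Bray-Curtis dissimilarity, Mantel tests, and distance-class correlograms.

The longitudinal extent of assemblage autocorrelation along the river is
measured with Mantel statistics between a community dissimilarity matrix
(Bray-Curtis) and geographic structure.  Site separation is measured along
the river axis (|Δ kilometre point|), not as straight-line distance,
because eDNA and fish follow the channel.

The Mantel correlogram follows the Legendre convention: per contiguous
fixed-width distance class, the statistic is the *negated* Pearson
correlation between the community dissimilarity and the within-class
indicator matrix, so positive r means sites in that class are more similar
than average.  Per-class permutation p-values are corrected progressively
(Holm over the first k tested classes), and the autocorrelation extent is
the upper edge of the initial run of significant positive classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "bray_curtis",
    "mantel",
    "mantel_correlogram",
    "CorrelogramResult",
]


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity d = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ).

    Symmetric with zero diagonal, values in [0, 1].  All-zero rows are an
    error (their dissimilarity to anything is undefined).
    """
    X = np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    zero = X.sum(axis=1) == 0
    if zero.any():
        bad = list(np.asarray(matrix.index)[zero])
        raise ValueError(f"all-zero abundance rows for sites: {bad}")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(mat, k=1)
    return mat[iu]


def _check_square(d: pd.DataFrame | np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(d, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(a, a.T, equal_nan=True):
        raise ValueError(f"{name} must be symmetric")
    return a


def mantel(
    d1,
    d2,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with a permutation test.

    r is the Pearson correlation of the upper triangles; the p-value comes
    from simultaneous row/column permutations of the second matrix,
    one-tailed toward r >= observed, p = (1 + exceedances)/(1 + n_perm).
    A constant upper triangle yields (nan, nan).
    """
    if isinstance(d1, pd.DataFrame) and isinstance(d2, pd.DataFrame):
        if not d1.index.equals(d2.index):
            raise ValueError("matrices must share the same site set and order")
    a = _check_square(d1, "d1")
    b = _check_square(d2, "d2")
    if a.shape != b.shape:
        raise ValueError("matrices must have the same shape")
    x = _upper(a)
    if np.std(x) == 0 or np.std(_upper(b)) == 0:
        logger.warning("constant distance triangle: Mantel r undefined")
        return float("nan"), float("nan")
    r_obs = float(np.corrcoef(x, _upper(b))[0, 1])
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = np.corrcoef(x, _upper(b[np.ix_(perm, perm)]))[0, 1]
        if r >= r_obs - 1e-12:
            exceed += 1
    return r_obs, (1 + exceed) / (1 + n_perm)


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    k = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(k)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (k - rank) * pvals[idx]))
        adj[idx] = running
    return adj


@dataclass
class CorrelogramResult:
    """Mantel correlogram over contiguous fixed-width distance classes.

    ``autocorrelation_extent`` is the upper edge (km) of the last class in
    the initial run of significant positive-correlation classes, or 0 when
    the first class is already non-significant.
    """

    class_edges: np.ndarray  # length n_classes + 1
    class_r: np.ndarray
    class_p: np.ndarray
    class_p_corrected: np.ndarray
    class_n: np.ndarray
    significant: np.ndarray
    autocorrelation_extent: float
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lower_km": self.class_edges[:-1],
                "upper_km": self.class_edges[1:],
                "n_pairs": self.class_n,
                "mantel_r": self.class_r,
                "p": self.class_p,
                "p_corrected": self.class_p_corrected,
                "significant": self.significant,
            }
        )


def mantel_correlogram(
    d_comm,
    positions,
    class_width_km: float = 10.0,
    n_classes: int = 19,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> CorrelogramResult:
    """Distance-class Mantel correlogram of community dissimilarity.

    Per class [k·w, (k+1)·w): the statistic is −corr(D_comm, indicator of
    pair membership), positive when within-class pairs are more similar
    than average; its permutation p (same simultaneous permutation scheme
    as :func:`mantel`, one-tailed toward the observed sign) is corrected
    progressively with Holm over the classes tested so far.  Empty classes
    report NaN statistics.
    """
    if class_width_km <= 0:
        raise ValueError("class_width_km must be positive")
    if n_classes < 2:
        raise ValueError("need at least 2 distance classes")
    D = _check_square(d_comm, "d_comm")
    pos = np.asarray(positions, dtype=float)
    if pos.size != D.shape[0]:
        raise ValueError("positions length must match the dissimilarity matrix")
    geo = np.abs(pos[:, None] - pos[None, :])
    edges = np.arange(n_classes + 1, dtype=float) * class_width_km
    x = _upper(D)
    rng = np.random.default_rng(seed)
    n = D.shape[0]
    perms = [rng.permutation(n) for _ in range(n_perm)]

    r_arr = np.full(n_classes, np.nan)
    p_arr = np.full(n_classes, np.nan)
    n_arr = np.zeros(n_classes, dtype=int)
    for k in range(n_classes):
        member = ((geo >= edges[k]) & (geo < edges[k + 1])).astype(float)
        np.fill_diagonal(member, 0.0)
        y = _upper(member)
        n_arr[k] = int(y.sum())
        if n_arr[k] == 0 or np.std(y) == 0:
            logger.info("distance class %g-%g km empty; statistic missing", edges[k], edges[k + 1])
            continue
        r_obs = -float(np.corrcoef(x, y)[0, 1])
        sign = 1.0 if r_obs >= 0 else -1.0
        exceed = 0
        for perm in perms:
            yp = _upper(member[np.ix_(perm, perm)])
            r = -np.corrcoef(x, yp)[0, 1]
            if sign * r >= sign * r_obs - 1e-12:
                exceed += 1
        r_arr[k] = r_obs
        p_arr[k] = (1 + exceed) / (1 + n_perm)

    # progressive Holm: class k corrected across the first k tested classes
    p_corr = np.full(n_classes, np.nan)
    tested = [k for k in range(n_classes) if np.isfinite(p_arr[k])]
    for i, k in enumerate(tested):
        sub = np.array([p_arr[j] for j in tested[: i + 1]])
        p_corr[k] = _holm(sub)[-1]

    signif = np.zeros(n_classes, dtype=bool)
    for k in range(n_classes):
        signif[k] = bool(np.isfinite(p_corr[k]) and p_corr[k] <= alpha)

    extent = 0.0
    for k in range(n_classes):
        if signif[k] and np.isfinite(r_arr[k]) and r_arr[k] > 0:
            extent = float(edges[k + 1])
        else:
            break
    return CorrelogramResult(
        class_edges=edges,
        class_r=r_arr,
        class_p=p_arr,
        class_p_corrected=p_corr,
        class_n=n_arr,
        significant=signif,
        autocorrelation_extent=extent,
        alpha=alpha,
    )
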