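"""Supervised and descriptive companions to the progression analysis.

Per-feature permutational one-way ANOVA across age groups (with Bonferroni
correction), Spearman correlation of each feature with age, Shannon alpha
diversity and Bray–Curtis beta diversity of age-group profiles, and a PCA
overview of the sample-level composition matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

__all__ = [
    "permutation_anova",
    "spearman_vs_age",
    "shannon_index",
    "bray_curtis",
    "bray_curtis_matrix",
    "pca_overview",
]


def _f_statistics(X: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Classical one-way ANOVA F per column of X (vectorized over columns).

    Columns with zero within-group variance but positive between-group
    variance get F = inf; columns constant overall get F = 0.
    """
    n, p = X.shape
    G = len(groups)
    grand = X.sum(axis=0)
    sst = (X**2).sum(axis=0) - grand**2 / n
    ssb = np.zeros(p)
    for g in groups:
        mask = labels == g
        ng = int(mask.sum())
        s = X[mask].sum(axis=0)
        ssb += s**2 / ng
    ssb -= grand**2 / n
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (G - 1)) / (ssw / (n - G))
    F = np.where(ssw <= 1e-300, np.where(ssb > 1e-300, np.inf, 0.0), F)
    return F


def permutation_anova(
    rel: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutational one-way ANOVA of every feature across age groups.

    The F statistic is the classical between/within mean-square ratio; its
    null distribution comes from ``n_perm`` random reassignments of the
    group labels (group sizes preserved), shared across features.
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so the smallest attainable
    p is 1/(n_perm+1); Bonferroni multiplies by the number of features.

    Returns a DataFrame indexed by feature with columns F, p, p_adj, n_perm.
    """
    labels = np.asarray(groups.loc[rel.index])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("permutation ANOVA needs at least 2 groups")
    small = uniq[counts < 2]
    if len(small):
        raise ValueError(f"groups with fewer than 2 samples: {list(small)}")
    X = rel.to_numpy(dtype=float)
    F_obs = _f_statistics(X, labels, uniq)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(X.shape[1], dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(len(labels))
        F_b = _f_statistics(X, labels[perm], uniq)
        exceed += F_b >= F_obs
    p = (1 + exceed) / (1 + n_perm)
    p_adj = np.minimum(1.0, p * X.shape[1])
    return pd.DataFrame(
        {"F": F_obs, "p": p, "p_adj": p_adj, "n_perm": n_perm}, index=rel.columns
    )


def spearman_vs_age(rel: pd.DataFrame, ages: pd.Series) -> pd.DataFrame:
    """Spearman correlation of each feature's relative abundance with age.

    Average-rank ties; two-sided p via the t approximation.  A constant
    feature is reported with rho = 0, p = 1 and ``degenerate`` = True.

    Returns a DataFrame indexed by feature with columns rho, p, degenerate.
    """
    if len(rel) < 3:
        raise ValueError("need at least 3 samples for a Spearman correlation")
    a = np.asarray(ages.loc[rel.index], dtype=float)
    rows = []
    for col in rel.columns:
        x = rel[col].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(a == a[0]):
            rows.append((0.0, 1.0, True))
            continue
        res = sps.spearmanr(x, a)
        rows.append((float(res.statistic), float(res.pvalue), False))
    return pd.DataFrame(rows, index=rel.columns, columns=["rho", "p", "degenerate"])


def shannon_index(profile: np.ndarray | pd.Series, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i ln p_i of a composition (nats by default).

    ``profile`` must be a relative-abundance vector summing to 1 (within
    1e-6); zero entries contribute nothing.  Pass ``base=2`` for bits.
    """
    p = np.asarray(profile, dtype=float)
    if (p < 0).any():
        raise ValueError("negative relative abundance in profile")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"profile sums to {p.sum():.6g}, not 1")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def bray_curtis(x: np.ndarray | pd.Series, y: np.ndarray | pd.Series) -> float:
    """Bray–Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("profiles have different feature axes")
    if (xv < 0).any() or (yv < 0).any():
        raise ValueError("negative abundances")
    denom = float((xv + yv).sum())
    if denom == 0:
        raise ValueError("both profiles are all-zero")
    return float(np.abs(xv - yv).sum() / denom)


def bray_curtis_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Symmetric zero-diagonal Bray–Curtis matrix between profile rows."""
    n = len(profiles)
    M = np.zeros((n, n))
    vals = profiles.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = bray_curtis(vals[i], vals[j])
    return pd.DataFrame(M, index=profiles.index, columns=profiles.index)


def pca_overview(
    rel: pd.DataFrame, n_components: int = 3, scale: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the column-centered (optionally scaled) composition matrix.

    Returns per-sample coordinates and the fractions of total variance
    explained by each component (non-increasing, summing to at most 1).
    """
    if len(rel) < 2:
        raise ValueError("PCA needs at least 2 samples")
    k = min(n_components, len(rel) - 1, rel.shape[1])
    X = rel.to_numpy(dtype=float)
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    cols = [f"PC{i+1}" for i in range(k)]
    return (
        pd.DataFrame(coords, index=rel.index, columns=cols),
        pca.explained_variance_ratio_,
    )
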