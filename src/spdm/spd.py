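"""Sample Progression Discovery over age-group profiles.

The method asks whether many features change *gradually* along one common
ordering of the sample groups, without ever using the group ages:

1. For each feature, build the minimum spanning tree (MST) of the complete
   graph on the G groups under Euclidean distance in that feature's
   normalized profile — for a single feature this is the path visiting
   groups in sorted order of its values, i.e. a putative progression
   ordering.
2. Cross-compare: test every feature against every tree with a permutation
   test on the total absolute change along tree edges (small cost = the
   feature varies smoothly along that ordering).
3. Count, for each feature pair, the trees both fit at significance level
   alpha — the progression-similarity matrix.  A coherent block in this
   matrix is a set of features that agree on a common set of orderings.
4. Build one overall MST from the block's features jointly; its diameter
   path is the recovered progression ordering of the groups.

All randomness flows from a single integer seed; the null permutations for
a given tree are shared by every feature tested against it, so results do
not depend on feature order and identical features get identical p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations as _itpermutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .feature_table import GroupProfiles

__all__ = [
    "FeatureMST",
    "FitMatrix",
    "ProgressionResult",
    "discover_progression",
    "build_mst",
    "tree_cost",
    "fit_pvalue",
    "fit_pvalue_exhaustive",
    "fit_matrix",
    "similarity_matrix",
    "select_progression_features",
    "overall_mst",
    "extract_ordering",
    "compare_orderings",
]

# Relative slack when comparing permutation costs with the observed cost, so
# that exact ties (e.g. reversal of a path, which re-orders float additions)
# are counted as <= regardless of rounding.
_TIE_RTOL = 1e-9
_TIE_ATOL = 1e-12


@dataclass(frozen=True)
class FeatureMST:
    """Spanning tree over group ids induced by a feature set.

    ``edges`` are ``(u, v, weight)`` with ``u < v`` and weight the Euclidean
    distance between the two groups' normalized profiles restricted to
    ``source_features``.
    """

    nodes: tuple[int, ...]
    edges: tuple[tuple[int, int, float], ...]
    source_features: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.nodes) - 1:
            raise ValueError("a spanning tree on G nodes has exactly G-1 edges")

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {n: [] for n in self.nodes}
        for u, v, _ in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        for n in adj:
            adj[n].sort()
        return adj

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))


@dataclass
class FitMatrix:
    """Permutation p-values of every feature against every candidate tree."""

    pvalues: pd.DataFrame  # features x trees
    alpha: float
    n_perm: int
    seed: int

    @property
    def fits(self) -> pd.DataFrame:
        return self.pvalues <= self.alpha


@dataclass
class ProgressionResult:
    """Selected feature block, overall tree, and extracted group ordering."""

    selected_features: tuple[str, ...]
    overall_tree: FeatureMST
    ordering: tuple[int, ...]
    off_path: dict[int, int]


class _UnionFind:
    def __init__(self, items: Iterable[int]):
        self.parent = {i: i for i in items}

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _kruskal(nodes: Sequence[int], dist: np.ndarray) -> list[tuple[int, int, float]]:
    """Kruskal MST with a deterministic tie-break.

    Equal-weight edges are taken smaller group-gap first, then smaller
    (u, v); on fully degenerate input (all distances equal) this yields the
    consecutive path 1-2-...-G rather than a star.
    """
    idx = {n: i for i, n in enumerate(nodes)}
    cand = [
        (float(dist[idx[u], idx[v]]), v - u, u, v)
        for i, u in enumerate(nodes)
        for v in nodes[i + 1 :]
    ]
    cand.sort()
    cand = [(w, u, v) for w, _, u, v in cand]
    uf = _UnionFind(nodes)
    edges = []
    for w, u, v in cand:
        if uf.union(u, v):
            edges.append((u, v, w))
            if len(edges) == len(nodes) - 1:
                break
    return edges


def build_mst(profiles: GroupProfiles, features: Sequence[str]) -> FeatureMST:
    """MST of the G groups under Euclidean distance over ``features``.

    Distances are taken in the normalized (per-feature standardized) profile
    space.  Equal-weight edges are broken deterministically (smaller group
    gap first, then smaller (u, v)); for a single feature with all-equal
    values this gives the path 1-2-...-G.
    """
    features = list(features)
    if not features:
        raise ValueError("build_mst needs at least one feature")
    if profiles.normalized is None:
        raise ValueError("profiles.normalized is not filled; run normalize_features")
    unknown = [f for f in features if f not in profiles.normalized.columns]
    if unknown:
        raise KeyError(f"unknown feature ids: {unknown}")
    X = profiles.normalized[features].to_numpy(dtype=float)
    nodes = tuple(int(g) for g in profiles.group_ids)
    dist = squareform(pdist(X, metric="euclidean"))
    edges = _kruskal(list(nodes), dist)
    return FeatureMST(nodes=nodes, edges=tuple(edges), source_features=tuple(features))


def tree_cost(values: Mapping[int, float] | pd.Series, tree: FeatureMST) -> float:
    """Total absolute change of ``values`` along the tree's edges."""
    missing = [n for n in tree.nodes if n not in values]
    if missing:
        raise KeyError(f"values missing for nodes: {missing}")
    return float(sum(abs(values[u] - values[v]) for u, v, _ in tree.edges))


def _edge_index(tree: FeatureMST) -> tuple[np.ndarray, np.ndarray]:
    pos = {n: i for i, n in enumerate(tree.nodes)}
    eu = np.array([pos[u] for u, _, _ in tree.edges])
    ev = np.array([pos[v] for _, v, _ in tree.edges])
    return eu, ev


def _perm_costs(vals: np.ndarray, eu: np.ndarray, ev: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Cost of each row-permutation in ``perms`` (n_perm x G) of ``vals``."""
    pv = vals[perms]  # n_perm x G
    return np.abs(pv[:, eu] - pv[:, ev]).sum(axis=1)


def fit_pvalue(
    values: Mapping[int, float] | pd.Series,
    tree: FeatureMST,
    n_perm: int = 1000,
    rng_seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for how well a feature fits a candidate ordering.

    The observed statistic is :func:`tree_cost`; the null shuffles the G
    group values across the tree's nodes.  p = (1 + #{cost_perm <=
    cost_obs}) / (1 + n_perm), so p is never 0 and a constant feature gets
    exactly 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    vals = np.array([float(values[n]) for n in tree.nodes])
    eu, ev = _edge_index(tree)
    obs = float(np.abs(vals[eu] - vals[ev]).sum())
    G = len(tree.nodes)
    perms = np.argsort(rng.random((n_perm, G)), axis=1)
    costs = _perm_costs(vals, eu, ev, perms)
    b = int((costs <= obs * (1 + _TIE_RTOL) + _TIE_ATOL).sum())
    return (1 + b) / (1 + n_perm)


def fit_pvalue_exhaustive(
    values: Mapping[int, float] | pd.Series, tree: FeatureMST
) -> float:
    """Exact version of :func:`fit_pvalue` enumerating all G! permutations.

    Only sensible for small G; p = (1 + #{cost <= obs}) / (1 + G!) with the
    systematic enumeration playing the role of the n_perm draws.
    """
    vals = np.array([float(values[n]) for n in tree.nodes])
    eu, ev = _edge_index(tree)
    obs = float(np.abs(vals[eu] - vals[ev]).sum())
    G = len(tree.nodes)
    perms = np.array(list(_itpermutations(range(G))))
    costs = _perm_costs(vals, eu, ev, perms)
    b = int((costs <= obs * (1 + _TIE_RTOL) + _TIE_ATOL).sum())
    return (1 + b) / (1 + len(perms))


def _tree_rng(seed: int, tree_index: int) -> np.random.Generator:
    """One RNG stream per candidate tree, derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(tree_index,)))


def fit_matrix(
    profiles: GroupProfiles,
    trees: Sequence[FeatureMST],
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> FitMatrix:
    """Cross-compare every feature against every candidate tree.

    The same ``n_perm`` null permutations (one stream per tree, derived
    from ``seed``) are applied to all features, which makes the result
    independent of feature order and gives identical features identical
    rows of p-values.
    """
    if profiles.normalized is None:
        raise ValueError("profiles.normalized is not filled; run normalize_features")
    Z = profiles.normalized.to_numpy(dtype=float)  # G x p
    G, p = Z.shape
    node_pos = {n: i for i, n in enumerate(profiles.group_ids)}
    pvals = np.empty((p, len(trees)))
    for t, tree in enumerate(trees):
        if set(tree.nodes) != set(node_pos):
            raise ValueError(f"tree {t} is over different groups than the profiles")
        eu = np.array([node_pos[u] for u, _, _ in tree.edges])
        ev = np.array([node_pos[v] for _, v, _ in tree.edges])
        obs = np.abs(Z[eu, :] - Z[ev, :]).sum(axis=0)  # p
        rng = _tree_rng(seed, t)
        perms = np.argsort(rng.random((n_perm, G)), axis=1)
        pu = Z[perms[:, eu], :]  # n_perm x E x p
        costs = np.abs(pu - Z[perms[:, ev], :]).sum(axis=1)  # n_perm x p
        b = (costs <= obs * (1 + _TIE_RTOL) + _TIE_ATOL).sum(axis=0)
        pvals[:, t] = (1 + b) / (1 + n_perm)
    pv = pd.DataFrame(pvals, index=profiles.feature_ids, columns=range(len(trees)))
    return FitMatrix(pvalues=pv, alpha=alpha, n_perm=n_perm, seed=seed)


def similarity_matrix(fit: FitMatrix) -> pd.DataFrame:
    """Features x features count of candidate orderings both features fit.

    Symmetric, integer, with S[i][i] = number of trees feature i fits and
    S[i][j] <= min(S[i][i], S[j][j]).
    """
    F = fit.fits.to_numpy(dtype=np.int64)
    S = F @ F.T
    return pd.DataFrame(S, index=fit.pvalues.index, columns=fit.pvalues.index)


def select_progression_features(
    S: pd.DataFrame,
    method: str = "auto",
    manual_ids: Sequence[str] | None = None,
    k_max: int = 10,
    min_size: int = 5,
) -> tuple[str, ...]:
    """Pick the coherent block of features from the similarity matrix.

    ``manual`` returns exactly the requested ids (the workflow of picking a
    highlighted block off a heatmap by eye).  ``auto`` runs Ward-linkage
    hierarchical clustering on D = max(S) - S, cuts at k = 2..k_max, and
    returns the cluster (of size >= min_size) with the greatest total
    within-cluster similarity in excess of the matrix-wide mean,
    sum_{i!=j in C} (S_ij - mean_offdiag(S)).  The excess criterion prefers
    the full coherent block over its densest core, while the chance-level
    baseline keeps diffuse background clusters from winning on size alone.
    Deterministic given S.
    """
    if method == "manual":
        if not manual_ids:
            raise ValueError("manual selection requires explicit feature ids")
        unknown = [f for f in manual_ids if f not in S.index]
        if unknown:
            raise KeyError(f"manual ids not in similarity matrix: {unknown}")
        return tuple(manual_ids)
    if method != "auto":
        raise ValueError(f"unknown selection method {method!r}")
    p = S.shape[0]
    if p < min_size:
        raise ValueError(f"auto selection needs at least min_size={min_size} features")
    Sv = S.to_numpy(dtype=float)
    if Sv.max() <= 0:
        warnings.warn("similarity matrix is all zeros; no coherent block", UserWarning)
        return ()
    D = Sv.max() - Sv
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="ward")
    offdiag = ~np.eye(p, dtype=bool)
    baseline = float(Sv[offdiag].mean())
    best: tuple[float, int, tuple[str, ...]] | None = None
    for k in range(2, min(k_max, p) + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            if len(members) < min_size:
                continue
            block = Sv[np.ix_(members, members)]
            off = block[~np.eye(len(members), dtype=bool)]
            score = float((off - baseline).sum())
            cand = (score, len(members), tuple(S.index[members]))
            if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
    if best is None:
        raise ValueError(f"no cluster of size >= {min_size} found")
    return best[2]


def overall_mst(profiles: GroupProfiles, selected: Sequence[str]) -> FeatureMST:
    """Joint MST of the groups over all selected features at once."""
    if not selected:
        raise ValueError("overall_mst requires a non-empty feature selection")
    return build_mst(profiles, selected)


def _bfs(adj: dict[int, list[int]], start: int) -> tuple[dict[int, int], dict[int, int]]:
    dist = {start: 0}
    parent: dict[int, int] = {}
    queue = [start]
    while queue:
        nxt = []
        for u in queue:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    parent[v] = u
                    nxt.append(v)
        queue = nxt
    return dist, parent


def _farthest(dist: dict[int, int]) -> int:
    # max distance, ties toward the smaller node id
    return min(dist, key=lambda n: (-dist[n], n))


def extract_ordering(tree: FeatureMST, weighted: bool = False) -> ProgressionResult:
    """Diameter path of the tree as the progression ordering.

    Two passes of farthest-node search (hop count by default; edge weights
    if ``weighted``).  Off-path groups map to their nearest on-path group,
    ties toward the smaller group id.  The path orientation is arbitrary;
    it is returned with the smaller endpoint first, and callers must treat
    it as reversible.
    """
    adj = tree.adjacency()
    if len(tree.nodes) == 1:
        return ProgressionResult((), tree, (tree.nodes[0],), {})
    if weighted:
        import networkx as nx

        g = nx.Graph()
        g.add_weighted_edges_from(tree.edges)
        start = min(tree.nodes)
        d0 = nx.single_source_dijkstra_path_length(g, start)
        u = min(d0, key=lambda n: (-d0[n], n))
        d1, paths = nx.single_source_dijkstra(g, u)
        v = min(d1, key=lambda n: (-d1[n], n))
        path = paths[v]
        dist_from_u, _ = _bfs(adj, u)
    else:
        d0, _ = _bfs(adj, min(tree.nodes))
        u = _farthest(d0)
        dist_from_u, parent = _bfs(adj, u)
        v = _farthest(dist_from_u)
        path = [v]
        while path[-1] != u:
            path.append(parent[path[-1]])
        path.reverse()
    on_path = set(path)
    off_path: dict[int, int] = {}
    for n in sorted(set(tree.nodes) - on_path):
        d, _ = _bfs(adj, n)
        off_path[n] = min(on_path, key=lambda m: (d[m], m))
    if path[0] > path[-1]:
        path.reverse()
    return ProgressionResult(
        selected_features=tree.source_features,
        overall_tree=tree,
        ordering=tuple(path),
        off_path=off_path,
    )


def discover_progression(
    profiles: GroupProfiles,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    select: str = "auto",
    manual_ids: Sequence[str] | None = None,
    k_max: int = 10,
    min_size: int = 5,
) -> ProgressionResult:
    """Full discovery chain: per-feature trees, cross-fit, block, ordering."""
    trees = [build_mst(profiles, [f]) for f in profiles.feature_ids]
    fit = fit_matrix(profiles, trees, alpha=alpha, n_perm=n_perm, seed=seed)
    S = similarity_matrix(fit)
    selected = select_progression_features(
        S, method=select, manual_ids=manual_ids, k_max=k_max, min_size=min_size
    )
    if not selected:
        raise ValueError("no coherent progression block found")
    return extract_ordering(overall_mst(profiles, selected))


def compare_orderings(pred: Sequence[int], truth: Sequence[int]) -> float:
    """|Spearman| between positions in a recovered and a reference ordering.

    Computed on the elements common to both sequences, so a partial
    (diameter-path) ordering is scored only on the groups it places;
    orientation-invariant through the absolute value.
    """
    pos_pred = {x: i for i, x in enumerate(pred)}
    pos_truth = {x: i for i, x in enumerate(truth)}
    common = [x for x in truth if x in pos_pred]
    if len(common) < 3:
        raise ValueError("need at least 3 common elements to compare orderings")
    rho = spearmanr([pos_pred[x] for x in common], [pos_truth[x] for x in common]).statistic
    # round away float fuzz so an exact rank agreement scores exactly 1.0
    return float(round(abs(rho), 12))
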