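"""Cluster-based permutation test over electrodes.

Paired two-sided t-tests are computed per channel; channels exceeding the
cluster-forming threshold are grouped into spatially connected clusters
(separately by sign), each scored by its summed t statistic.  The null
distribution of the maximum absolute cluster score is built by randomly
sign-flipping each subject's condition difference (exchangeability of the
paired labels), and each observed cluster receives a Monte-Carlo p-value
with the (b+1)/(m+1) correction.  Family-wise error is controlled at the
cluster-level alpha because every observed cluster is compared against the
same max-statistic null distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import Delaunay, QhullError


@dataclass
class AdjacencyGraph:
    """Symmetric channel adjacency used for spatial clustering."""

    labels: list[str]
    edges: set[tuple[int, int]]          # index pairs, i < j
    neighbors: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.neighbors:
            nb: list[list[int]] = [[] for _ in self.labels]
            for i, j in self.edges:
                nb[i].append(j)
                nb[j].append(i)
            self.neighbors = nb

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def is_connected(self) -> bool:
        if not self.labels:
            return True
        seen = {0}
        stack = [0]
        while stack:
            for j in self.neighbors[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == len(self.labels)


def build_adjacency(
    positions: dict[str, tuple[float, float]],
    method: str = "delaunay",
    prune_quantile: float | None = 0.98,
) -> AdjacencyGraph:
    """Channel adjacency from 2-D positions via Delaunay triangulation.

    Long Delaunay edges (hull shortcuts) can optionally be pruned at a
    length quantile.  Collinear layouts fall back to a nearest-neighbour
    chain along the line.
    """
    labels = list(positions)
    pts = np.asarray([positions[l] for l in labels], dtype=float)
    if len(labels) != len({tuple(p) for p in pts}):
        raise ValueError("duplicate channel positions")
    if method != "delaunay":
        raise ValueError(f"unknown adjacency method {method!r}")

    edges: set[tuple[int, int]] = set()
    if len(labels) < 2:
        return AdjacencyGraph(labels=labels, edges=edges)
    degenerate = len(labels) == 2 or np.linalg.matrix_rank(pts - pts.mean(0)) < 2
    if not degenerate:
        try:
            tri = Delaunay(pts)
            for simplex in tri.simplices:
                for a in range(3):
                    for b in range(a + 1, 3):
                        i, j = sorted((simplex[a], simplex[b]))
                        edges.add((i, j))
        except QhullError:
            degenerate = True
    if degenerate:
        # chain consecutive channels along the dominant direction
        d = pts - pts.mean(0)
        u = np.linalg.svd(d, full_matrices=False)[2][0]
        order = np.argsort(d @ u)
        for a, b in zip(order[:-1], order[1:]):
            edges.add(tuple(sorted((int(a), int(b)))))
    elif prune_quantile is not None and len(edges) > 4:
        lengths = {e: np.linalg.norm(pts[e[0]] - pts[e[1]]) for e in edges}
        cut = np.quantile(list(lengths.values()), prune_quantile)
        pruned = {e for e, L in lengths.items() if L <= cut}
        g = AdjacencyGraph(labels=labels, edges=pruned)
        if g.is_connected():  # never disconnect the layout by pruning
            return g
    return AdjacencyGraph(labels=labels, edges=edges)


@dataclass
class Cluster:
    channels: list[str]
    sign: int
    stat: float          # summed t over member channels
    p: float             # Monte-Carlo p, (b+1)/(m+1)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_values: np.ndarray
    channel_labels: list[str]
    n_permutations: int
    cluster_alpha: float
    cluster_forming_alpha: float
    seed: int | None = None
    tail: str = "two-sided"

    def significant_clusters(self, alpha: float | None = None) -> list[Cluster]:
        a = self.cluster_alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p <= a]


def _components(mask: np.ndarray, neighbors: list[list[int]]) -> list[list[int]]:
    """Connected components of the supra-threshold subgraph."""
    comps: list[list[int]] = []
    seen = np.zeros(len(mask), dtype=bool)
    for start in np.flatnonzero(mask):
        if seen[start]:
            continue
        comp = [int(start)]
        seen[start] = True
        stack = [int(start)]
        while stack:
            for j in neighbors[stack.pop()]:
                if mask[j] and not seen[j]:
                    seen[j] = True
                    comp.append(j)
                    stack.append(j)
        comps.append(comp)
    return comps


def _max_cluster_stat(t: np.ndarray, thresh: float,
                      neighbors: list[list[int]]) -> float:
    """Largest |summed t| over sign-specific supra-threshold clusters."""
    best = 0.0
    for sign in (1, -1):
        mask = (sign * t) > thresh
        if not mask.any():
            continue
        for comp in _components(mask, neighbors):
            s = abs(float(t[comp].sum()))
            if s > best:
                best = s
    return best


def cluster_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    adjacency: AdjacencyGraph,
    n_perm: int = 5000,
    cluster_alpha: float = 0.05,
    cluster_forming_alpha: float = 0.05,
    seed: int | None = None,
) -> ClusterResult:
    """Paired cluster permutation test between two conditions.

    ``cond_a`` and ``cond_b`` are subjects x channels matrices with the
    same subject rows.  Returns all supra-threshold clusters with
    Monte-Carlo p-values against the max-statistic sign-flip null.
    """
    a = np.asarray(cond_a, float)
    b = np.asarray(cond_b, float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("conditions must be equal-shape subjects x channels")
    n_subj, n_ch = a.shape
    if n_ch != adjacency.n_channels:
        raise ValueError("channel count does not match the adjacency graph")
    if n_subj < 5:
        raise ValueError("need at least 5 paired subjects")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: p-values will be coarse",
                      stacklevel=2)

    d = a - b
    thresh = float(stats.t.ppf(1.0 - cluster_forming_alpha / 2.0, n_subj - 1))

    def t_stats(signs: np.ndarray) -> np.ndarray:
        # signs: n_perm x n_subj of +-1; returns n_perm x n_ch paired t
        m = signs @ d / n_subj
        q = np.mean(d * d, axis=0)          # invariant under sign flips
        var = (q[None, :] - m * m) * (n_subj / (n_subj - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / np.sqrt(var / n_subj)
        # 0/0 (no difference at all) counts as t=0; a constant non-zero
        # difference is capped at a huge finite t
        return np.nan_to_num(t, nan=0.0, posinf=1e9, neginf=-1e9)

    t_obs = t_stats(np.ones((1, n_subj)))[0]

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    t_perm = t_stats(signs)
    null_max = np.fromiter(
        (_max_cluster_stat(t_perm[p], thresh, adjacency.neighbors)
         for p in range(n_perm)),
        dtype=float, count=n_perm)

    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = (sign * t_obs) > thresh
        if not mask.any():
            continue
        for comp in _components(mask, adjacency.neighbors):
            s = float(t_obs[comp].sum())
            p = (np.count_nonzero(null_max >= abs(s)) + 1) / (n_perm + 1)
            clusters.append(Cluster(
                channels=[adjacency.labels[i] for i in comp],
                sign=sign, stat=s, p=float(p)))
    clusters.sort(key=lambda c: abs(c.stat), reverse=True)
    return ClusterResult(clusters=clusters, t_values=t_obs,
                         channel_labels=list(adjacency.labels),
                         n_permutations=n_perm, cluster_alpha=cluster_alpha,
                         cluster_forming_alpha=cluster_forming_alpha,
                         seed=seed)
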