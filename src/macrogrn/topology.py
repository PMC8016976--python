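"""Network topology statistics: the centrality battery, hub calling,
scale-free fit, random-graph baseline, group comparisons and
hypergeometric enrichment.

Conventions (stated explicitly because they differ across tools):

* betweenness is normalized to [0, 1] by (n-1)(n-2)/2 unordered pairs;
* stress counts geodesics through a node over unordered source-target
  pairs, endpoints excluded;
* the topological coefficient of node i is mean_j J(i, j) / k_i over all
  partners j that share at least one neighbor with i, where J is the
  shared-neighbor count plus one if i and j are adjacent;
* average shortest path length is taken over the node's own connected
  component (NaN for isolated nodes);
* connectivity is the weighted degree (edge weights default to 1);
* all shortest-path quantities treat the graph as unweighted.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UsageError, ValidationError

DEFAULT_HUB_THRESHOLD = 50
#: at or below this pooled sample size the rank-sum test enumerates all
#: group assignments exactly (handles ties, unlike the standard recurrence)
EXACT_RANKSUM_MAX_N = 16


def _bfs_counts(adj: list[np.ndarray], source: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Distances and geodesic counts from one source (unweighted BFS)."""
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    dist[source] = 0.0
    sigma[source] = 1.0
    queue = deque([source])
    while queue:
        v = queue.popleft()
        dv = dist[v]
        for w in adj[v]:
            if np.isinf(dist[w]):
                dist[w] = dv + 1.0
                queue.append(w)
            if dist[w] == dv + 1.0:
                sigma[w] += sigma[v]
    return dist, sigma


def compute_centralities(
    graph: nx.Graph, hub_threshold: int = DEFAULT_HUB_THRESHOLD
) -> pd.DataFrame:
    """Per-node centrality records for a simple undirected graph.

    Returns a DataFrame indexed by node (sorted) with columns degree,
    betweenness, stress, clustering_coefficient, topological_coefficient,
    connectivity, avg_shortest_path and is_hub50.
    """
    if nx.number_of_selfloops(graph) > 0:
        raise ValidationError("graph contains self-loops")
    nodes = sorted(graph.nodes(), key=str)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [np.fromiter((index[u] for u in graph[v]), dtype=int) for v in nodes]

    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for i in range(n):
        dist[i], sigma[i] = _bfs_counts(adj, i, n)

    # stress: for every unordered pair (s, t), add sigma(s,v) * sigma(v,t)
    # whenever v lies on a geodesic (d(s,v) + d(v,t) = d(s,t)), v not an
    # endpoint.  sigma and dist are symmetric for undirected graphs.
    stress = np.zeros(n)
    finite = np.isfinite(dist)
    for v in range(n):
        on_path = finite & (dist[:, [v]] + dist[[v], :] == dist)
        counts = np.outer(sigma[v], sigma[v]) * on_path
        counts[v, :] = 0.0
        counts[:, v] = 0.0
        stress[v] = np.triu(counts, k=1).sum()

    betweenness = nx.betweenness_centrality(graph, normalized=True)
    clustering = nx.clustering(graph)

    neighbor_sets = {v: set(graph[v]) for v in nodes}
    topo = np.zeros(n)
    for i, v in enumerate(nodes):
        nv = neighbor_sets[v]
        k = len(nv)
        if k == 0:
            continue
        partners: dict = {}
        for u in nv:
            for w in neighbor_sets[u]:
                if w != v:
                    partners[w] = partners.get(w, 0) + 1
        if not partners:
            continue
        total = 0.0
        for w, shared in partners.items():
            total += shared + (1 if w in nv else 0)
        topo[i] = total / (len(partners) * k)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        reach = finite.copy()
        np.fill_diagonal(reach, False)
        path_sums = np.where(reach, dist, 0.0).sum(axis=1)
        n_reach = reach.sum(axis=1)
        avg_path = np.where(n_reach > 0, path_sums / np.maximum(n_reach, 1), np.nan)

    degree = np.array([graph.degree(v) for v in nodes])
    connectivity = np.array(
        [sum(d.get("weight", 1.0) for d in graph[v].values()) for v in nodes]
    )
    return pd.DataFrame(
        {
            "degree": degree,
            "betweenness": [betweenness[v] for v in nodes],
            "stress": stress.astype(np.int64),
            "clustering_coefficient": [clustering[v] for v in nodes],
            "topological_coefficient": topo,
            "connectivity": connectivity,
            "avg_shortest_path": avg_path,
            "is_hub50": degree >= hub_threshold,
        },
        index=pd.Index(nodes, name="node"),
    )


def hub_genes(
    records: pd.DataFrame, hub_threshold: int = DEFAULT_HUB_THRESHOLD
) -> frozenset:
    """Nodes whose degree reaches the hub threshold (>= 50 by default)."""
    return frozenset(records.index[records["degree"] >= hub_threshold])


def powerlaw_fit_r2(
    degrees: Sequence[float] | np.ndarray, n_bins: int = 10
) -> tuple[float, float]:
    """Scale-free fit: R^2 and slope of log10(frequency) on log10(degree).

    Integer-valued inputs with at most ``n_bins`` distinct values use one
    bin per distinct value with raw counts; otherwise equal-occupancy
    bins are formed from quantiles and frequencies are count densities
    (count / bin width), which preserves the power-law slope.  Zero or
    negative values are dropped with a warning; fewer than 3 usable bins
    is an error.
    """
    k = np.asarray(degrees, dtype=float)
    nonpos = k <= 0
    if nonpos.any():
        warnings.warn(
            f"dropping {int(nonpos.sum())} non-positive degree value(s)", stacklevel=2
        )
        k = k[~nonpos]
    if k.size == 0:
        raise UsageError("no positive degree values")

    distinct = np.unique(k)
    integral = np.allclose(k, np.round(k))
    if integral and distinct.size <= n_bins:
        if distinct.size < 3:
            raise UsageError(
                f"only {distinct.size} distinct degree value(s); need >= 3 bins"
            )
        centers = distinct
        freq = np.array([(k == v).sum() for v in distinct], dtype=float)
    else:
        edges = np.unique(np.quantile(k, np.linspace(0.0, 1.0, n_bins + 1)))
        if edges.size < 4:
            raise UsageError("degree distribution collapses to fewer than 3 bins")
        counts, _ = np.histogram(k, bins=edges)
        widths = np.diff(edges)
        keep = counts > 0
        if keep.sum() < 3:
            raise UsageError("fewer than 3 non-empty degree bins")
        centers = np.array(
            [k[(k >= lo) & (k <= hi if i == len(edges) - 2 else k < hi)].mean()
             if c else np.nan
             for i, (lo, hi, c) in enumerate(zip(edges[:-1], edges[1:], counts))]
        )[keep]
        freq = (counts / widths)[keep]
    fit = stats.linregress(np.log10(centers), np.log10(freq))
    return float(fit.rvalue ** 2), float(fit.slope)


def random_reference_graph(n_nodes: int, n_edges: int, seed: int = 0) -> nx.Graph:
    """Uniform simple graph with exactly ``n_edges`` edges (Erdos-Renyi
    G(n, m)); deterministic given the seed."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise UsageError(
            f"{n_edges} edges infeasible for {n_nodes} nodes (max {max_edges})"
        )
    if n_edges < 0:
        raise UsageError("n_edges must be >= 0")
    return nx.gnm_random_graph(n_nodes, n_edges, seed=seed)


def _mann_whitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of group a over group b, with 0.5 per tie."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def compare_group_centrality(
    values_a: Sequence[float],
    values_b: Sequence[float],
    paired: bool = False,
) -> tuple[float, float]:
    """Two-sided rank test between two groups of centrality values.

    Unpaired groups use a Mann-Whitney U test (exact by full enumeration
    of group assignments when the pooled sample is small, normal
    approximation otherwise); paired inputs use the Wilcoxon signed-rank
    test.  All-zero paired differences are degenerate and return p = 1
    with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise UsageError("both groups must be non-empty")
    if paired:
        if a.size != b.size:
            raise UsageError("paired comparison needs equal-length groups")
        diffs = a - b
        if np.all(diffs == 0):
            warnings.warn("all paired differences are zero; p set to 1", stacklevel=2)
            return 0.0, 1.0
        res = stats.wilcoxon(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)

    u_obs = _mann_whitney_u(a, b)
    n1, n2 = a.size, b.size
    mu = n1 * n2 / 2.0
    if n1 + n2 <= EXACT_RANKSUM_MAX_N:
        pooled = np.concatenate([a, b])
        dev = abs(u_obs - mu)
        hits = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            u = _mann_whitney_u(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def hypergeom_enrichment(
    overlap: int, set_a_size: int, set_b_size: int, universe_size: int
) -> float:
    """One-sided over-representation p-value, P(X >= overlap) for X
    hypergeometric(universe, set_a, draws = set_b)."""
    for name, val in (
        ("overlap", overlap),
        ("set_a_size", set_a_size),
        ("set_b_size", set_b_size),
        ("universe_size", universe_size),
    ):
        if val < 0:
            raise UsageError(f"{name} must be >= 0")
    if set_a_size > universe_size or set_b_size > universe_size:
        raise UsageError("set sizes cannot exceed the universe")
    if overlap > min(set_a_size, set_b_size):
        raise UsageError("overlap cannot exceed either set size")
    if overlap < max(0, set_a_size + set_b_size - universe_size):
        raise UsageError("overlap smaller than the forced minimum; counts inconsistent")
    p = float(stats.hypergeom.sf(overlap - 1, universe_size, set_a_size, set_b_size))
    return min(max(p, 0.0), 1.0)
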