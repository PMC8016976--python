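"""Centrality battery against brute-force path enumeration, scale-free
fit, random baseline, rank tests and hypergeometric enrichment."""

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from macrogrn.exceptions import UsageError, ValidationError
from macrogrn.topology import (
    compare_group_centrality,
    compute_centralities,
    hub_genes,
    hypergeom_enrichment,
    powerlaw_fit_r2,
    random_reference_graph,
)


# ---------------------------------------------------------------------------
# brute-force oracle: enumerate every shortest path explicitly


def brute_force_centralities(g: nx.Graph):
    """Independent oracle via explicit path enumeration and set counting."""
    nodes = sorted(g.nodes(), key=str)
    n = len(nodes)
    stress = {v: 0 for v in nodes}
    betw = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            stress[v] += through
            betw[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2
    betw = {v: (b / norm if norm > 0 else 0.0) for v, b in betw.items()}

    clustering = {}
    topo = {}
    avg_path = {}
    for v in nodes:
        nv = set(g[v])
        k = len(nv)
        links = sum(1 for a, b in combinations(sorted(nv, key=str), 2)
                    if g.has_edge(a, b))
        clustering[v] = 2 * links / (k * (k - 1)) if k >= 2 else 0.0
        js = []
        for w in nodes:
            if w == v:
                continue
            shared = len(nv & set(g[w]))
            if shared > 0:
                js.append(shared + (1 if g.has_edge(v, w) else 0))
        topo[v] = (sum(js) / len(js) / k) if js and k > 0 else 0.0
        dists = [len(nx.shortest_path(g, v, w)) - 1 for w in nodes
                 if w != v and nx.has_path(g, v, w)]
        avg_path[v] = sum(dists) / len(dists) if dists else float("nan")
    return stress, betw, clustering, topo, avg_path


def _assert_matches_oracle(g):
    rec = compute_centralities(g)
    stress, betw, clustering, topo, avg_path = brute_force_centralities(g)
    for v in rec.index:
        assert rec.loc[v, "stress"] == stress[v], f"stress({v})"
        assert rec.loc[v, "betweenness"] == pytest.approx(betw[v], abs=1e-9)
        assert rec.loc[v, "clustering_coefficient"] == pytest.approx(
            clustering[v], abs=1e-9)
        assert rec.loc[v, "topological_coefficient"] == pytest.approx(
            topo[v], abs=1e-9)
        if math.isnan(avg_path[v]):
            assert math.isnan(rec.loc[v, "avg_shortest_path"])
        else:
            assert rec.loc[v, "avg_shortest_path"] == pytest.approx(
                avg_path[v], abs=1e-9)


class TestComputeCentralities:
    def test_path_graph_center(self):
        g = nx.path_graph(["a", "b", "c"])
        rec = compute_centralities(g)
        assert rec.loc["b", "betweenness"] == 1.0
        assert rec.loc["b", "stress"] == 1
        assert rec.loc["b", "degree"] == 2

    def test_triangle_closed_form(self):
        g = nx.complete_graph(3)
        rec = compute_centralities(g)
        assert (rec["clustering_coefficient"] == 1.0).all()
        # J = 1 shared neighbor + 1 for adjacency = 2, k = 2 -> T = 1
        assert (rec["topological_coefficient"] == 1.0).all()

    def test_four_cycle_symmetry_and_oracle(self):
        g = nx.cycle_graph(4)
        rec = compute_centralities(g)
        for col in ("betweenness", "stress", "clustering_coefficient",
                    "topological_coefficient", "avg_shortest_path"):
            assert rec[col].nunique() == 1
        _assert_matches_oracle(g)

    def test_star_betweenness_normalization(self):
        g = nx.star_graph(5)
        rec = compute_centralities(g)
        assert rec.loc[0, "betweenness"] == 1.0
        assert (rec.loc[1:, "betweenness"] == 0.0).all()

    def test_random_small_graphs_match_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            n = int(rng.integers(2, 8))
            p = float(rng.uniform(0.25, 0.9))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
            _assert_matches_oracle(g)

    def test_disconnected_components_use_own_component(self):
        g = nx.Graph([("a", "b"), ("c", "d"), ("d", "e")])
        g.add_node("lonely")
        rec = compute_centralities(g)
        assert rec.loc["a", "avg_shortest_path"] == 1.0
        assert rec.loc["c", "avg_shortest_path"] == pytest.approx(1.5)
        assert math.isnan(rec.loc["lonely", "avg_shortest_path"])

    def test_weighted_connectivity(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.5)
        g.add_edge("a", "c", weight=0.25)
        rec = compute_centralities(g)
        assert rec.loc["a", "connectivity"] == pytest.approx(0.75)
        assert rec.loc["a", "degree"] == 2

    def test_self_loop_rejected(self):
        g = nx.Graph([("a", "a")])
        with pytest.raises(ValidationError, match="self-loop"):
            compute_centralities(g)


class TestHubGenes:
    def test_boundary_at_threshold(self):
        g = nx.star_graph(50)  # center degree exactly 50
        rec = compute_centralities(g)
        assert hub_genes(rec) == {0}
        assert rec.loc[0, "is_hub50"]
        assert hub_genes(rec, hub_threshold=51) == frozenset()

    def test_empty_graph(self):
        rec = compute_centralities(nx.Graph())
        assert hub_genes(rec) == frozenset()


class TestPowerlawFit:
    def test_exact_power_law_fixture(self):
        """freq(k) = 256 / k^2 over k in {1,2,4,8,16}: perfect log-log line."""
        degrees = np.repeat([1, 2, 4, 8, 16], [256, 64, 16, 4, 1])
        r2, slope = powerlaw_fit_r2(degrees)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert slope == pytest.approx(-2.0, abs=1e-9)

    def test_regular_graph_rejected(self):
        with pytest.raises(UsageError):
            powerlaw_fit_r2([4] * 100)

    def test_preferential_attachment_beats_matched_random(self):
        pa = nx.barabasi_albert_graph(2000, 3, seed=42)
        er = nx.gnm_random_graph(2000, pa.number_of_edges(), seed=42)
        r2_pa, slope_pa = powerlaw_fit_r2([d for _, d in pa.degree()])
        r2_er, _ = powerlaw_fit_r2([d for _, d in er.degree()])
        assert r2_pa > r2_er
        assert slope_pa < 0


class TestRandomReferenceGraph:
    def test_complete_graph_when_forced(self):
        g = random_reference_graph(5, 10, seed=1)
        assert g.number_of_edges() == 10
        assert nx.density(g) == 1.0

    def test_zero_edges(self):
        assert random_reference_graph(4, 0, seed=1).number_of_edges() == 0

    def test_handshake_identity_and_determinism(self):
        g1 = random_reference_graph(30, 60, seed=7)
        g2 = random_reference_graph(30, 60, seed=7)
        assert sum(d for _, d in g1.degree()) == 120
        assert set(g1.edges()) == set(g2.edges())

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(UsageError, match="infeasible"):
            random_reference_graph(4, 7, seed=0)


class TestCompareGroupCentrality:
    def test_identical_groups_exact_p_is_one(self):
        _, p = compare_group_centrality([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_complete_separation_exact_p(self):
        """{1,2,3} vs {10,11,12}: U = 9, 2 of 20 assignments as extreme."""
        u, p = compare_group_centrality([1, 2, 3], [10, 11, 12])
        assert u == 0.0  # first group entirely below the second
        assert p == pytest.approx(0.1)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=6), rng.normal(1, 1, size=5)
        _, p1 = compare_group_centrality(a, b)
        _, p2 = compare_group_centrality(b, a)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_swap_symmetry_large_sample(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=40), rng.normal(0.5, 1, size=30)
        _, p1 = compare_group_centrality(a, b)
        _, p2 = compare_group_centrality(b, a)
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_paired_all_zero_differences_degenerate(self):
        with pytest.warns(UserWarning, match="zero"):
            stat, p = compare_group_centrality([1, 2], [1, 2], paired=True)
        assert p == 1.0

    def test_paired_wilcoxon_runs(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=20)
        _, p = compare_group_centrality(a, a + 1, paired=True)
        assert p < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(UsageError, match="non-empty"):
            compare_group_centrality([], [1.0])


class TestHypergeomEnrichment:
    def test_worked_example(self):
        # C(5,4) * C(5,0) / C(10,4) = 5 / 210
        assert hypergeom_enrichment(4, 5, 4, 10) == pytest.approx(
            5 / 210, abs=1e-12)

    def test_zero_draws_gives_one(self):
        assert hypergeom_enrichment(0, 5, 0, 10) == 1.0

    def test_everything_overlaps_gives_one(self):
        assert hypergeom_enrichment(6, 6, 6, 6) == 1.0

    def test_matches_brute_force_enumeration_small_universe(self):
        """P(X >= o) equals the explicit combinatorial sum."""
        for universe in (5, 8, 12):
            for a in range(universe + 1):
                for b in range(universe + 1):
                    lo = max(0, a + b - universe)
                    for o in range(lo, min(a, b) + 1):
                        expected = sum(
                            math.comb(a, j) * math.comb(universe - a, b - j)
                            for j in range(o, min(a, b) + 1)
                        ) / math.comb(universe, b)
                        got = hypergeom_enrichment(o, a, b, universe)
                        assert got == pytest.approx(expected, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(UsageError):
            hypergeom_enrichment(5, 4, 6, 10)
        with pytest.raises(UsageError):
            hypergeom_enrichment(0, 8, 8, 10)  # forced minimum overlap is 6
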