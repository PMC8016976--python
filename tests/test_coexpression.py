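"""Soft thresholding, TOM arithmetic, module detection and edge export."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from macrogrn import synthetic_data as sd
from macrogrn.coexpression import (
    adjacency_from_correlation,
    build_adjacency_tom,
    coexpression_edges,
    detect_modules,
    pick_soft_threshold,
)
from macrogrn.exceptions import UsageError


def _random_log_matrix(seed, n_genes=40, n_samples=8):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(5, 1, size=(n_genes, n_samples)),
                        index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(n_samples)])


class TestAdjacency:
    def test_bounds_and_power_monotonicity(self):
        df = _random_log_matrix(0)
        corr = pd.DataFrame(np.corrcoef(df), index=df.index, columns=df.index)
        a1 = adjacency_from_correlation(corr, 1).to_numpy()
        a6 = adjacency_from_correlation(corr, 6).to_numpy()
        assert a1.min() >= 0 and a1.max() <= 1
        assert (a6 <= a1 + 1e-12).all()

    def test_constant_gene_dropped_with_warning(self):
        df = _random_log_matrix(1)
        df.loc["flat"] = 2.0
        with pytest.warns(UserWarning, match="constant"):
            _, table = pick_soft_threshold(df, powers=[2])
        assert len(table) == 1


class TestPickSoftThreshold:
    def test_forced_single_power(self):
        df = _random_log_matrix(2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            power, table = pick_soft_threshold(df, powers=[18], target_fit=0.99)
        assert power == 18

    def test_higher_power_improves_fit_on_random_genes(self):
        df = _random_log_matrix(3, n_genes=300, n_samples=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, table = pick_soft_threshold(df, powers=[1, 12])
        fit = dict(zip(table["power"], table["fit"]))
        assert fit[12] > fit[1]

    def test_empty_powers_rejected(self):
        with pytest.raises(UsageError, match="powers"):
            pick_soft_threshold(_random_log_matrix(4), powers=[])


class TestTom:
    def test_all_ones_adjacency_gives_tom_one(self):
        # three genes, pairwise |cor| = 1: TOM = (1 + 1) / (2 + 1 - 1) = 1
        base = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame([base, 2 * base, 3 * base + 1],
                          index=list("abc"), columns=list("wxyz"))
        _, tom = build_adjacency_tom(df, power=1)
        assert np.allclose(tom.to_numpy(), 1.0)

    def test_zero_adjacency_gives_zero_off_diagonal(self):
        # orthogonal patterns with exactly zero correlation
        df = pd.DataFrame(
            [[1.0, 1.0, -1.0, -1.0], [1.0, -1.0, 1.0, -1.0], [1.0, -1.0, -1.0, 1.0]],
            index=list("abc"), columns=list("wxyz"))
        _, tom = build_adjacency_tom(df, power=1)
        t = tom.to_numpy()
        off = t[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0, atol=1e-12)
        assert np.allclose(np.diag(t), 1.0)

    def test_tom_symmetric_and_bounded_on_random_input(self):
        df = _random_log_matrix(5, n_genes=60)
        _, tom = build_adjacency_tom(df, power=6)
        t = tom.to_numpy()
        assert np.allclose(t, t.T, atol=1e-10)
        assert t.min() >= 0.0 and t.max() <= 1.0


class TestDetectModules:
    def _planted_tom(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        t = rng.uniform(0.0, 0.1, size=(n, n))
        half = n // 2
        t[:half, :half] = rng.uniform(0.6, 0.9, size=(half, half))
        t[half:, half:] = rng.uniform(0.6, 0.9, size=(n - half, n - half))
        t = (t + t.T) / 2
        np.fill_diagonal(t, 1.0)
        idx = [f"g{i}" for i in range(n)]
        return pd.DataFrame(t, index=idx, columns=idx), [0] * half + [1] * (n - half)

    def test_two_planted_blocks_recovered(self):
        tom, planted = self._planted_tom()
        labels = detect_modules(tom, min_module_size=10)
        assert adjusted_rand_score(planted, labels.tolist()) >= 0.8
        assert labels.nunique() == 2

    def test_identical_rows_form_single_module(self):
        n = 20
        t = np.full((n, n), 0.8)
        np.fill_diagonal(t, 1.0)
        idx = [f"g{i}" for i in range(n)]
        labels = detect_modules(pd.DataFrame(t, index=idx, columns=idx),
                                min_module_size=5)
        assert labels.nunique() == 1
        assert (labels == "M1").all()

    def test_min_size_above_n_leaves_all_unassigned(self):
        tom, _ = self._planted_tom(n=20)
        labels = detect_modules(tom, min_module_size=50)
        assert (labels == "grey").all()

    def test_deterministic(self):
        tom, _ = self._planted_tom(seed=3)
        assert detect_modules(tom).equals(detect_modules(tom))

    def test_min_size_below_two_rejected(self):
        tom, _ = self._planted_tom()
        with pytest.raises(UsageError, match="min_module_size"):
            detect_modules(tom, min_module_size=1)


class TestCoexpressionEdges:
    def _adjacency(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 0.9, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        idx = [f"g{i}" for i in range(n)]
        return pd.DataFrame(a, index=idx, columns=idx)

    def test_threshold_above_max_gives_no_edges(self):
        adj = self._adjacency()
        net = coexpression_edges(adj, edge_threshold=0.999)
        assert len(net.edges) == 0

    def test_low_threshold_on_all_ones_gives_complete_graph(self):
        n = 10
        a = np.ones((n, n)) - np.eye(n)
        idx = [f"g{i}" for i in range(n)]
        net = coexpression_edges(pd.DataFrame(a, index=idx, columns=idx),
                                 edge_threshold=1e-9)
        assert len(net.edges) == n * (n - 1) // 2

    def test_auto_threshold_hits_target_mean_degree(self):
        adj = self._adjacency(n=100)
        net = coexpression_edges(adj, target_mean_degree=10.0)
        mean_degree = 2 * len(net.edges) / 100
        assert mean_degree == pytest.approx(10.0, abs=1.0)

    def test_connectivity_from_full_adjacency_correlates_with_degree(self):
        adj = self._adjacency(seed=4, n=80)
        net = coexpression_edges(adj, target_mean_degree=10.0)
        degree = pd.concat([net.edges["gene_a"], net.edges["gene_b"]]) \
            .value_counts().reindex(adj.index, fill_value=0)
        np.testing.assert_allclose(net.connectivity.to_numpy(),
                                   adj.to_numpy().sum(axis=0))
        r, _ = stats.pearsonr(net.connectivity, degree)
        assert r > 0

    def test_connectivity_correlates_with_degree_on_synthetic_bundle(
            self, small_truth, small_params):
        """On simulated data the soft connectivity and the thresholded
        degree agree (the qualitative hub property)."""
        expr, _, _, _ = sd.simulate_bundle(small_truth, small_params)
        logm = np.log2(expr.values.loc[list(small_truth.genes)] + 1)
        adj, _ = build_adjacency_tom(logm, 6)
        net = coexpression_edges(adj, target_mean_degree=10.0)
        degree = pd.concat([net.edges["gene_a"], net.edges["gene_b"]]) \
            .value_counts().reindex(adj.index, fill_value=0)
        r, _ = stats.pearsonr(net.connectivity, degree)
        assert r > 0.5

    def test_invalid_threshold_rejected(self):
        with pytest.raises(UsageError, match="edge_threshold"):
            coexpression_edges(self._adjacency(), edge_threshold=1.5)
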