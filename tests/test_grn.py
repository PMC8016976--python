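"""Promoter overlap arithmetic, GRN integration logic and set algebra."""

import numpy as np
import pandas as pd
import pytest

from macrogrn import synthetic_data as sd
from macrogrn.containers import (
    ExpressionMatrix,
    GeneAnnotationTable,
    MotifPriorTable,
    PeakSet,
    PromoterWindow,
    StrainGRN,
)
from macrogrn.exceptions import UsageError
from macrogrn.grn import (
    accessible_promoter_genes,
    build_strain_grn,
    combine_grns,
    grn_summary,
    strain_unique_tfs,
    unique_tf_grn,
)


def _annotation(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    return GeneAnnotationTable(df.set_index("gene_id"))


class TestAccessiblePromoterGenes:
    window = PromoterWindow(upstream=1000, downstream=100)

    def test_plus_strand_overlap(self):
        # tss 1000, '+': promoter [0, 1100); peak [950, 1050) overlaps
        ann = _annotation([("g", "chr1", 1000, "+")])
        peaks = PeakSet("s", (("chr1", 950, 1050),))
        assert accessible_promoter_genes(peaks, ann, self.window) == {"g"}

    def test_half_open_boundary_excludes_touching_peak(self):
        # peak [1100, 1200) touches the promoter end 1100 exactly: no overlap
        ann = _annotation([("g", "chr1", 1000, "+")])
        peaks = PeakSet("s", (("chr1", 1100, 1200),))
        assert accessible_promoter_genes(peaks, ann, self.window) == frozenset()

    def test_minus_strand_window_is_mirrored(self):
        # tss 1000, '-': promoter [900, 2000); peak [1950, 2050) overlaps
        ann = _annotation([("g", "chr1", 1000, "-")])
        peaks = PeakSet("s", (("chr1", 1950, 2050),))
        assert accessible_promoter_genes(peaks, ann, self.window) == {"g"}

    def test_peak_on_other_chromosome_does_not_count(self):
        ann = _annotation([("g", "chr2", 1000, "+")])
        peaks = PeakSet("s", (("chr1", 0, 10_000),))
        assert accessible_promoter_genes(peaks, ann, self.window) == frozenset()

    def test_window_widening_is_monotone(self, small_truth, small_params):
        _, peaks, ann, _ = sd.simulate_bundle(small_truth, small_params)
        s = small_truth.strains[0]
        narrow = accessible_promoter_genes(peaks[s], ann, PromoterWindow(200, 50))
        wide = accessible_promoter_genes(peaks[s], ann, PromoterWindow(2000, 500))
        assert narrow <= wide


class TestBuildStrainGrn:
    def _toy(self):
        # strain means: A=20, B=5, g1=15, g2=50, g3=8, g4=12
        means = {"A": 20.0, "B": 5.0, "g1": 15.0, "g2": 50.0, "g3": 8.0, "g4": 12.0}
        values = pd.DataFrame(
            {"s_r1": list(means.values()), "s_r2": list(means.values())},
            index=list(means),
        )
        m = ExpressionMatrix(values, {"s_r1": "s", "s_r2": "s"})
        prior = MotifPriorTable(frozenset(
            {("A", "g1"), ("A", "g2"), ("A", "g3"), ("B", "g1"), ("B", "g4"),
             ("A", "B")}))
        return m, prior

    def test_triple_intersection_rule(self):
        """Expressed TF + expressed target + accessible target + prior."""
        m, prior = self._toy()
        grn = build_strain_grn(m, "s", {"g1", "g2", "g4", "A"}, prior)
        assert grn.edges == {("A", "g1"), ("A", "g2")}

    def test_no_accessible_genes_gives_empty_grn(self):
        m, prior = self._toy()
        grn = build_strain_grn(m, "s", frozenset(), prior)
        assert grn.edges == frozenset()

    def test_lowering_threshold_is_monotone(self):
        m, prior = self._toy()
        acc = {"g1", "g2", "g3", "g4", "A", "B"}
        strict = build_strain_grn(m, "s", acc, prior, tpm_threshold=10)
        loose = build_strain_grn(m, "s", acc, prior, tpm_threshold=4)
        assert strict.edges <= loose.edges

    def test_unknown_strain_rejected(self):
        m, prior = self._toy()
        with pytest.raises(UsageError, match="strain"):
            build_strain_grn(m, "nope", set(), prior)

    def test_tf_universe_must_come_from_prior(self):
        m, prior = self._toy()
        with pytest.raises(UsageError, match="tf_universe"):
            build_strain_grn(m, "s", set(), prior, tf_universe={"Z"})


class TestCombineGrns:
    def test_pan_and_core_on_worked_example(self):
        g1 = StrainGRN("s1", frozenset({("a", "x"), ("a", "y")}))
        g2 = StrainGRN("s2", frozenset({("a", "x"), ("b", "z")}))
        pan = combine_grns([g1, g2], "union")
        core = combine_grns([g1, g2], "intersection")
        assert len(pan.edges) == 3
        assert core.edges == {("a", "x")}
        assert pan.provenance[("a", "x")] == ("s1", "s2")

    def test_identical_grns_make_pan_equal_core(self):
        g1 = StrainGRN("s1", frozenset({("a", "x")}))
        g2 = StrainGRN("s2", frozenset({("a", "x")}))
        assert combine_grns([g1, g2], "union").edges == \
            combine_grns([g1, g2], "intersection").edges == {("a", "x")}

    def test_disjoint_grns_make_core_empty(self):
        g1 = StrainGRN("s1", frozenset({("a", "x")}))
        g2 = StrainGRN("s2", frozenset({("b", "y")}))
        assert combine_grns([g1, g2], "intersection").edges == frozenset()
        assert len(combine_grns([g1, g2], "union").edges) == 2

    def test_node_count_identity(self):
        g1 = StrainGRN("s1", frozenset({("a", "b"), ("b", "x")}))
        g2 = StrainGRN("s2", frozenset({("a", "x")}))
        pan = combine_grns([g1, g2], "union")
        n_tfs, n_targets, n_nodes = pan.node_counts()
        assert n_nodes == n_tfs + n_targets - len(pan.tfs & pan.targets)

    def test_fewer_than_two_rejected(self):
        g1 = StrainGRN("s1", frozenset())
        with pytest.raises(UsageError, match="at least 2"):
            combine_grns([g1], "union")


class TestStrainUniqueTfs:
    def _matrix(self, rows):
        values = pd.DataFrame(rows, index=["tfA", "tfB"],
                              columns=["s1_r1", "s1_r2", "s2_r1", "s2_r2",
                                       "s3_r1", "s3_r2"])
        mapping = {c: c.split("_")[0] for c in values.columns}
        return ExpressionMatrix(values, mapping)

    def test_unique_and_shared_tfs(self):
        m = self._matrix([[20, 20, 4, 4, 4, 4],  # unique to s1
                          [20, 20, 20, 20, 4, 4]])  # shared: nowhere
        unique = strain_unique_tfs(m, {"tfA", "tfB"})
        assert unique["s1"] == {"tfA"}
        assert unique["s2"] == frozenset() and unique["s3"] == frozenset()

    def test_planted_unique_tfs_recovered(self, small_truth, small_params):
        expr, _, _, _ = sd.simulate_bundle(small_truth, small_params)
        unique = strain_unique_tfs(expr, set(small_truth.tfs))
        assert unique == small_truth.unique_tfs()


class TestUniqueTfGrn:
    def test_strict_removes_foreign_targets(self):
        g = StrainGRN("s1", frozenset({("u", "x"), ("u", "y"), ("v", "x")}))
        other = StrainGRN("s2", frozenset({("w", "y")}))
        sub = unique_tf_grn(g, [other], {"u"})
        assert sub.edges == {("u", "x")}

    def test_loose_keeps_all_unique_tf_edges(self):
        g = StrainGRN("s1", frozenset({("u", "x"), ("u", "y"), ("v", "x")}))
        other = StrainGRN("s2", frozenset({("w", "y")}))
        sub = unique_tf_grn(g, [other], {"u"}, strict=False)
        assert sub.edges == {("u", "x"), ("u", "y")}

    def test_no_unique_tfs_gives_empty_grn(self):
        g = StrainGRN("s1", frozenset({("u", "x")}))
        assert unique_tf_grn(g, [], frozenset()).edges == frozenset()

    def test_empty_other_grns_keep_everything(self):
        g = StrainGRN("s1", frozenset({("u", "x"), ("u", "y")}))
        empty = StrainGRN("s2", frozenset())
        assert unique_tf_grn(g, [empty], {"u"}).edges == g.edges


class TestGrnSummary:
    def test_out_degrees(self):
        g = StrainGRN("s", frozenset({("A", "x"), ("A", "y"), ("B", "x")}))
        table, _ = grn_summary(g)
        assert dict(zip(table["tf"], table["out_degree"])) == {"A": 2, "B": 1}

    def test_gene_set_induced_sub_grn(self):
        g = StrainGRN("s", frozenset({("A", "x"), ("A", "y"), ("B", "x")}))
        _, sub = grn_summary(g, gene_set={"x"})
        assert sub.edges == {("A", "x"), ("B", "x")}
        assert sub.nodes == {"A", "B", "x"}

    def test_empty_gene_set_gives_empty_sub_grn(self):
        g = StrainGRN("s", frozenset({("A", "x")}))
        _, sub = grn_summary(g, gene_set=set())
        assert sub.edges == frozenset()


class TestPlantedRecovery:
    def test_noise_free_bundle_recovers_truth_exactly(self):
        params = sd.SimulationParams(seed=21, n_tfs=8, n_genes=120,
                                     n_strains=3, replicate_sd=0.0)
        truth = sd.generate_ground_truth(params)
        expr, peaks, ann, prior = sd.simulate_bundle(truth, params)
        for s in truth.strains:
            acc = accessible_promoter_genes(peaks[s], ann)
            g = build_strain_grn(expr, s, acc, prior)
            assert g.edges == truth.true_edges[s]

    def test_core_within_strain_within_pan(self, small_truth, small_params):
        expr, peaks, ann, prior = sd.simulate_bundle(small_truth, small_params)
        grns = []
        for s in small_truth.strains:
            acc = accessible_promoter_genes(peaks[s], ann)
            grns.append(build_strain_grn(expr, s, acc, prior))
        pan = combine_grns(grns, "union")
        core = combine_grns(grns, "intersection")
        for g in grns:
            assert core.edges <= g.edges <= pan.edges
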