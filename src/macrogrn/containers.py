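"""Core data containers shared across the pipeline.

The pipeline moves a small number of typed objects between stages: a TPM
expression matrix with a sample-to-strain map, per-strain ATAC peak sets,
a TSS annotation table, a motif-derived TF->target prior, and the directed
strain GRNs built from their intersection.  All containers validate their
invariants at construction time so that downstream code can assume
well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ValidationError

VALID_STRANDS = ("+", "-")


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-aware promoter interval around a TSS, in base pairs.

    For a gene on the ``+`` strand the promoter is ``[tss - upstream,
    tss + downstream)``; on the ``-`` strand the window is mirrored to
    ``[tss - downstream, tss + upstream)``.  Coordinates are clipped at 0.
    """

    upstream: int = 1000
    downstream: int = 100

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValidationError("promoter window sizes must be non-negative")
        if self.upstream + self.downstream <= 0:
            raise ValidationError("promoter window must have positive extent")

    def interval(self, tss: int, strand: str) -> tuple[int, int]:
        """Half-open genomic interval of the promoter for one gene."""
        if strand == "+":
            start, end = tss - self.upstream, tss + self.downstream
        elif strand == "-":
            start, end = tss - self.downstream, tss + self.upstream
        else:
            raise ValidationError(f"invalid strand {strand!r}")
        return max(start, 0), max(end, 0)


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM table plus a sample -> strain assignment.

    ``values`` is a float DataFrame (rows: gene ids, columns: sample ids);
    all entries are non-negative TPM.  Every sample column must appear in
    ``sample_to_strain``.
    """

    values: pd.DataFrame
    sample_to_strain: dict[str, str]

    def __post_init__(self) -> None:
        v = self.values
        # an all-filtered matrix (0 genes) is representable; file readers
        # additionally require >= 1 gene
        if v.shape[1] < 2:
            raise ValidationError(
                f"expression matrix needs at least 2 samples, got {v.shape[1]}"
            )
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        try:
            self.values = v = v.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric TPM values: {exc}") from exc
        if not np.isfinite(v.values).all():
            raise ValidationError("non-finite TPM values present")
        if (v.values < 0).any():
            bad = v.index[(v.values < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative TPM values for genes {bad[:5]}")
        missing = [s for s in v.columns if s not in self.sample_to_strain]
        if missing:
            raise ValidationError(
                f"samples without a strain assignment: {missing}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def strains(self) -> list[str]:
        """Strain labels in order of first appearance among the columns."""
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_to_strain[s], None)
        return list(seen)

    def samples_of(self, strain: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_to_strain[s] == strain]

    def strain_means(self) -> pd.DataFrame:
        """Mean TPM per gene within each strain (replicate average)."""
        cols = {s: self.values[self.samples_of(s)].mean(axis=1) for s in self.strains}
        return pd.DataFrame(cols)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep].copy(), dict(self.sample_to_strain))


@dataclass(frozen=True)
class PeakSet:
    """Open-chromatin intervals for one strain (BED convention: 0-based,
    half-open)."""

    strain: str
    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if not self.strain:
            raise ValidationError("peak set needs a non-empty strain label")
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValidationError(
                    f"degenerate interval {chrom}:{start}-{end} (start must be < end)"
                )
            if start < 0:
                raise ValidationError(f"negative coordinate in {chrom}:{start}-{end}")
        object.__setattr__(self, "intervals", tuple(sorted(self.intervals)))

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class GeneAnnotationTable:
    """Per-gene TSS reference: columns ``chrom``, ``tss`` (0-based), ``strand``."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"chrom", "tss", "strand"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids in annotation: {dups[:5]}")
        if (t["tss"] < 0).any():
            raise ValidationError("annotation contains a negative TSS")
        bad = ~t["strand"].isin(VALID_STRANDS)
        if bad.any():
            raise ValidationError(
                f"invalid strand values: {sorted(t.loc[bad, 'strand'].unique())}"
            )
        t.index.name = "gene_id"

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def promoter(self, gene: str, window: PromoterWindow) -> tuple[str, int, int]:
        row = self.table.loc[gene]
        start, end = window.interval(int(row["tss"]), str(row["strand"]))
        return str(row["chrom"]), start, end


@dataclass(frozen=True)
class MotifPriorTable:
    """Candidate TF -> target pairs from promoter motif matches."""

    pairs: frozenset[tuple[str, str]]

    @property
    def tfs(self) -> frozenset[str]:
        return frozenset(tf for tf, _ in self.pairs)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(t for _, t in self.pairs)

    def targets_of(self, tf: str) -> frozenset[str]:
        return frozenset(t for f, t in self.pairs if f == tf)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class StrainGRN:
    """Directed TF -> target edge set for one strain.

    ``tfs`` are nodes with outgoing edges, ``targets`` nodes with at least
    one incoming edge; a TF may itself be a target.  Self-loops are allowed
    only when present in the motif prior and are simply carried through.
    """

    strain: str
    edges: frozenset[tuple[str, str]]

    @property
    def tfs(self) -> frozenset[str]:
        return frozenset(tf for tf, _ in self.edges)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(t for _, t in self.edges)

    @property
    def nodes(self) -> frozenset[str]:
        return self.tfs | self.targets

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def targets_of(self, tf: str) -> frozenset[str]:
        return frozenset(t for f, t in self.edges if f == tf)

    def out_degrees(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for tf, _ in self.edges:
            out[tf] = out.get(tf, 0) + 1
        return out

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph(strain=self.strain)
        for tf, target in sorted(self.edges):
            g.add_edge(tf, target)
        return g


@dataclass
class CombinedGRN:
    """Pan (union) or core (intersection) GRN with per-edge strain provenance."""

    mode: str  # "union" | "intersection"
    edges: frozenset[tuple[str, str]]
    provenance: dict[tuple[str, str], tuple[str, ...]]
    strains: tuple[str, ...]

    @property
    def tfs(self) -> frozenset[str]:
        return frozenset(tf for tf, _ in self.edges)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(t for _, t in self.edges)

    @property
    def nodes(self) -> frozenset[str]:
        return self.tfs | self.targets

    def node_counts(self) -> tuple[int, int, int]:
        """(n_tfs, n_targets, n_nodes) with n_nodes = |tfs U targets|."""
        return len(self.tfs), len(self.targets), len(self.nodes)


@dataclass
class Bicluster:
    """A gene x sample submatrix with its mean squared residue."""

    rows: tuple[str, ...]
    cols: tuple[str, ...]
    msr: float


@dataclass
class CoexpressionNetwork:
    """Thresholded undirected co-expression network.

    ``edges`` holds retained pairs (columns gene_a, gene_b, weight);
    ``connectivity`` is the soft connectivity from the *full* adjacency,
    not the thresholded graph.  ``module`` maps gene -> module label with
    "grey" reserved for unassigned genes.
    """

    edges: pd.DataFrame
    connectivity: pd.Series
    threshold: float
    module: pd.Series | None = None

    def to_graph(self, include_isolated: bool = False) -> nx.Graph:
        g = nx.Graph()
        if include_isolated:
            g.add_nodes_from(self.connectivity.index)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, weight=float(row.weight))
        return g
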