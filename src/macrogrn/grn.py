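"""Strain GRN construction and set algebra.

A directed edge TF -> gene enters a strain's GRN exactly when four
conditions hold simultaneously: the pair appears in the motif prior, the
TF's replicate-mean TPM in that strain reaches the expression threshold,
the target's does too, and the target has an open-chromatin peak
overlapping its promoter window.  A TF is not itself required to have an
accessible promoter: expression is taken as sufficient evidence that it
is available as a regulator.

The pan GRN is the edge union over strains (with per-edge strain
provenance) and the core GRN the edge intersection; strain-unique TFs are
TFs expressed above threshold in exactly one strain, and their "unique
target" sub-GRNs restrict, under the default strict reading, to targets
that receive no edge at all in any other strain's GRN.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .containers import (
    CombinedGRN,
    ExpressionMatrix,
    GeneAnnotationTable,
    MotifPriorTable,
    PeakSet,
    PromoterWindow,
    StrainGRN,
)
from .exceptions import UsageError

DEFAULT_TPM_THRESHOLD = 10.0


def accessible_promoter_genes(
    peaks: PeakSet,
    annotation: GeneAnnotationTable,
    window: PromoterWindow = PromoterWindow(),
) -> frozenset[str]:
    """Genes with at least one peak overlapping their promoter window.

    Overlap is non-empty intersection of half-open intervals on the same
    chromosome; a peak ending exactly where the promoter starts does not
    overlap it.  Genes on chromosomes without any peak are simply not
    accessible.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for chrom, start, end in peaks.intervals:
        trees[chrom].addi(start, end)
    accessible: set[str] = set()
    table = annotation.table
    for gene, row in table.iterrows():
        chrom = str(row["chrom"])
        if chrom not in trees:
            continue
        start, end = window.interval(int(row["tss"]), str(row["strand"]))
        if end <= start:
            continue  # window fully clipped off the chromosome start
        if trees[chrom].overlap(start, end):
            accessible.add(str(gene))
    return frozenset(accessible)


def build_strain_grn(
    m: ExpressionMatrix,
    strain: str,
    accessible: Iterable[str],
    prior: MotifPriorTable,
    tf_universe: Iterable[str] | None = None,
    tpm_threshold: float = DEFAULT_TPM_THRESHOLD,
) -> StrainGRN:
    """Triple-intersection GRN for one strain.

    ``tf_universe`` restricts which prior TFs may act as regulators; it
    defaults to every TF appearing in the prior and must be a subset of
    them.  Entities absent from the expression matrix count as not
    expressed.
    """
    if strain not in m.strains:
        raise UsageError(f"strain {strain!r} not present in the expression matrix")
    prior_tfs = prior.tfs
    if tf_universe is None:
        universe = set(prior_tfs)
    else:
        universe = set(tf_universe)
        extra = universe - prior_tfs
        if extra:
            raise UsageError(
                f"tf_universe contains ids absent from the prior: {sorted(extra)[:5]}"
            )
    means = m.strain_means()[strain]
    expressed = frozenset(means.index[means >= tpm_threshold])
    accessible = frozenset(accessible)
    edges = frozenset(
        (tf, target)
        for tf, target in prior.pairs
        if tf in universe
        and tf in expressed
        and target in expressed
        and target in accessible
    )
    return StrainGRN(strain=strain, edges=edges)


def combine_grns(grns: Sequence[StrainGRN], mode: str = "union") -> CombinedGRN:
    """Pan (union) or core (intersection) GRN with strain provenance."""
    if len(grns) < 2:
        raise UsageError("combining GRNs needs at least 2 strains")
    if mode not in ("union", "intersection"):
        raise UsageError(f"unknown combine mode {mode!r}")
    strains = tuple(g.strain for g in grns)
    if len(set(strains)) != len(strains):
        raise UsageError("duplicate strain labels among the GRNs")
    presence: dict[tuple[str, str], list[str]] = defaultdict(list)
    for g in grns:
        for edge in g.edges:
            presence[edge].append(g.strain)
    if mode == "union":
        edges = frozenset(presence)
    else:
        edges = frozenset(e for e, present in presence.items() if len(present) == len(grns))
    provenance = {e: tuple(presence[e]) for e in edges}
    return CombinedGRN(mode=mode, edges=edges, provenance=provenance, strains=strains)


def strain_unique_tfs(
    m: ExpressionMatrix,
    tf_universe: Iterable[str],
    tpm_threshold: float = DEFAULT_TPM_THRESHOLD,
) -> dict[str, frozenset[str]]:
    """TFs whose replicate-mean TPM reaches the threshold in exactly one
    strain; a TF expressed in two or more strains appears nowhere."""
    strains = m.strains
    if len(strains) < 2:
        raise UsageError("strain-unique TFs need at least 2 strains")
    means = m.strain_means()
    out: dict[str, set[str]] = {s: set() for s in strains}
    for tf in tf_universe:
        if tf not in means.index:
            continue
        on = [s for s in strains if means.loc[tf, s] >= tpm_threshold]
        if len(on) == 1:
            out[on[0]].add(tf)
    return {s: frozenset(v) for s, v in out.items()}


def unique_tf_grn(
    strain_grn: StrainGRN,
    other_grns: Sequence[StrainGRN],
    unique_tfs: Iterable[str],
    strict: bool = True,
) -> StrainGRN:
    """Sub-GRN of a strain's unique TFs.

    Under the default strict reading an edge survives only if its target
    receives no edge from *any* TF in any other strain's GRN, i.e. both
    regulator and target are strain-exclusive.  With ``strict=False`` all
    edges of the unique TFs are kept regardless of the target's status
    elsewhere.
    """
    unique = frozenset(unique_tfs)
    extra = unique - strain_grn.tfs
    if extra:
        raise UsageError(
            f"unique TFs absent from the strain GRN: {sorted(extra)[:5]}"
        )
    if strict:
        foreign_targets = frozenset().union(*(g.targets for g in other_grns)) \
            if other_grns else frozenset()
        edges = frozenset(
            (tf, t) for tf, t in strain_grn.edges
            if tf in unique and t not in foreign_targets
        )
    else:
        edges = frozenset((tf, t) for tf, t in strain_grn.edges if tf in unique)
    return StrainGRN(strain=strain_grn.strain, edges=edges)


def grn_summary(
    grn: StrainGRN, gene_set: Iterable[str] | None = None
) -> tuple[pd.DataFrame, StrainGRN | None]:
    """Per-TF out-degree table, plus the gene-set-induced sub-GRN if a set
    is given (edges whose target lies in the set; the TF side is retained
    regardless of membership)."""
    out = grn.out_degrees()
    table = pd.DataFrame(
        {"tf": sorted(out), "out_degree": [out[tf] for tf in sorted(out)]}
    )
    sub = None
    if gene_set is not None:
        members = frozenset(gene_set)
        sub = StrainGRN(
            strain=grn.strain,
            edges=frozenset((tf, t) for tf, t in grn.edges if t in members),
        )
    return table, sub


def write_combined_grn(combined: CombinedGRN, path) -> None:
    """TSV with a strain-provenance column (semicolon-joined labels)."""
    with open(path, "w") as fh:
        fh.write("tf\ttarget\tstrains\n")
        for tf, target in sorted(combined.edges):
            strains = ";".join(
                s for s in combined.strains if s in combined.provenance[(tf, target)]
            )
            fh.write(f"{tf}\t{target}\t{strains}\n")
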