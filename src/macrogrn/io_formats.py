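"""Readers and writers for every external format the pipeline touches.

Conventions are fixed package-wide: BED intervals are 0-based half-open,
TSS coordinates are 0-based, gene identifiers are matched as exact,
case-sensitive strings, and the sample -> strain assignment is a required
two-column TSV sidecar next to the expression matrix.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneAnnotationTable,
    MotifPriorTable,
    PeakSet,
    StrainGRN,
)
from .exceptions import ParseError, UsageError, ValidationError

CENTRALITY_COLUMNS = (
    "node",
    "degree",
    "betweenness",
    "stress",
    "clustering_coefficient",
    "topological_coefficient",
    "connectivity",
    "avg_shortest_path",
    "is_hub50",
)

GRN_FORMATS = ("tsv", "sif", "graphml")


def _require_file(path: str | Path) -> Path:
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"input file not found: {p}")
    return p


# ---------------------------------------------------------------------------
# readers


def read_strain_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample_id, strain), header optional."""
    p = _require_file(path)
    mapping: dict[str, str] = {}
    with open(p) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{p}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            if lineno == 1 and fields[0].lower() in ("sample", "sample_id"):
                continue
            mapping[fields[0]] = fields[1]
    if not mapping:
        raise ParseError(f"{p}: empty sample->strain map")
    return mapping


def read_expression_matrix(
    path: str | Path, strain_map_path: str | Path
) -> ExpressionMatrix:
    """Expression TSV: first column gene_id, remaining columns sample TPMs."""
    p = _require_file(path)
    mapping = read_strain_map(strain_map_path)
    try:
        df = pd.read_csv(p, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{p}: could not parse expression TSV: {exc}") from exc
    if df.shape[0] < 1:
        raise ValidationError(f"{p}: expression matrix has no genes")
    try:
        return ExpressionMatrix(df, mapping)
    except ValidationError as exc:
        raise ValidationError(f"{p}: {exc}") from exc


def read_peaks(path: str | Path, strain: str) -> PeakSet:
    """BED3+ file; extra columns beyond chrom/start/end are ignored."""
    p = _require_file(path)
    intervals: list[tuple[str, int, int]] = []
    with open(p) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{p}:{lineno}: BED line has fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{p}:{lineno}: non-integer BED coordinates"
                ) from exc
            if start >= end:
                raise ParseError(
                    f"{p}:{lineno}: interval start {start} must be < end {end}"
                )
            if start < 0:
                raise ParseError(f"{p}:{lineno}: negative BED coordinate")
            intervals.append((chrom, start, end))
    return PeakSet(strain=strain, intervals=tuple(intervals))


def read_annotation(path: str | Path) -> GeneAnnotationTable:
    """TSV with columns gene_id, chrom, tss, strand; extras ignored."""
    p = _require_file(path)
    try:
        df = pd.read_csv(p, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{p}: could not parse annotation TSV: {exc}") from exc
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{p}: annotation missing columns {sorted(missing)}")
    df = df.set_index("gene_id")[["chrom", "tss", "strand"]]
    try:
        df["tss"] = df["tss"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{p}: non-integer TSS coordinate") from exc
    try:
        return GeneAnnotationTable(df)
    except ValidationError as exc:
        raise ValidationError(f"{p}: {exc}") from exc


def read_prior(path: str | Path) -> MotifPriorTable:
    """TSV with columns tf_id, target_id; duplicate pairs collapse to one."""
    p = _require_file(path)
    try:
        df = pd.read_csv(p, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{p}: could not parse prior TSV: {exc}") from exc
    required = {"tf_id", "target_id"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{p}: prior missing columns {sorted(missing)}")
    if df[["tf_id", "target_id"]].isna().any().any():
        raise ParseError(f"{p}: prior contains empty tf/target fields")
    pairs = frozenset(zip(df["tf_id"], df["target_id"]))
    return MotifPriorTable(pairs=pairs)


def read_input_bundle(
    expression_path: str | Path,
    peaks_paths: Mapping[str, str | Path],
    annotation_path: str | Path,
    prior_path: str | Path,
    strain_map_path: str | Path,
) -> tuple[ExpressionMatrix, dict[str, PeakSet], GeneAnnotationTable, MotifPriorTable]:
    """Load and validate a full input bundle.

    ``peaks_paths`` maps strain label -> BED path.  Gene identifiers are
    matched as exact strings across all four files; no alias resolution is
    attempted.
    """
    expr = read_expression_matrix(expression_path, strain_map_path)
    peaks = {strain: read_peaks(path, strain) for strain, path in peaks_paths.items()}
    annotation = read_annotation(annotation_path)
    prior = read_prior(prior_path)
    return expr, peaks, annotation, prior


# ---------------------------------------------------------------------------
# writers


def write_strain_map(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tstrain\n")
        for sample, strain in mapping.items():
            fh.write(f"{sample}\t{strain}\n")


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in peaks.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_annotation(annotation: GeneAnnotationTable, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="gene_id")


def write_prior(prior: MotifPriorTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tf_id\ttarget_id\n")
        for tf, target in sorted(prior.pairs):
            fh.write(f"{tf}\t{target}\n")


def write_grn_edge_list(grn: StrainGRN, path: str | Path, format: str = "tsv") -> None:
    """Serialize a strain GRN as a TSV edge list, SIF, or GraphML."""
    if format not in GRN_FORMATS:
        raise UsageError(f"unknown GRN format {format!r}; expected one of {GRN_FORMATS}")
    edges = sorted(grn.edges)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("tf\ttarget\tstrain\n")
            for tf, target in edges:
                fh.write(f"{tf}\t{target}\t{grn.strain}\n")
    elif format == "sif":
        with open(path, "w") as fh:
            for tf, target in edges:
                fh.write(f"{tf}\tregulates\t{target}\n")
    else:  # graphml
        nx.write_graphml(grn.to_digraph(), path)


def read_grn_edge_list(
    path: str | Path, format: str = "tsv", strain: str | None = None
) -> StrainGRN:
    """Inverse of :func:`write_grn_edge_list`.

    SIF carries no strain label, so ``strain`` must be given for that
    format; for TSV and GraphML it overrides the stored label if provided.
    """
    if format not in GRN_FORMATS:
        raise UsageError(f"unknown GRN format {format!r}; expected one of {GRN_FORMATS}")
    p = _require_file(path)
    if format == "tsv":
        edges: set[tuple[str, str]] = set()
        strains: set[str] = set()
        with open(p) as fh:
            header = fh.readline()
            if not header.startswith("tf\ttarget"):
                raise ParseError(f"{p}:1: expected GRN TSV header")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise ParseError(f"{p}:{lineno}: expected 3 fields")
                edges.add((fields[0], fields[1]))
                strains.add(fields[2])
        label = strain if strain is not None else (strains.pop() if len(strains) == 1 else "")
        if not label:
            label = "combined" if strains else "empty"
        return StrainGRN(strain=label, edges=frozenset(edges))
    if format == "sif":
        if strain is None:
            raise UsageError("SIF files carry no strain label; pass strain=")
        edges = set()
        with open(p) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise ParseError(f"{p}:{lineno}: expected 3 SIF fields")
                edges.add((fields[0], fields[2]))
        return StrainGRN(strain=strain, edges=frozenset(edges))
    g = nx.read_graphml(p)
    label = strain if strain is not None else g.graph.get("strain", "unknown")
    return StrainGRN(strain=label, edges=frozenset((u, v) for u, v in g.edges()))


def write_centrality_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write per-node centrality records as a TSV, sorted by node id.

    ``table`` must either be indexed by node id or carry a ``node`` column,
    plus the remaining centrality columns.  Duplicate node ids are refused.
    """
    df = table.copy()
    if "node" not in df.columns:
        df = df.reset_index(names="node")
    missing = [c for c in CENTRALITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"centrality table missing columns {missing}")
    if df["node"].duplicated().any():
        dups = df.loc[df["node"].duplicated(), "node"].tolist()
        raise ValidationError(f"duplicate node ids in centrality table: {dups[:5]}")
    df = df[list(CENTRALITY_COLUMNS)].sort_values("node")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_centrality_table(path: str | Path) -> pd.DataFrame:
    p = _require_file(path)
    df = pd.read_csv(p, sep="\t")
    missing = [c for c in CENTRALITY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{p}: centrality table missing columns {missing}")
    return df.set_index("node")
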