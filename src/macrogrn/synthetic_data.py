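"""Synthetic multi-strain input bundles with a planted regulatory program.

The generator emulates the structure of a resting-macrophage multi-omics
study: S inbred strains with R RNA-seq replicates each, per-strain ATAC
promoter accessibility, and a motif-prior table.  A planted ground truth
(which TFs and genes are expressed per strain, which promoters are open,
and which prior pairs are real) makes every downstream stage testable by
exact recovery: in the noise-free limit the strain GRNs reconstructed from
the bundle equal the planted edges.

Design of the expression model
------------------------------
TPM values are log-normal: an entity that is "on" in a strain is drawn
around ``on_tpm_mean`` on the log2 scale with replicate noise
``replicate_sd``; "off" entities sit around ``off_tpm_mean``.  Genes in
the same planted co-expression module share a per-sample latent factor
(sd ``module_sd``, truncated at two sigma) so within-module correlation
exceeds between-module correlation.  The truncation keeps "on" strain
means above and "off" strain means below the expression threshold even in
the noise-free limit, which is what makes exact recovery well defined.

Decoy prior pairs always point at genes that are silent in every strain,
so no decoy can ever satisfy the expressed-and-accessible integration
rule; the precision of GRN construction is therefore well defined.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneAnnotationTable,
    MotifPriorTable,
    PeakSet,
)
from .exceptions import UsageError, ValidationError
from . import io_formats

#: default strain labels when simulating the five-strain study design
FIVE_STRAINS = ("C57", "BALB", "NOD", "PWK", "SPRET")

#: TPM threshold the defaults are calibrated against ("expressed" gate)
EXPRESSED_TPM = 10.0

# genomic layout of the synthetic chromosome
_TSS_SPACING = 10_000
_PROMOTER_PEAK_HALFWIDTH = 50
_DISTAL_OFFSET = 3_000
_DISTAL_WIDTH = 200


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic study; defaults mirror a five-strain,
    two-replicate design with 30 TFs and 600 genes."""

    seed: int
    n_tfs: int = 30
    n_genes: int = 600
    n_strains: int = 5
    n_replicates: int = 2
    on_tpm_mean: float = 100.0
    off_tpm_mean: float = 1.0
    replicate_sd: float = 0.25  # log2 scale
    module_sd: float = 0.8  # log2 scale, shared within planted modules
    decoy_rate: float = 0.2  # fraction of the prior that is unrealizable
    peak_dropout: float = 0.0  # probability a real promoter peak is missing
    tf_on_prob: float = 0.8
    module_variable_prob: float = 0.3  # chance a module is strain-variable
    gene_on_prob: float = 0.7  # per-strain on probability in variable patterns
    silent_gene_frac: float = 0.08  # everywhere-silent genes (decoy targets)
    accessible_prob: float = 0.85
    targets_per_tf_frac: float = 0.15
    tf_target_prob: float = 0.1  # chance a TF also targets another TF

    def __post_init__(self) -> None:
        for name in ("n_tfs", "n_genes", "n_strains", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if self.n_strains < 2:
            raise UsageError(
                "n_strains must be >= 2: pan/core set algebra is undefined "
                "for a single strain"
            )
        if self.n_tfs < self.n_strains:
            raise UsageError("need at least one TF per strain (n_tfs >= n_strains)")
        if not (self.on_tpm_mean > EXPRESSED_TPM > self.off_tpm_mean > 0):
            raise ValidationError(
                f"need on_tpm_mean > {EXPRESSED_TPM} > off_tpm_mean > 0"
            )
        for name in ("decoy_rate", "peak_dropout", "tf_on_prob", "gene_on_prob",
                     "accessible_prob", "tf_target_prob", "module_variable_prob",
                     "silent_gene_frac"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.decoy_rate >= 1.0:
            raise ValidationError("decoy_rate must be < 1 (the prior must contain "
                                  "at least the realizable pairs)")
        if self.replicate_sd < 0 or self.module_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")


@dataclass
class GroundTruth:
    """Planted regulatory program: per-strain expression and accessibility
    states, realizable prior pairs, and the true edge sets they induce."""

    strains: tuple[str, ...]
    tfs: tuple[str, ...]
    genes: tuple[str, ...]
    true_edges: dict[str, frozenset[tuple[str, str]]]
    expr_state: dict[tuple[str, str], bool]
    peak_state: dict[tuple[str, str], bool]
    modules: dict[str, str]
    candidate_pairs: frozenset[tuple[str, str]]
    decoy_pairs: frozenset[tuple[str, str]]
    silent_genes: frozenset[str]

    @property
    def entities(self) -> tuple[str, ...]:
        return self.tfs + self.genes

    def expressed_in(self, strain: str) -> frozenset[str]:
        return frozenset(e for e in self.entities if self.expr_state[(strain, e)])

    def unique_tfs(self) -> dict[str, frozenset[str]]:
        """TFs whose planted expression state is on in exactly one strain."""
        out: dict[str, set[str]] = {s: set() for s in self.strains}
        for tf in self.tfs:
            on = [s for s in self.strains if self.expr_state[(s, tf)]]
            if len(on) == 1:
                out[on[0]].add(tf)
        return {s: frozenset(v) for s, v in out.items()}


def _strain_labels(n_strains: int) -> tuple[str, ...]:
    if n_strains == len(FIVE_STRAINS):
        return FIVE_STRAINS
    return tuple(f"S{i + 1}" for i in range(n_strains))


def generate_ground_truth(params: SimulationParams) -> GroundTruth:
    """Plant the regulatory program.

    Construction guarantees: every strain has at least one expressed TF
    (the first ``n_strains`` TFs are each on in exactly one strain, so the
    strain-unique logic is always exercised); every true edge satisfies
    expressed-TF / expressed-target / accessible-promoter by definition,
    because the true edge sets are *derived* from the planted states with
    the same integration rule the pipeline applies.
    """
    rng = np.random.default_rng([params.seed, 11])
    strains = _strain_labels(params.n_strains)
    tfs = tuple(f"TF{i:03d}" for i in range(params.n_tfs))
    genes = tuple(f"G{i:04d}" for i in range(params.n_genes))

    expr_state: dict[tuple[str, str], bool] = {}
    # TF states: one strain-exclusive TF per strain, the rest broadly on.
    for i, tf in enumerate(tfs):
        if i < len(strains):
            states = [s == strains[i] for s in strains]
        else:
            states = list(rng.random(len(strains)) < params.tf_on_prob)
            if not any(states):
                states[int(rng.integers(len(strains)))] = True
        for s, on in zip(strains, states):
            expr_state[(s, tf)] = bool(on)

    # planted co-expression modules partition the genes.  Expression class
    # is a property of the module, not the gene: a module is either
    # constitutive (members on in every strain) or strain-variable (all
    # members share one on/off pattern across strains).  This keeps the
    # module label the dominant co-expression signal for every member --
    # mixing on/off classes inside a module would let the large on/off
    # swing, not the planted factor, drive the correlation structure.
    n_modules = max(2, int(round(params.n_genes / 100)))
    order = rng.permutation(params.n_genes)
    modules: dict[str, str] = {}
    module_names = [f"mod{m + 1:02d}" for m in range(n_modules)]
    splits = np.array_split(order, n_modules)
    for name, idx in zip(module_names, splits):
        for j in idx:
            modules[genes[j]] = name

    # the first module is always constitutive (it hosts the silent decoy
    # genes); the rest are strain-variable with distinct on/off patterns
    variable_modules = [
        name for name in module_names[1:]
        if rng.random() < params.module_variable_prob
    ]
    module_pattern: dict[str, tuple[bool, ...]] = {}
    used_patterns: set[tuple[bool, ...]] = set()
    for name in variable_modules:
        pattern: tuple[bool, ...] = ()
        for _ in range(50):
            cand = tuple(bool(b) for b in rng.random(len(strains)) < params.gene_on_prob)
            if any(cand) and not all(cand) and cand not in used_patterns:
                pattern = cand
                break
        if not pattern:  # pattern space exhausted; fall back to constitutive
            continue
        used_patterns.add(pattern)
        module_pattern[name] = pattern
    variable_modules = [m for m in variable_modules if m in module_pattern]

    # everywhere-silent genes (decoy targets) live in constitutive modules
    const_genes = [g for g in genes if modules[g] not in module_pattern]
    n_silent = int(round(params.silent_gene_frac * params.n_genes))
    if params.decoy_rate > 0:
        n_silent = max(1, n_silent)
    n_silent = min(n_silent, len(const_genes))
    chosen = rng.choice(len(const_genes), size=n_silent, replace=False) \
        if n_silent else np.array([], dtype=int)
    silent_genes = frozenset(const_genes[j] for j in chosen)
    for g in genes:
        if g in silent_genes:
            states: tuple[bool, ...] = tuple([False] * len(strains))
        elif modules[g] in module_pattern:
            states = module_pattern[modules[g]]
        else:
            states = tuple([True] * len(strains))
        for s, on in zip(strains, states):
            expr_state[(s, g)] = bool(on)

    # promoter accessibility per (strain, entity)
    peak_state: dict[tuple[str, str], bool] = {}
    entities = tfs + genes
    acc = rng.random((len(strains), len(entities))) < params.accessible_prob
    for i, s in enumerate(strains):
        for j, e in enumerate(entities):
            peak_state[(s, e)] = bool(acc[i, j])

    # realizable prior pairs: TFs target non-silent genes (plus rare TF->TF)
    target_pool = [g for g in genes if g not in silent_genes]
    if not target_pool:
        raise UsageError("all genes are silent; cannot plant regulatory targets")
    n_targets = max(1, int(round(params.targets_per_tf_frac * params.n_genes)))
    n_targets = min(n_targets, len(target_pool))
    candidate: set[tuple[str, str]] = set()
    for tf in tfs:
        chosen = rng.choice(len(target_pool), size=n_targets, replace=False)
        for j in chosen:
            candidate.add((tf, target_pool[j]))
        if params.n_tfs > 1 and rng.random() < params.tf_target_prob:
            others = [t for t in tfs if t != tf]
            candidate.add((tf, others[int(rng.integers(len(others)))]))

    # decoys: unrealizable pairs pointing at everywhere-silent genes
    decoys: set[tuple[str, str]] = set()
    if params.decoy_rate > 0:
        n_decoys = int(round(params.decoy_rate / (1 - params.decoy_rate) * len(candidate)))
        pool = sorted(set((tf, g) for tf in tfs for g in sorted(silent_genes)) - candidate)
        if n_decoys > len(pool):
            warnings.warn(
                f"requested {n_decoys} decoy pairs but only {len(pool)} "
                "silent-gene pairs exist; capping", stacklevel=2)
            n_decoys = len(pool)
        chosen = rng.choice(len(pool), size=n_decoys, replace=False)
        decoys = {pool[j] for j in chosen}

    true_edges = {
        s: frozenset(
            (tf, t) for tf, t in candidate
            if expr_state[(s, tf)] and expr_state[(s, t)] and peak_state[(s, t)]
        )
        for s in strains
    }
    return GroundTruth(
        strains=strains,
        tfs=tfs,
        genes=genes,
        true_edges=true_edges,
        expr_state=expr_state,
        peak_state=peak_state,
        modules=modules,
        candidate_pairs=frozenset(candidate),
        decoy_pairs=frozenset(decoys),
        silent_genes=silent_genes,
    )


def simulate_bundle(
    truth: GroundTruth, params: SimulationParams
) -> tuple[ExpressionMatrix, dict[str, PeakSet], GeneAnnotationTable, MotifPriorTable]:
    """Emit the four input files' in-memory equivalents for a ground truth.

    Deterministic given ``params.seed``; all random draws happen in a fixed
    order regardless of parameter values so that e.g. setting a rate to
    zero does not shift the random stream of later draws.
    """
    rng = np.random.default_rng([params.seed, 23])
    strains = truth.strains
    entities = truth.entities
    samples = [f"{s}_rep{r + 1}" for s in strains for r in range(params.n_replicates)]
    sample_to_strain = {f"{s}_rep{r + 1}": s for s in strains
                        for r in range(params.n_replicates)}

    n_e, n_s = len(entities), len(samples)
    base = np.empty((n_e, n_s))
    log_on = np.log2(params.on_tpm_mean)
    log_off = np.log2(params.off_tpm_mean)
    for j, smp in enumerate(samples):
        strain = sample_to_strain[smp]
        for i, e in enumerate(entities):
            base[i, j] = log_on if truth.expr_state[(strain, e)] else log_off

    # shared latent factor per (module, sample).  Factors are
    # orthogonalized across modules (planted programs are distinct by
    # construction, so chance correlation between the random factor
    # vectors cannot blur module boundaries) and truncated at two sigma
    # so "on" strain means stay above and "off" means below the
    # expression threshold even in the noise-free limit.
    module_labels = sorted(set(truth.modules.values()))
    n_m = len(module_labels)
    raw = rng.standard_normal((n_m, n_s))
    if 1 < n_m <= n_s:
        q, _ = np.linalg.qr(raw.T)  # columns orthonormal
        factors = q.T * np.sqrt(n_s)  # per-sample variance ~ 1
    else:
        factors = raw
    factors = np.clip(factors, -2.0, 2.0) * params.module_sd
    module_row = np.zeros((n_e, n_s))
    mod_index = {m: k for k, m in enumerate(module_labels)}
    for i, e in enumerate(entities):
        m = truth.modules.get(e)
        if m is not None:
            module_row[i] = factors[mod_index[m]]

    eps = rng.standard_normal((n_e, n_s)) * params.replicate_sd
    tpm = np.power(2.0, base + module_row + eps)
    expr = ExpressionMatrix(
        pd.DataFrame(tpm, index=list(entities), columns=samples),
        sample_to_strain,
    )

    # annotation: one synthetic chromosome, alternating strands
    ann = pd.DataFrame(
        {
            "chrom": "chrSim",
            "tss": [_TSS_SPACING * (i + 1) for i in range(n_e)],
            "strand": ["+" if i % 2 == 0 else "-" for i in range(n_e)],
        },
        index=list(entities),
    )
    annotation = GeneAnnotationTable(ann)

    # peaks: promoter peak straddling the TSS for every accessible entity
    # (minus dropout), plus distal decoy peaks away from any promoter
    drop_u = rng.random((len(strains), n_e))
    distal_pick = rng.integers(0, n_e, size=(len(strains), max(1, n_e // 2)))
    peak_sets: dict[str, PeakSet] = {}
    for si, s in enumerate(strains):
        intervals: list[tuple[str, int, int]] = []
        for i, e in enumerate(entities):
            if not truth.peak_state[(s, e)]:
                continue
            if drop_u[si, i] < params.peak_dropout:
                continue
            tss = _TSS_SPACING * (i + 1)
            intervals.append(
                ("chrSim", tss - _PROMOTER_PEAK_HALFWIDTH, tss + _PROMOTER_PEAK_HALFWIDTH)
            )
        for i in distal_pick[si]:
            tss = _TSS_SPACING * (int(i) + 1)
            intervals.append(("chrSim", tss + _DISTAL_OFFSET, tss + _DISTAL_OFFSET + _DISTAL_WIDTH))
        peak_sets[s] = PeakSet(strain=s, intervals=tuple(sorted(set(intervals))))

    prior = MotifPriorTable(pairs=truth.candidate_pairs | truth.decoy_pairs)
    return expr, peak_sets, annotation, prior


def simulate_chip_peaks(
    truth: GroundTruth,
    strain: str,
    tf: str,
    dropout: float = 0.0,
    false_rate: float = 0.0,
    seed: int = 0,
) -> frozenset[str]:
    """A ChIP-derived target set for one TF in one strain.

    Returns ``round((1 - dropout) * n_true)`` of the TF's true targets plus
    ``round(false_rate * n_true)`` random non-targets.  Deterministic given
    ``seed``.
    """
    if tf not in truth.tfs:
        raise UsageError(f"unknown TF {tf!r}")
    if strain not in truth.strains:
        raise UsageError(f"unknown strain {strain!r}")
    if not 0.0 <= dropout <= 1.0 or not 0.0 <= false_rate <= 1.0:
        raise UsageError("dropout and false_rate must lie in [0, 1]")
    rng = np.random.default_rng([seed, 31])
    true_targets = sorted(t for f, t in truth.true_edges[strain] if f == tf)
    n_true = len(true_targets)
    n_keep = int(np.floor((1.0 - dropout) * n_true + 0.5))
    kept = [true_targets[j] for j in rng.choice(n_true, size=n_keep, replace=False)] \
        if n_keep else []
    n_false = int(np.floor(false_rate * n_true + 0.5))
    non_targets = sorted(set(truth.entities) - set(true_targets) - {tf})
    false = [non_targets[j] for j in rng.choice(len(non_targets), size=n_false,
                                                replace=False)] if n_false else []
    return frozenset(kept) | frozenset(false)


# ---------------------------------------------------------------------------
# bundle + ground truth serialization (one directory = one study)


def write_bundle(
    bundle: tuple[ExpressionMatrix, dict[str, PeakSet], GeneAnnotationTable, MotifPriorTable],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write a bundle to ``outdir`` in exactly the formats the readers expect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, peaks, annotation, prior = bundle
    paths = {
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "annotation": outdir / "annotation.tsv",
        "prior": outdir / "prior.tsv",
    }
    io_formats.write_expression_matrix(expr, paths["expression"])
    io_formats.write_strain_map(expr.sample_to_strain, paths["samples"])
    io_formats.write_annotation(annotation, paths["annotation"])
    io_formats.write_prior(prior, paths["prior"])
    for strain, pset in peaks.items():
        p = outdir / f"peaks_{strain}.bed"
        io_formats.write_peaks(pset, p)
        paths[f"peaks_{strain}"] = p
    return paths


def read_bundle(
    outdir: str | Path,
) -> tuple[ExpressionMatrix, dict[str, PeakSet], GeneAnnotationTable, MotifPriorTable]:
    outdir = Path(outdir)
    expr = io_formats.read_expression_matrix(outdir / "expression.tsv", outdir / "samples.tsv")
    peaks = {
        s: io_formats.read_peaks(outdir / f"peaks_{s}.bed", s) for s in expr.strains
    }
    annotation = io_formats.read_annotation(outdir / "annotation.tsv")
    prior = io_formats.read_prior(outdir / "prior.tsv")
    return expr, peaks, annotation, prior


def write_ground_truth(truth: GroundTruth, outdir: str | Path) -> Path:
    """Persist the planted program as JSON (plus a flat edge TSV oracle)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "strains": list(truth.strains),
        "tfs": list(truth.tfs),
        "genes": list(truth.genes),
        "true_edges": {s: sorted(map(list, truth.true_edges[s])) for s in truth.strains},
        "expr_state": {f"{s}|{e}": truth.expr_state[(s, e)]
                       for s in truth.strains for e in truth.entities},
        "peak_state": {f"{s}|{e}": truth.peak_state[(s, e)]
                       for s in truth.strains for e in truth.entities},
        "modules": truth.modules,
        "candidate_pairs": sorted(map(list, truth.candidate_pairs)),
        "decoy_pairs": sorted(map(list, truth.decoy_pairs)),
        "silent_genes": sorted(truth.silent_genes),
    }
    path = outdir / "ground_truth.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")
    with open(outdir / "true_edges.tsv", "w") as fh:
        fh.write("strain\ttf\ttarget\n")
        for s in truth.strains:
            for tf, t in sorted(truth.true_edges[s]):
                fh.write(f"{s}\t{tf}\t{t}\n")
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    if path.is_dir():
        path = path / "ground_truth.json"
    with open(path) as fh:
        payload = json.load(fh)
    strains = tuple(payload["strains"])

    def _unkey(d: dict[str, bool]) -> dict[tuple[str, str], bool]:
        out = {}
        for key, val in d.items():
            s, e = key.split("|", 1)
            out[(s, e)] = bool(val)
        return out

    return GroundTruth(
        strains=strains,
        tfs=tuple(payload["tfs"]),
        genes=tuple(payload["genes"]),
        true_edges={s: frozenset(map(tuple, payload["true_edges"][s])) for s in strains},
        expr_state=_unkey(payload["expr_state"]),
        peak_state=_unkey(payload["peak_state"]),
        modules=dict(payload["modules"]),
        candidate_pairs=frozenset(map(tuple, payload["candidate_pairs"])),
        decoy_pairs=frozenset(map(tuple, payload["decoy_pairs"])),
        silent_genes=frozenset(payload["silent_genes"]),
    )
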