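# macrogrn

Strain-resolved gene regulatory network (GRN) reconstruction for resting
(unstimulated) macrophages — and, more generally, for any multi-strain
design with bulk RNA-seq, ATAC-seq peaks and a TF→target motif prior.

Genetically distinct inbred mouse strains rewire their basal macrophage
regulatory circuitry even before any stimulus arrives.  To map that
rewiring, a strain's GRN is built by a triple intersection of evidence:
a directed edge TF → gene exists in strain *s* exactly when

* (TF, gene) is a candidate pair in the motif-prior table,
* the TF is expressed in *s* (replicate-mean TPM ≥ 10),
* the gene is expressed in *s* (replicate-mean TPM ≥ 10), and
* an ATAC peak overlaps the gene's promoter window
  ([−1000, +100) bp around the TSS, strand-aware).

Across strains the package then derives the **pan** GRN (edge union,
with per-edge strain provenance), the **core** GRN (edge intersection),
strain-unique TFs (mean TPM ≥ 10 in exactly one strain) and their
exclusive sub-networks.  Around this core it provides the accompanying
analyses such a study runs: differential expression (Welch t-test on
log2(TPM+1), BH-FDR < 0.05 with |log2FC| > 2), top-variable-gene k-means
and PCA, Cheng–Church δ-biclustering on the mean squared residue
H(I,J) = (1/|I||J|) Σ (a_ij − a_iJ − a_Ij + a_IJ)², a WGCNA-style
co-expression network (adjacency |cor|^β, topological overlap, module
detection, scale-free fit R² of log p(k) on log k), a centrality battery
(degree, betweenness, stress, clustering and topological coefficients,
connectivity, path lengths, Hub⁵⁰ = degree ≥ 50), hypergeometric
enrichment, and validation of predicted regulons against ChIP-derived
target sets.

Because the real study data are external, the package ships a
first-class synthetic data generator that plants a full regulatory
program (expression states, promoter accessibility, co-expression
modules, decoy prior pairs) and emits exactly the file formats the
readers consume.  In the noise-free limit the reconstructed strain GRNs
equal the planted edges — recovery is exact, not approximate — which is
what makes every downstream stage testable.  See `docs/methods.md` for
the models and their assumptions.

## Worked example

Run the whole pipeline on the default synthetic five-strain study
(5 strains × 2 replicates, 30 TFs, 600 genes) and print the summary:

```bash
macrogrn run --outdir demo --seed-override 1
macrogrn report --outdir demo
```

The report prints, among other things:

```
--- grn/grn_stats.json ---
{
 "core": { "n_edges": 152, "n_nodes": 95, "n_targets": 86, "n_tfs": 9 },
 "pan":  { "n_edges": 2561, "n_nodes": 578, "n_targets": 550, "n_tfs": 30 },
 "per_strain": {
  "BALB":  { "n_edges": 1391, "n_nodes": 398, ... },
  "C57":   { "n_edges": 1557, "n_nodes": 481, ... },
  ...
 }
}
--- topology/topology_stats.json ---
{
 "hub_count": 73,
 "n_edges": 4365,
 "n_nodes": 307,
 "random_reference_r2": 0.0125,
 "scale_free_r2": 0.8525,
 ...
}
--- validate/validation.tsv ---
tf      strain  n_predicted  n_chip  n_overlap  precision  recall
TF010   C57     82           82      82         1          1
```

Reading the numbers: each strain's GRN keeps only the prior pairs whose
TF and target are expressed and whose target promoter is open in that
strain, so the five GRNs differ (983–1557 edges).  Their union — the pan
atlas — has 2561 edges over 578 nodes; only 152 edges survive in all
five strains (the core), carried by the 9 TFs expressed everywhere.
The thresholded co-expression network (307 nodes, 4365 edges) fits a
decaying power law far better than a size-matched random graph
(R² 0.85 vs 0.01), and 73 nodes are Hub⁵⁰.  The validation row checks
the C57 GRN's busiest TF against a simulated ChIP target set: at zero
ChIP dropout every predicted target is supported (precision 1), as the
planted ground truth guarantees.

The same outputs exist as plain files under `demo/<stage>/` (TSV edge
lists, SIF/GraphML export via `macrogrn.io_formats`, per-stage
`manifest.json` with parameter echoes and output SHA-256 digests).  Real
data enter through the `inputs:` section of the YAML config instead of
the `simulate` stage: a TPM matrix TSV, a sample→strain TSV, BED peak
files per strain, a TSS annotation TSV and a motif-prior TSV, all keyed
by exact gene identifiers.

Library use mirrors the CLI:

```python
from macrogrn import synthetic_data as sd
from macrogrn.grn import accessible_promoter_genes, build_strain_grn, combine_grns

params = sd.SimulationParams(seed=1)
truth = sd.generate_ground_truth(params)
expr, peaks, annotation, prior = sd.simulate_bundle(truth, params)
grns = [
    build_strain_grn(expr, s, accessible_promoter_genes(peaks[s], annotation), prior)
    for s in truth.strains
]
pan = combine_grns(grns, "union")       # 2561 edges
core = combine_grns(grns, "intersection")  # 152 edges
```

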