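# Methods

`macrogrn` reconstructs basal-state gene regulatory networks (GRNs) for a
panel of genetically distinct strains by intersecting three evidence
layers, and surrounds that core with the standard network analyses a
regulatory-genomics study runs on such data.  This note describes the
models, the parameters that matter, what the synthetic data generator
does and does not emulate, and the numerical choices made where the
design was genuinely open.

## The GRN integration rule

For strain *s*, a directed edge TF → gene enters the GRN exactly when all
four conditions hold:

1. the pair appears in the motif-prior table (promoter motif match);
2. the TF's replicate-mean TPM in *s* is ≥ `tpm_threshold` (default 10);
3. the target's replicate-mean TPM in *s* is ≥ `tpm_threshold`;
4. at least one open-chromatin peak overlaps the target's promoter
   window.

The promoter window is strand-aware: `[tss − upstream, tss + downstream)`
on the `+` strand and mirrored on `−`, with defaults of 1000 bp upstream
and 100 bp downstream (the "promoter-TSS" convention common to peak
annotation tools), clipped at coordinate 0.  All intervals are 0-based
half-open throughout the package, so a peak ending exactly at a promoter
start does not overlap it.  A TF needs only to be expressed, not itself
promoter-accessible, to act as a regulator: accessibility is evidence
about where binding can land, and the rule applies it to targets.

The **pan** GRN is the edge union across strains (each edge annotated with
the strains carrying it), the **core** GRN the edge intersection.  By
construction core ⊆ every strain GRN ⊆ pan edge-wise, and the pan node
count satisfies `n_nodes = n_tfs + n_targets − |tfs ∩ targets|` (TFs can
be targets of other TFs).  A **strain-unique TF** is one whose mean TPM
reaches the threshold in exactly one strain; its "unique-target" sub-GRN
keeps, under the default strict reading, only targets that receive no
edge at all in any other strain's GRN.  The looser reading (all edges of
unique TFs) is available via `strict=False`; the strict one is the
default because it isolates regulation that is exclusive on both ends.

Monotonicity properties used by the tests: lowering the TPM threshold or
widening the promoter window can only add edges, never remove them.

## Expression analyses

Genes are kept when their replicate-mean TPM reaches 10 in at least one
strain; all statistics then run on `log2(TPM + 1)`.  Differential
expression between two strains is a per-gene Welch t-test on the log2
scale with Benjamini–Hochberg FDR control; a gene is called up when
fdr < 0.05 and log2FC > 2, down when log2FC < −2, otherwise `ns`.  The
fold-change gate makes the procedure conservative under the null — the
realized false-positive fraction in the calibration test is far below
the nominal 5% because a null fold change rarely exceeds 2.  The t-test
stands in for a count-based negative-binomial model because the pipeline
consumes TPM matrices, not read counts; the stage is a single function
and can be swapped.  Degenerate rows (zero variance in both groups) get
p = 1 when the means agree and p = 0 otherwise.

Variable-gene clustering ranks genes by log-scale variance (the ranking
scale is a choice; TPM-scale variance would over-weight highly expressed
genes), z-scores the top `n_top` rows, and runs k-means (k = 9 by
default) with 10 seeded restarts.  PCA centers per gene and reports
sample scores and explained-variance fractions from the SVD, with a
deterministic sign convention.

## Cheng–Church biclustering

The mean squared residue of a submatrix (rows I, columns J) is

    H(I,J) = (1/|I||J|) Σ_{i,j} (a_ij − a_iJ − a_Ij + a_IJ)²,

zero exactly for additive submatrices `a_ij = r_i + c_j`.  Discovery is
the classical greedy scheme: multiple node deletion (drop rows/columns
with mean residue > α·H while an axis exceeds 100 elements), single node
deletion (drop the single worst row or column while H > δ; each such
step cannot increase H), then node addition (re-admit rows/columns whose
mean residue does not exceed H, with a guard that reverts an addition
round if H would exceed δ).  The found bicluster is masked with seeded
uniform noise over the matrix range and the search repeats; reported
biclusters always have ≥ 2 rows and columns and their MSR is certified
against the *original* matrix, so a later round that strays into masked
cells is discarded rather than reported.  The original algorithm's
mirror-image (inverted-row) addition is omitted.  δ defaults to 10% of
the whole matrix's MSR — a scale-free default usable on z-scored input.

A caution that shaped the tests: Cheng–Church finds *additively
coherent* submatrices, not outlier stripes.  A constant block whose
value sits far from the surrounding noise mean gives its own rows the
highest residues in the full matrix (each row mixes block cells with
noise cells), so greedy deletion removes the planted rows first.
Planted-recovery exercises therefore embed the constant block at the
noise mean and use a δ below the noise floor, where the exact-zero MSR
of the block makes it the unique attractor of the deletion path.

## Co-expression network

Unsigned WGCNA-style construction: adjacency `a_ij = |cor(i,j)|^β`
(signed variant available), soft connectivity `k_i = Σ_j a_ij`, unsigned
topological overlap

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),  l_ij = Σ_u a_iu a_uj,

symmetric, in [0, 1], unit diagonal.  The scale-free fit index is the R²
of log10(frequency) against log10(k) over binned connectivities,
multiplied by −sign(slope): without the sign penalty an upward-sloping
(dense, non-scale-free) connectivity distribution can score a high R²
and the automatic power pick collapses to β = 1.  Binning uses one bin
per distinct value for small integer supports (this reproduces exact
power-law fixtures with R² = 1) and equal-occupancy quantile bins with
count densities (count/width) otherwise — equal-occupancy bins with raw
frequencies are flat by construction and carry no slope information.

The pipeline's default soft power is 18; with only S×R ≈ 10 samples the
per-power fit index is too noisy for a reliable data-driven pick, so the
pick (smallest β reaching `fit_target`, else argmax with a warning) is
computed and written for the record but not used unless requested
(`soft_power: null`).

**Module detection** clusters `1 − TOM` by average linkage and decomposes
the dendrogram by *recursive gap cutting*: within a homogeneous cluster
the merge heights form a dense ramp, while a genuine module boundary
appears as a gap between the within-module merges and the join that
glues modules together.  At each level the algorithm considers every gap
of at least `min_gap` (default 0.05 on the 0–1 dissimilarity scale),
cuts at the candidate that keeps the most genes in clusters of at least
`min_module_size` (ties toward the larger gap), and recurses into the
parts.  This handles hierarchies whose cross-module joins happen at
staggered heights — there, no single global cut height separates every
module, which is why a static height scan was abandoned — and the
assignment score prevents a spurious low-height gap from shattering a
cluster into fragments.  Clusters below `min_module_size` (default 30)
become the reserved "grey" label; modules are renamed M1, M2, … by
decreasing size with lexicographic tie-breaks, so labels are
deterministic.  No PAM-style reattachment of borderline genes is
performed.

Edge export thresholds the adjacency so the network has a target mean
degree (default 15, matching the edge-to-node ratio of published
co-expression networks of this kind); connectivity is always reported
from the full adjacency, not the thresholded graph.

## Network topology

Centralities are computed on the simple undirected graph (self-loops
rejected), with conventions stated once: betweenness is normalized by
(n−1)(n−2)/2 unordered pairs; **stress** counts geodesics through a node
over unordered pairs, endpoints excluded, via per-source BFS
shortest-path counts combined pairwise; the **topological coefficient**
of node i averages `J(i,j)/k_i` over all partners j sharing at least one
neighbor, where J is the shared-neighbor count plus one if i and j are
adjacent (so a triangle scores 1 everywhere); average shortest path
length is over the node's own component (NaN for isolated nodes);
connectivity is the weighted degree; all path quantities are unweighted.
Hub calling uses the degree ≥ 50 rule ("Hub50").

The random baseline is Erdős–Rényi G(n, m) with matched node and edge
counts.  Group comparisons (e.g. TFs vs genes) default to a two-sided
Mann–Whitney test — the two groups are unpaired and differently sized —
computed exactly by full enumeration of group assignments when the
pooled sample has ≤ 16 values (the enumeration handles ties, which the
standard exact recurrence does not) and by normal approximation
otherwise; a Wilcoxon signed-rank test is available for genuinely paired
inputs and returns p = 1 with a warning when every difference is zero.
Hypergeometric enrichment reports the one-sided over-representation tail
P(X ≥ overlap).

## ChIP validation

For a TF with predicted targets P and a ChIP-derived set C, the headline
recovery fraction is |P ∩ C| / |P| (precision of the GRN's predictions);
|P ∩ C| / |C| is reported alongside since either direction can be the
quantity of interest.  A TF with no predicted targets is an error, not a
zero.  Expected recovery declines monotonically in ChIP dropout, which
the tests assert over seeded replicates.

## The synthetic study generator

The generator emulates the structure of a five-strain,
two-replicates-per-strain resting-macrophage study: 30 TFs and 600 genes
by default, with strain labels C57/BALB/NOD/PWK/SPRET when five strains
are simulated.  Its planted program is constructed so that every
downstream stage has an exact oracle:

* **Expression states.**  Each of the first S TFs is on in exactly one
  strain (so strain-unique logic is always exercised); remaining TFs are
  on per strain with probability 0.8.  Genes are partitioned into
  planted modules (~100 genes each); expression class is a property of
  the *module* — a module is either constitutive (members on in every
  strain) or strain-variable (all members share one on/off pattern,
  distinct across modules).  This makes the module label each member's
  dominant co-expression signal; mixing on/off classes inside a module
  would let the ±6–7 log2 on/off swing, not the planted factor, drive
  the correlation structure.  A fraction of genes (8%) is silent in
  every strain and hosted only in constitutive modules; these are the
  decoy targets.
* **TPM model.**  `log2(TPM)` = on/off base (log2 of 100 or 1 TPM) + a
  per-(module, sample) latent factor + replicate noise (sd 0.25 log2
  units).  Module factors (sd 0.8) are orthogonalized across modules —
  planted programs are distinct by construction, so chance correlation
  between random factor vectors cannot blur module boundaries — and
  truncated at two sigma so "on" strain means stay above and "off" means
  below the TPM-10 threshold even in the noise-free limit.  That
  truncation is what makes exact noise-free recovery a theorem rather
  than a tendency.
* **Peaks.**  Every accessible (strain, entity) pair gets a 100-bp peak
  straddling its TSS on a synthetic chromosome (TSS spacing 10 kb),
  minus a configurable dropout; distal decoy peaks sit 3 kb downstream
  of random TSSs, outside any default promoter window.  Accessibility is
  0.85 per (strain, entity).
* **Prior.**  Each TF targets ~15% of the genes (drawn from non-silent
  genes, occasionally another TF); decoy pairs point exclusively at
  everywhere-silent genes, so no decoy can ever satisfy the integration
  rule and GRN precision is well defined.  `decoy_rate` is the decoy
  fraction of the final prior.
* **True edges** are *derived* from the planted states with the same
  integration rule the pipeline applies, so with zero replicate noise
  and zero peak dropout the reconstructed strain GRNs equal the planted
  edges exactly; with peak dropout d, expected recall is ≈ 1 − d while
  precision stays 1.
* **ChIP sets** subsample a TF's true targets (`round((1−dropout)·n)`)
  plus `round(false_rate·n)` random non-targets, deterministically per
  seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level noise and mapping artifacts;
count-based mean–variance relationships (TPM is drawn log-normal
directly); enhancer–gene regulation beyond the promoter window;
correlated TF–target expression (synthetic TFs carry no module factor,
so TF-vs-gene centrality comparisons on synthetic co-expression networks
do not reproduce the elevated TF centralities seen in real data);
motif-strength gradations in the prior (a pair is present or absent);
and genuine biological pathway structure.  Recovery results certify the
integration and analysis machinery, not performance on real sequencing
data.

## Problem sizes and determinism

The test suite runs every stage at the generator's default scale where
the check depends on those conditions (noise-free and dropout recovery,
ChIP monotonicity, pipeline determinism) and at a reduced scale
(3 strains, 8 TFs, 120 genes) for checks whose property is
size-independent, such as the 200-bundle set-algebra sweep; replicate
counts stated with each property (200 bundles, 100 seeds, 500 graphs,
50 runs) are kept as is.  All randomness flows from explicit seeds —
generator seeds via `numpy` seed sequences, k-means restarts and
bicluster masking via the config seed — and two pipeline runs with the
same config produce byte-identical outputs for every stage; the
timestamped `run.log` is the only file excluded from that guarantee
(stage manifests record parameters and output SHA-256 digests, no
timestamps).

## Known limitations

* The Mann–Whitney normal approximation (pooled n > 16) is not
  continuity-corrected in the exact sense; at the group sizes the
  pipeline compares this is immaterial.
* The Cheng–Church addition phase runs once per discovery round rather
  than to a fixed point, and inverted-row addition is omitted.
* `pick_soft_threshold` is honest but noisy at ~10 samples; prefer a
  fixed power (the pipeline default) unless the design has more samples.
* Gene identifiers are matched as exact case-sensitive strings; no
  symbol/alias resolution is attempted.
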