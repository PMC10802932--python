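# Methods

This note documents the models, the numerical choices and the design
decisions behind `toppathways`, and what the synthetic-data tests do and do
not establish about real data.

## Data model and quality control

The pipeline consumes a sparse gene × cell UMI count matrix with per-cell
cluster, stage and subset labels. Clustering, trajectory inference and
cell-cycle correction are deliberately out of scope: labels are inputs, the
package analyzes signaling given them.

QC removes cells with UMI totals outside `[min_umi, max_umi]`
(defaults 100 and 1500, bounds inclusive — cells strictly above/below the
band are discarded) and then drops genes whose identifier starts with the
mitochondrial prefix (`MT-`, case-insensitive). Mitochondrial removal
operates at the gene level because read-level data is unavailable once a
count matrix exists. Cells are filtered on their stored UMI totals *before*
gene removal; the UMI column is then recomputed so that CP10K column sums
are exactly 10⁴. The order (cells first, then genes) is a documented choice.

Normalization is counts-per-10,000: `x[g,c] = counts[g,c] / umi[c] · 1e4`.
This fixed size-factor dialect replaces pool-based size-factor estimators;
it keeps per-cell normalization subset-invariant, which the comparative
module relies on (subsetting never requires re-normalization). Gene and
cell identifiers are opaque strings matched exactly and case-sensitively;
database genes absent from a dataset are logged once and score zero.

## Interaction scoring

For ligand–receptor pair (l, r) and ordered cluster pair (s → t), the raw
score is the product of CP10K cluster means,
`S = mean_expr[l, s] · mean_expr[r, t]`, normalized per LR pair by its sum
over all ordered cluster pairs (self-pairs included, so autocrine signaling
such as SLIT/ROBO within one epithelium cluster is representable). The
product-of-means form is the minimal score consistent with normalizing over
all pairwise cluster interactions; information-theoretic prioritization of
pair specificity (KL-divergence style) is intentionally not layered on top —
ranking uses the normalized score directly. Normalization per
(ligand, receptor, pathway) group makes every group sum to 1 unless all its
raw scores are zero, in which case all normalized scores are zero.
By default senders range over all clusters; a sender whitelist is exposed
for analyses that restrict to specific support cells.

## Differential expression

The progenitor-vs-mature test is a two-sided Wilcoxon rank-sum on CP10K
values. Group sizes ≤ 8 on both sides use exact enumeration over all group
assignments with midranks, defining p = P(|W − E W| ≥ |w_obs − E W|); larger
groups use the tie-corrected normal approximation *without* continuity
correction, which keeps the global-null false-positive rate at nominal level
for the discrete, tie-heavy values typical of shallow single-cell counts
(verified by the calibration test). Genes constant across both groups get
p = 1. A zero-inflated NB test could be slotted behind the same interface;
the rank-sum choice trades model fidelity for distribution-free calibration,
which is what the downstream filter actually consumes.

Fold change is computed on cluster means with a pseudocount:
`FC = (mean_mature + ε)/(mean_prog + ε)`, ε = 0.01 CP10K units
(configurable), bounding ratios for lowly expressed genes. BH step-up
adjustment gives the FDR. The DEG filter keeps genes with `fdr < 0.1` and
fold change beyond 2× — two-sidedly by default (`max(FC, 1/FC) > 2`), since
the network scoring uses |log₂FC| and down-regulated targets are equally
informative; a one-sided mode is available. Both inequalities are strict.

## Multilayer network and pathway activity

Admission gates: a ligand needs expression fraction ≥ `min_expr_frac`
(default 0.1) in at least one sender; receptors and TFs need it in the
receiver; targets must be filtered DEGs wired to an admitted TF. Only direct
edges from the supplied receptor→TF and TF→target tables are used — no
inference of signaling routes from interaction databases — so database
completeness is the caller's contract. Nodes without a complete
ligand → target path are pruned iteratively to a fixed point; an empty
result raises a diagnostic naming the layer that emptied first.

Scoring flows bottom-up with sum-to-1 normalization at every layer:

* target weight `w ∝ |log₂FC|` — absolute log scale makes up- and
  down-regulated targets commensurable (signed/linear variants would bias
  toward induction; the absolute form is the default dialect);
* TF score `u ∝ mean of w` over the TF's targets (a `count` mode using the
  number of targets is available; mean-of-weights is the default because it
  lets the target fold-change information propagate upward);
* receptor `v ∝ Σ u`, ligand `z ∝ Σ v`, pathway `P ∝ Σ z` over the
  pathway's annotated LR edges — a ligand contributes once per annotated
  edge, so promiscuous ligands feed every pathway they belong to.

Sum-to-1 normalization (divide by the layer's raw-score total) is the
specific normalization dialect chosen because it makes cross-run activity
ratios well defined. Degenerate case: if every retained target has
|log₂FC| = 0 (possible only with the filter disabled), target weights fall
back to uniform with a logged warning; all higher layers are then positive
by construction. Ties in the final ranking break lexicographically, making
every output deterministic.

The interaction-scoring stage and the network stage are deliberately
decoupled: ligands enter the network by expression fraction, not by
interaction rank. An optional `min_norm_score` gate couples them when
desired.

## Developmental analysis

A module score is the per-cell mean of z-scored `log1p(CP10K)` expression
over a gene set, z-scored per gene across *all* cells (the scoring scope is
a documented choice); zero-variance genes contribute 0. No control-gene-set
subtraction is used — the developmental score is a *difference* of two
module scores (maturation minus progenitor), which cancels cell-level
offsets to first order. Identical sets give exactly 0; swapping the sets
negates the score.

Proportions are computed within (compartment, subset, stage) strata from a
user-supplied cluster → compartment map and sum to 1 per stratum.
First-appearance detection scans stages in the user-supplied order (never
lexicographic) for the earliest stage where a cell type's within-compartment
fraction reaches the presence threshold, default 1% (no principled value
exists; 1% of a compartment is well above singleton noise at typical
stratum sizes and is configurable).

## Comparative runs

`run_toppathways` composes subset → QC → normalize → profile → interaction
scores → DE → DEG filter → network → scoring → ranking, labels any failure
with its stage name, and records provenance (transition, parameters,
database checksum, package version). Per-subset runs must share one database
— enforced by content checksum — and activity ratios are smoothed,
`(Pₐ + δ)/(P_b + δ)` with δ = 1e-6, so pathways absent from one run stay
finite and are flagged. Because activities are normalized within each run,
ratios measure *relative* pathway dominance, and a planted effect ratio ρ
maps to an activity ratio compressed toward 1 by the shared reference
pathways (see the generator section); raw per-layer scores are available
through the run details for users who want unnormalized comparisons.

## Synthetic data generator

Counts are negative binomial with mean μ[g, c] and dispersion φ
(variance μ + μ²/φ). Defaults: baseline mean μ₀ = 0.5 per gene, φ = 2,
~400 genes (300 background + 8 pathways × (2 ligands, 2 receptors, 2 TFs,
6 targets) + 10 markers), six clusters named for the tooth-germ lineages
(DEM, DP, POB, OB, EK, IEE), ~2,000 cells. At μ₀ = 0.5 the NB zero mass
(~0.64 per gene) already gives sci-RNA-seq-like sparsity, so no explicit
dropout layer is added (a deliberate simplification). Per-cell expected UMI
totals are drawn uniformly from (200, 1000) and the cell's means rescaled
accordingly, emulating library-size variation inside the QC band.

Planted structure enters through the means: ligand × α in the sender,
receptor × β in the receiver, responsive targets × 2^f in the mature
cluster, marker genes following configured per-cluster means. Decoy
pathways are wired identically but unboosted, making the null ranking
exchangeable — the property that gives the null-calibration check its
meaning. Cell counts per (subset, stage, cluster) follow the configured
proportion schedule with deterministic largest-remainder allocation, so
planted first-appearance stages are exact rather than sampled. One RNG
stream is consumed in fixed order (per-cell scales, then the count matrix,
genes outer / cells inner), so identical (config, seed) reproduce
byte-identical output.

Study configurations:

* `default_config` — one planted FGF signal (α = 8, β = 4, f = 3) among 8
  pathways; the recovery harness checks it ranks first.
* `null_config` — boosts 1, f = 0: all pathways exchangeable; the designated
  label should rank first ~1/8 of the time. For this configuration the DEG
  filter is disabled (`null_params`): under the null the standard filter
  correctly empties the target layer, so calibration is assessed on the
  ranking itself, with every pathway's targets entering at noise-driven
  weights.
* `ratio_config(ρ)` — two subsets; the FGF pathway has 16 TF → target
  channels wired one-to-one, of which 2ρ respond (f = 2.5) in one subset vs
  2 in the other, and 7 reference pathways respond identically in both.
  One-to-one wiring matters: under fully connected TF → target wiring the
  mean-of-weights TF score provably erases target multiplicity, so a
  multiplicity-coded effect would be invisible by construction. With
  symmetric topology the expected activity is P(FGF) = k/(k + 42) for k
  responsive channels, i.e. expected incisor/molar ratios ≈ 1.9 (ρ = 2) and
  ≈ 5.5 (ρ = 7) — monotone in ρ and within a factor of two of ρ, which is
  what the recovery harness asserts. Per-gene log₂FC cannot carry a 7:1
  effect directly: every surviving target must exceed the fold-change
  threshold (flooring the per-gene effect) and very large boosts distort
  CP10K library sizes.
* `kinetics_config` — two subsets × five stages; OB reaches the 1% presence
  threshold one stage earlier in the incisor, and maturation/progenitor
  marker means rise/fall along DP → POB → OB.

## What the synthetic tests do and do not show

The generator plants clean block structure: independent NB genes,
homogeneous clusters, no batch effects, ambient RNA, doublets or barcode
collisions, and database wiring that exactly matches the planted topology.
Passing the recovery, calibration and ratio harnesses therefore
demonstrates that the *pipeline machinery* is correct — scores computed as
specified, normalizations exact, ranking faithful to planted signal, null
behavior unbiased — not that the method is robust to misannotated
databases, correlated genes or continuous differentiation gradients in real
tissue. Conclusions about real data additionally depend on the quality of
the supplied clustering and pathway database.

## Problem sizes and tolerances

Test and acceptance runs use the defaults above (~2,000 cells for recovery
and null harnesses, ~1,000 cells per subset for ratio harnesses, 1,200
cells for kinetics), sizes at which every planted effect is comfortably
detectable while the whole suite runs in well under a minute of compute per
harness. Layer normalization is asserted to 1e-9; oracle equivalence to
1e-10 absolute; statistical checks use exact binomial 99% confidence
intervals. The rank-sum exact path is limited to groups of ≤ 8 per side
(12,870 enumerated assignments at worst).
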