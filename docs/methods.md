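# Methods

## Pipeline model

clonoscope treats a multiplexed single-cell TCR experiment as two linked
inputs: per-sample expression triplets (Matrix Market counts + features +
barcodes, one directory per Sample Tag) and a single AIRR Rearrangement
TSV with one row per assembled dominant chain contig. The pipeline is a
fixed stage order — import/merge → normalize → gate → chain cleaning →
pairing → clonotype and CDR3-type counting → multimodal features →
embedding → export — with every stage usable on its own from Python.

Assumptions: the upstream platform has already assembled one dominant
contig per chain (multiplet rows are tolerated and resolved, see below);
chains are amino-acid sequences over the 20 residues plus `*` (stop) and
`X` (ambiguous); cell identity is the shared barcode between expression
matrix and AIRR `cell_id`.

## Chain cleaning

* **IG removal.** Rows with locus IGH/IGK/IGL are B-cell contamination and
  are dropped, counted in the log.
* **Productive/UMI filter.** Only rows flagged productive with
  `umi_count ≥ min_umi` (default 1) survive. A missing UMI count parses to
  0 with a warning, which keeps the record but costs it tie-breaks and the
  default UMI filter — fail-soft on an optional field.
* **5′-UTR trimming.** Pseudo-translation of the 5′ UTR prepends residues
  and stop codons to the real open reading frame. The mature chain is
  taken from the first methionine strictly after the **last** stop codon
  (a UTR can pseudo-translate through several stops; the true start
  follows the final one). Without any stop the sequence is trimmed to its
  first methionine; a chain with no qualifying methionine is dropped and
  logged. The operation is idempotent.
* **Constant-region restoration** is two-level. The annotation level
  always applies: an empty or ambiguous `c_call` becomes the locus default
  (TRA→TRAC, TRB→TRBC1, TRG→TRGC1, TRD→TRDC). The sequence level applies
  only when a canonical constant amino-acid table is supplied: if the
  chain ends partway into the canonical constant sequence (longest
  suffix/prefix overlap), the missing canonical tail is appended.
  Sequence-level restoration is off by default because extending a
  sequence without a reference is not possible; shipping one is a
  configuration choice, not a default.

## Pairing and counting

Per cell, one dominant chain per locus is chosen: highest UMI count, ties
broken by lexicographically smallest sequence so the outcome never depends
on row order. Cells with both TRA and TRB become αβ cells, both TRG and
TRD γδ cells; a cell qualifying for both receives the type with the larger
summed UMI (tie → αβ) and is flagged. Cells without a complete pair are
dropped and counted. Contigs are `TRA:<aa>___TRB:<aa>` /
`TRG:<aa>___TRD:<aa>` with fixed chain order and separator.

Counting is exact grouping by contig identity (no edit-distance
clustering), sorted by cell count descending then contig ascending.
CDR3-types group by the paired CDR3 sequences; a paired cell lacking a
CDR3 annotation on either chain still counts as a clonotype but is
excluded from CDR3-typing (logged).

Hash identifiers are the first 8 bytes of the contig's SHA-256, rendered
as an unsigned big-endian decimal — stable across runs, platforms and
Python processes, unlike the built-in `hash()`.

## Normalization and gating

`log_normalize` computes `log2(count/total × scale_factor + pseudocount)`
with scale factor 10,000 and pseudocount 1 (zeros map to zeros, sparsity
preserved; the computation touches only stored nonzeros). Cells with zero
total UMIs are QC failures and are dropped before division.

Gating thresholds default to "strictly above 0 on the normalized scale":
the T gate takes cells with any of CD3D/CD3E/CD3G positive (optionally
unioned with cells carrying a TR-locus chain); CD4 = T ∧ CD4⁺ ∧ all CD8
markers at/below threshold; CD8 symmetric. Double positives fall in
neither subset, avoiding double counting; they remain in the T gate.

## Multimodal features and embedding

The feature matrix concatenates marker expression, the cell's clonotype
size, one-hot Sample Tag, one-hot clonotype ID (clones below
`clonotype_min_cells` = 2 share one "singleton" column to bound
dimensionality), the αβ indicator and one-hot V(D)J gene segments.
Segment names are allele-stripped (`TRBV19*01` → `TRBV19`) so convergent
clones sharing a gene but not an allele co-locate. Columns exist only for
observed segments, so αβ cells are structurally zero in all γδ columns
and vice versa.

Embedding: per-feature z-scoring (zero-variance features set to 0, so a
constant column cannot perturb the result), PCA to `min(30, n_features−1,
n_cells−1)` components, UMAP to 2-D, HDBSCAN (min cluster size 10) on the
2-D coordinates; a flag switches clustering to the PCA space. Binary
columns are standardized like any other to keep the contract simple.

### Numerical choices

* All stochastic steps run from one seed (default 42).
* UMAP uses seeded **random initialization** rather than the spectral
  default. Cells of one clone have identical one-hot rows, which makes
  the k-NN graph Laplacian's eigengap degenerate; ARPACK's result then
  depends on solver-internal state that persists within a process, so
  spectral init is not reproducible call-to-call on exactly the data this
  package produces. Random init is fully determined by the seed; on the
  well-separated clone structure the layouts are equivalent for
  clustering purposes.
* HDBSCAN label −1 is noise; cluster labels are arbitrary, so ground-truth
  comparisons use the adjusted Rand index, which is label-invariant.

## Synthetic data generator

The generator emulates the input contract and the shape of an
antigen-stimulation experiment: two samples ("Pre", "Post"), a clonotype
pool with one planted dominant clone occupying `dominant_fraction`
(default 0.3) of the 500 αβ cells and confined to "Post", 50 γδ cells, 20
B cells contributing IGH/IGK rows, and a zipf-shaped (shape 1.5) clone
size distribution for the remainder. Chains are random scaffolds with a
leading methionine and a canonical `C…F` CDR3 embedded in the full
sequence; V/D/J calls come from small fixed vocabularies (8 TRBV, 2 TRBD,
6 TRBJ, …) so one-hot blocks stay inspectable. Non-dominant clone sizes
are capped strictly below the dominant clone (excess spilled to the
smallest clones); configs where that is impossible are rejected, since a
"dominant" clone that can be overtaken contradicts the generator's
contract.

Expression is negative-binomial (gamma–Poisson, dispersion 2.0) over a
12-gene hallmark panel with per-population means: CD3 chains mark T
cells, CD4 vs CD8A/CD8B split the αβ bulk (30 % CD4), the dominant clone
is an activated CD8 phenotype (CD8A/IL2RA/IFNG elevated), γδ cells are
NKG7-high, B cells MS4A1-high. A cell that samples all zeros gets one
PTPRC count so no barcode is silently lost to the zero-total QC drop.

Injectable artifacts, each at a configurable rate and all off by default:
5′-UTR prefixes (stops, no downstream methionine before the true start —
trimming recovers the original exactly), missing `c_call`, unpaired cells
(one chain removed; excluded from the expected count tables), and
duplicate-locus multiplets (a decoy chain at UMI 1, strictly below the
true chain's ≥ 2).

What passing tests on this generator do **not** show: robustness to real
transcriptome breadth (12 genes, no dropout structure beyond NB noise),
real V(D)J allele diversity, sequencing errors inside the CDR3, doublets
mixing two T cells, or platform-specific AIRR header drift beyond what
`column_map` remaps.

## Degenerate inputs and edge policies

Empty AIRR tables, all-IG tables and empty count tables are valid and
flow through; unknown loci and empty cell ids are dropped with counts
(fail-soft, since one malformed row should not kill a run); a required
AIRR column that cannot be remapped is a hard format error. Barcode
collisions between merged samples are disambiguated by suffixing the
Sample Tag. Exported feature names have `_` rewritten to `-` eagerly
(downstream frameworks do it silently); collisions after rewriting are a
hard error.

## Problem sizes

Tests and the acceptance script run at desk scale: 100–1,000 cells per
dataset, 30–100 datasets for oracle sweeps, 300–570 cells for embedding
checks. These sizes exercise every code path (all artifact types, both
receptor types, multi-sample merging) while a full run stays in the
minutes range on a single core.

## Known limitations

* Exact-identity clonotyping only; no edit-distance or motif grouping.
* Amino-acid level only; nucleotide contigs are out of scope.
* Sequence-level constant-region reconstruction requires a user-supplied
  canonical table; none ships by default.
* The automatic gate is a threshold rule; cluster-based population
  selection is a recipe over the features module, not a dedicated
  operation.
* No batch correction or weighted-nearest-neighbour integration; the
  export exists precisely to hand off to frameworks that provide them.
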