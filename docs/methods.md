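# Methods

This note documents the models, conventions and design choices behind
`clonotrack`, in the order the pipeline applies them, followed by the
synthetic-data model the tests rely on and its known limitations.

## Per-cell QC and normalization

A cell fails QC iff its mitochondrial fraction exceeds 0.25 **strictly**
or it expresses fewer than 200 genes **strictly** (a cell at exactly 25%
mitochondrial reads, or exactly 200 genes, passes).  These boundary
semantics are a literal reading of the stated criteria ("more than 25%…
fewer than 200") and are pinned by tests.  The mitochondrial gene set
defaults to all features prefixed `MT-` and is configurable, since no
canonical set is prescribed.  An optional explicit barcode blacklist
(default empty) stands in for any additional low-quality-cell removal; no
criterion is invented for it.

Normalization is per-cell library-size scaling with a log transform,
`value = ln(1 + count · s / total)` with scale factor `s = 10,000` — the
standard definition of the named single-cell convention.  Zeros map to
zeros, so sparsity is preserved, and a zero-total cell is an error (it
cannot have passed QC).

## Lineage gating and CD8⁺ selection

The reference workflow annotates graph-derived clusters; this package
instead gates **per cell** on canonical markers, removing the dependence
on an embedding/clustering stack while keeping the one decision the
clonality analysis needs — CD8⁺ selection with CD4/TRDC/CD68 exclusion —
deterministic and directly testable.  This is a deliberate deviation:
cluster numbering, UMAP layouts and fine CD8 phenotype subclusters are
out of scope, and phenotype axes are exposed instead as supervised panel
averages (`panel_average`).

Each label carries required-positive and required-negative gene sets
(shipped as editable YAML, seeded from the canonical kidney-infiltrate
markers: PTPRC, CD3E, CD8A, CD4, TRDC, CD19/MS4A1, CD68/CD14, EPCAM/KRT18).
Score = mean(normalized positives) − mean(normalized negatives); the cell
takes the argmax label among those meeting the threshold (default 0.1),
else `unassigned`; exact ties break by a fixed priority order and are
logged.  CD8⁺ selection keeps CD8-labeled cells whose CD4, TRDC and CD68
are all at or below an exclusion threshold.  "Expressing" defaults to raw
count > 0 — the strictest literal reading, since no cutoff is prescribed —
and is configurable to a normalized-value cutoff.  The chosen threshold is
echoed in the run report.

## Receptor assembly and clonotype calling

Contigs are first collapsed onto singular loci: the chain label is
normalized from the V/J gene locus prefix, allele suffixes (`*01`) are
stripped, and CDR3 strings are never modified.  Only productive,
full-length, high-confidence TRA/TRB contigs enter receptor assembly,
mirroring the filtered-file semantics of the upstream caller; TRD/TRG
contigs pass through flagged and are excluded downstream.  Contigs group
by verbatim barcode (the `-1` GEM-well suffix is kept; all joins use the
verbatim string).  Per-chain CDR3s are deduplicated; more than two
distinct α or β chains at one barcode marks the receptor malformed, which
excludes it (counted in the log).

Clonotype identity is the sorted CDR3α set plus the single CDR3β,
compared on **nucleotide** sequence by default — the stricter reading of
"identical" and the upstream caller's convention — with amino-acid keying
available (`key_level="aa"`) since either reading is defensible.  V/J
gene identity is deliberately not part of the key.  Dual-α cells merge
only on the full α set plus β; partial α overlap never merges clones.
Receptors with two β chains, or a single chain type, are keyless units:
unexpanded regardless of multiplicity.  Expansion requires more than 2
cells (configurable `min_expanded_size`, default 3).

Per-sample totals count every keyless receptor as its own unexpanded
unit, so `n_expanded + n_unexpanded = n_clonotypes_total` and the
expanded percentage has an auditable denominator; percentages round
half-up to one decimal (26/336 → 7.738 → 7.7).  Dual-α accounting is
cell-level within expanded-member vs unexpanded cells, with a
two-proportion z-test attached.  Note the test treats cells as
independent; when dual-α status is constant within a clone, expanded
cells are clustered and the test is mildly anticonservative — the
reported p-value should be read with that in mind.

## Tracking, persistence and overlap

Tracks match keys exactly across a participant's samples ordered by
(post-transplant day, biopsy before urine, sample id); construction is
independent of processing order.  Default scope keeps keys expanded in at
least one sample, mirroring how such figures are drawn; full scope is a
switch.  A clone expanded at a biopsy counts as **prior-seen** iff it was
*expanded* at an earlier biopsy (not merely present at size 1–2); the
any-presence alternative is a config switch, and urine samples do not
define "prior" for biopsy persistence unless configured.  Persistence
percentages round half-up to the nearest integer (13/18 → 72).
Biopsy–urine overlap is exact set intersection of expanded keys for
same-participant same-day pairs.

## Differential expression

Genes are screened before testing: detected in ≥ 20% of cells in at least
one group, and |log2 fold change| ≥ 1, where
`log_fc = log2((mean(expm1(x₁)) + 1) / (mean(expm1(x₂)) + 1))` on
log-normalized values — the v4 convention of the reference tool (natural-
log variant available).  P-values are two-sided Wilcoxon rank-sum: when
the smaller group has ≤ 8 cells the p-value is computed by full
enumeration of the C(n₁+n₂, n₁) assignments of tie-averaged pooled ranks
(the fraction of assignments at least as far from the mean rank-sum as
observed, with a 1e-12 tolerance on the boundary); larger groups use the
tie-corrected normal approximation with continuity correction.
Adjustment defaults to Bonferroni over **all** genes in the matrix (the
reference tool's convention for "adjusted p"), with Benjamini–Hochberg
and adjustment over the tested set one flag away; significance is
adjusted p < 0.05.  The defaults in force are recorded verbatim in the
run report.

## Synthetic cohort model

The generator emulates per-sample 10x 5′ outputs for a longitudinal
biopsy+urine cohort with planted truth.  Defaults reflect the study
conditions: paired-chain recovery 0.90 (full CDR3α/β obtained from ~90%
of T cells), dual TCR-α rate 0.08 (bracketing the reported 7.1% / 8.9%),
dual-β doublet rate 0.01, 3,000 cells per sample (the scale of a 10x
lane after recovery; per-sample loaded/recovered counts are not
published, so this is a convention, not a reproduction).  QC-violation
rates (mitochondrial outliers, low-gene cells) default to 0.03 each — a
typical few-percent of a dissociated tissue run.  One global integer
seed drives everything; per-sample streams are derived from
SeedSequence-style keys `(seed, participant_index, sample_index)`, which
serves the same purpose as fixed jump offsets (independent, parallel-safe
streams) with simpler bookkeeping.  Fixed seed ⇒ byte-identical files.

Expression counts are negative binomial (dispersion r = 2) with lineage-
and program-specific means.  Phenotype programs (activated, exhausted,
resident-memory, proliferating) shift the corresponding marker means
(GZMB/IFNG/PRF1; PDCD1/HAVCR2/LAG3/TIGIT/TOX; ZNF683/CD69/ITGAE/CXCR6;
MKI67), and expanded-clone cells receive immunosuppression-arm shifts on
the mTOR axis (belatacept: MTOR/RPTOR/RICTOR up, TSC1/TSC2 down;
iscalimab: FKBP1A/CD27/TNFRSF9/CD70 up) so the supervised panel contrast
is exercised end to end.  Two generator choices keep zero-noise configs
*exactly* recoverable, which the truth-recovery tests require:
lineage-defining markers carry a small deterministic count floor on top
of the NB draw (so no CD8 cell ever drops CD8A to zero), and exclusion
markers of foreign lineages have mean zero (so no CD8 cell ever draws a
CD4, TRDC or CD68 count).  CDR3s are drawn uniformly over stop-free
codons at 36–54 nt — keys only need uniqueness and identity semantics, so
no V(D)J-recombination realism is attempted.  Doublets are modeled only
as dual-β barcodes, not merged transcriptomes: only the V(D)J consequence
matters to the rules under test.  Urine samples carry each same-day
tissue clone with a shedding probability (default 0.5, at about half the
tissue size) plus urine-private clones, reproducing partial biopsy–urine
overlap.

What passing tests therefore show: the *rules* (QC boundaries, exclusion
gating, the >2-cell expansion rule, key matching across samples and
compartments, the DEG filters) are implemented exactly, and the pipeline
recovers planted truth and planted rates.  What they do not show:
robustness to ambient RNA, batch effects, merged-transcriptome doublets,
somatic processes or annotation ambiguity in real tissue — none of which
the generator emulates.

## Problem sizes and numerical choices

The end-to-end truth-recovery check uses 3 participants × (3 biopsies +
3 urine samples) at 3,000 cells/sample; rate recovery uses 6,000 cells;
DEG power uses 50 seeds at n = 100/100 with a planted log2 shift of 1.5,
and the null family-wise error check uses 200 replicates of 1,000 null
genes — sizes chosen so each property is measured with comfortable
binomial margins while the whole suite stays quick on one CPU.  Exact
rank-sum enumeration caps at 8 per group (≤ 12,870 assignments).
Matrices are sparse CSR/CSC throughout; MTX files are 1-based on disk and
0-based in memory with a single conversion point; duplicate MTX entries
are summed per MatrixMarket convention.  Degenerate inputs have defined
behavior: empty strata yield NaN with a warning, zero clonotype units
yield a NaN percentage, the first time point has prior count 0 by
definition, and empty result tables are written headers-only.

## Known limitations

- Clonotype keys ignore V/J genes; convergent junctions with different
  gene usage merge (consistent with the stated identity criterion).
- How a dual-α cell should be assigned when only one α matches an
  existing clonotype is undefined upstream; here it simply forms its own
  key and the ambiguity is flagged for review rather than guessed.
- The dual-α two-proportion test ignores clone-level clustering (above).
- DEG is cell-level, not pseudobulk: p-values treat cells as independent
  replicates, as the reference tool does.
- No doublet detection, ambient-RNA correction, HVG selection or
  integration; inputs are assumed per-sample 10x filtered outputs.
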