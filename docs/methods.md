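# Methods

This note records the models, conventions and numerical choices behind
each stage, the parameters that matter, and what the synthetic-data tests
do and do not demonstrate.

## Coordinates and the transcript model

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive)
and SAM are converted at the format boundary only. A transcript is a list
of exon intervals sorted 5'→3' in transcript orientation plus
transcript-coordinate spans for the 5'UTR, CDS and 3'UTR that tile the
transcript exactly. The stop codon is counted as part of the CDS,
following common plant-annotation practice; feature-proportion numbers
depend on this convention. When explicit `five_prime_UTR` /
`three_prime_UTR` features disagree with the exon−CDS derivation, the
explicit annotation wins and a warning is emitted (trust the annotator).
A CDS whose length is not a multiple of 3 is kept but flagged and skipped
by codon-level analyses. A footprint is reduced to its biological 5' end:
leftmost aligned base on `+`, rightmost on `-`. Multi-mapping reads are
not distinguished; the package analyzes whatever alignments it is given.

## Footprint QC

Reading frame is defined from the raw 5' end as
`(t − CDS_start) mod 3`; no P-site offset is estimated anywhere, so the
frame-0 fraction is interpretable only as a library-level periodicity
score, not as codon occupancy. Feature assignment uses the representative
(longest) transcript per gene; when a 5' end falls into several features,
priority is CDS > 5'UTR > 3'UTR > intron, with lexicographic gene id as
the tie-break — deterministic and CDS-favoring, as in common Ribo-seq QC.
All five labels (including intron and intergenic) are always reported.

## Quantification

`FPKM = count · 10⁹ / (length · total)`. The feature length is the CDS
for Ribo-seq (elongating footprints live there) and the full exonic
length for RNA-seq. `total` is the number of reads assigned to genes for
that assay and library — not the raw library size, which the package
never sees; this makes normalization self-consistent within the pipeline.
Counting rules: a Ribo-seq read belongs to a gene when its 5' end lies in
the CDS (strand-matched); an RNA-seq read when its aligned span overlaps
the exonic span (strand ignored; libraries are treated as unstranded).
Each read counts for at most one gene; ties go to the smaller gene id.

TE uses the per-condition **mean** FPKM over replicates, and a gene
qualifies only when that mean is ≥ 1 (`min_fpkm`) in both assays — the
least lossy reading of a replicate-unspecified "FPKM ≥ 1" rule; per-
replicate FPKMs remain available. The log₂ TE groups use the half-open
partition G1 ≤ −1 < G2 ≤ 0 < G3 ≤ 1 < G4, the only exhaustive and
disjoint reading of the conventional four-group description (the
boundary at +1 belongs to G3).

## Differential analysis

The built-in DE caller is a negative-binomial Wald test:

* median-of-ratios size factors over all libraries of the contrast;
* per-gene method-of-moments dispersion
  `d = max(0, (s² − μ) / μ²)` from within-condition variances, a
  least-squares trend `d ≈ a₀ + a₁/μ` over informative genes, and
  log-space shrinkage with weight `df / (df + prior_df)` toward the trend
  (`prior_df = 6`; with 2+2 replicates the gene weight is 0.25, a strong
  shrinkage appropriate for so few residual degrees of freedom);
* `z = Δln(μ̂ + ½) / SE`, `SE² = (1/μ̂_A + d)/n_A + (1/μ̂_B + d)/n_B`
  (delta method for the log of an NB mean), two-sided normal p-value,
  BH-adjusted.

The pseudocount ½ stabilizes fold changes of barely expressed genes and
preserves the A↔B swap symmetry (log2fc negates, p unchanged). Status
follows the standard contract: up iff log₂FC ≥ 1 and FDR < 0.05, down
symmetric, else unchanged — so low-count noise cannot produce calls
without clearing the effect-size bar. This caller is not a bit-level
re-implementation of any published tool; externally computed
(log2fc, p) tables are accepted via `de_results_from_table`, and only the
thresholding and quadrant classification depend on them.

**TE change.** No standard named test exists for two-replicate TE shifts;
the package's construction (its own design decision) is a Pearson
chi-square interaction test, without continuity correction, on the 2×2
table of assay × condition counts (normalized per assay by
median-of-ratios, summed over replicates), plus the effect floor
|Δlog₂TE| ≥ 1. The chi-square treats summed counts as if Poisson and is
anticonservative under overdispersion; the effect floor is what keeps the
empirical FDR controlled (verified on synthetic data). Genes with a zero
table margin are excluded and flagged rather than tested.

**Enrichment** is the upper-tail hypergeometric test per term with BH
over terms, against a user-supplied gene→term map; no ontology database
ships with the package.

## Quadrants and summary statistics

The nine quadrants are the full 3×3 grid of (tx status, tl status);
classification is total on that grid, and the denominators of all
percentages are the genes classified at both levels (in practice, genes
passing the FPKM floor in both assays). The shared-DEG percentage is
`100 · (shared_up + shared_down) / (tx_up + tx_down + tl_up + tl_down −
shared_up − shared_down)`; a set-based entry point computes the same
quantity as |A∪B| of the up-Venn plus the down-Venn. Note the published
three-way percentages this statistic mirrors are not always internally
consistent (one reported heat-stress triple sums to >100%); this package
always reports fractions over one denominator, which sum to 100 exactly.
R² is the squared Pearson correlation of the per-gene log₂ fold changes.

## Sequence features

NMFE is the predicted minimum free energy divided by sequence length.
The default engine is a Nussinov base-pair maximization: −1 per
Watson–Crick or G:U pair, minimum hairpin loop of 3 unpaired bases,
O(n³) dynamic programming, verified against exhaustive enumeration of
all structures for short sequences. Its "energies" are pair counts, not
thermodynamics: comparisons are meaningful within one engine, and the
ViennaRNA backend should be used when physical energies matter.
TE-group comparisons use pairwise two-tailed Welch t-tests at α = 0.05
with a compact-letter display and **no** family-wise correction (raw
pairwise p-values are reported; the correction policy is left to the
analyst). The accordant-vs-discordant comparison uses the two-sample KS
test with exported empirical CDFs — the cumulative-curve comparison the
field usually plots, chosen here as the explicit statistic.

## uORF analysis

Eligible 5'UTRs are 60–460 nt inclusive. Every AUG opens at most one
uORF, ending at the first in-frame stop; the uORF must terminate inside
the 5'UTR. AUGs whose first in-frame stop lies beyond the UTR (potential
CDS-overlapping ORFs / N-terminal extensions) are returned separately and
excluded from uORF statistics — containment is what makes lengths and
distances well defined. The minimum uORF is AUG+stop (6 nt); no further
length floor is imposed. Translation is called from footprint FPKM over
the uORF span (5'-end containment; feature length = uORF length; same
mapped-read total as gene-level Ribo-seq FPKM), translated iff FPKM ≥ 1,
inclusive. Kozak windows cover −6..+4 with the A of AUG at +1 (no
position 0), matching the field's "−3(A/G), +4(G)" indexing; windows
truncated by the transcript end are skipped. Normalized distances are
`start / UTR_length` (to TSS) and `(UTR_length − end) / UTR_length` (to
CDS), both in [0, 1]. Gene-level uORF aggregation uses the longest
transcript's 5'UTR, consistent with gene-level quantification.

## Synthetic-data generator

The generator plants known effects so that recovery is checkable:

* **Design**: 2 conditions × 2 replicates, 2,000 genes by default.
* **Counts**: negative binomial with gene-shared dispersion 0.01 and base
  expression log-uniform on [200, 2000] — strong-signal conditions under
  which the two-replicate design has power. Expected RNA counts scale
  with 2^tx_log2fc in the treated condition, RIBO counts with
  2^(tx+tl); per-library depth jitter is available
  (`library_scale_sigma`) but off by default so expectations stay exactly
  proportional.
* **Quadrants**: each gene draws a quadrant (70% E, 5% C/G, 4% B/D/F/H,
  2% A/I) and receives ±2 log₂ effects accordingly — comfortably past
  the |log₂FC| ≥ 1 calling threshold.
* **Footprints**: lengths on 25–35 nt with a fixed pmf peaking at 33;
  regions CDS/3'UTR/5'UTR at 0.80/0.11/0.09; CDS 5' ends on codon starts
  with probability p0 = 0.9, remainder split over frames 1/2. 5'UTR
  background reads avoid planted uORF intervals; each translated uORF
  receives enough dedicated reads to clear the FPKM threshold with a 2×
  margin, untranslated uORFs receive none.
* **Sequences**: A/C/G/T only, no Ns; 5'UTR background is AUG-free by
  construction and verified at build time, so the planted uORF set is
  exactly what a scanner must find. Main-ORF starts carry a planted
  Kozak bias (A/G at −3 with probability 0.85, G at +4 with 0.7); uORF
  starts carry none. Genes are single-exon by default (multi-exon
  optional); strands are random.

What passing these tests shows: the coordinate maps, counting rules,
thresholds and statistics do what they claim under the stated model.
What it does not show: behavior under real-data pathologies — multi-
mapping, 3'-biased coverage, isoform mixtures, overdispersion trends that
vary with expression, contaminating non-RPF fragments, or annotation
errors. The generator has no sequencing-error or alignment-ambiguity
model by design.

## Problem sizes and determinism

Default validation runs use 2,000 genes, 150,000 footprints, 10,000
random UTRs for the scanner oracle, 300 short sequences for the folding
oracle and 1,000 vectors for the BH oracle — sizes at which every check
is stable across seeds while the whole suite stays fast. All randomness
flows through explicit seeds (`SimConfig.seed` and derived streams);
repeated runs are byte-identical.

## Known limitations

* No P-site offsetting or codon-level occupancy; the frame statistic is
  library-level QC only.
* Gene-level only: the longest transcript stands in for the gene; no
  isoform quantification.
* The NB Wald caller with two replicates relies on strong dispersion
  shrinkage; for marginal effects a dedicated DE tool should be plugged
  in through the external-table interface.
* The TE-change chi-square ignores replicate-level variability beyond
  the effect floor; treat borderline calls with caution.
* Nussinov NMFE values are not thermodynamic energies.
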