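# Methods

## Model and assumptions

An intragenic tandem duplication (TD) repeats a block of one or more exons
head-to-tail on the genome. In RNA from such an allele the mature (and, with
total-RNA protocols, the precursor) transcript carries a non-canonical
junction joining the 3′ boundary of the duplicated block to its own 5′
boundary. Against the linear reference a read crossing this junction aligns
uniquely on one side with the remainder soft-clipped. The identical read
signature arises from back-spliced circular RNAs; the discriminating signal
is the mate position, because a circRNA physically confines both reads of a
fragment to the circularised region while a genomic TD does not.

The detector therefore assumes: (i) alignments come from a spliced aligner
that soft-clips junction-crossing reads and marks unique alignments with a
known MAPQ (255 for STAR; configurable); (ii) duplication breakpoints
coincide with annotated exon boundaries at the transcript level, so
candidate regions can be anchored exactly on exon starts/ends of a single
gene; (iii) mate position is usable from the SAM MPOS field, with the mate's
rightmost base inferred as `MPOS + read_length − 1` (the mate's CIGAR is not
required). Reads flagged secondary, supplementary or duplicate are excluded
before any counting.

## Procedure

1. **Candidate regions.** Every uniquely mapped read with a soft clip of at
   least `min_clip` bases whose clip-adjacent mapped coordinate sits exactly
   on an exon boundary proposes regions: for a right clip ending at exon end
   *e*, each exon start *s* < *e* of the same gene whose forward-strand
   sequence exactly matches the clipped bases; symmetrically for left clips.
   No coordinate tolerance is allowed. Candidates are deduplicated by
   (chrom, start, end, gene).
2. **Virtual junction.** K = min(100, region length); the junction sequence
   is the region's last K bases followed by its first K. For regions under
   100 bp the two halves overlap by construction; clips longer than K are
   compared on their junction-proximal K bases only.
3. **Read selection.** Reads overlapping the region with MAPQ equal to the
   unique-mapping value; when more than `read_cap` (4000) qualify, the
   positional first and last 2000 are kept — junction reads sit at the
   termini, so the cap discards only interior coverage.
4. **Verification.** A junction read must end exactly at the region 3′
   terminus (right clip) or start at the 5′ terminus (left clip), with ≥
   `min_clip` clipped bases matching the continuation across the virtual
   junction with zero mismatches.
5. **Mate evaluation.** Four qualifying scenarios: forward junction read
   (flag 99/163) with mate extending past the region end, or reverse
   junction read (83/147) with mate starting before the region start.
   "Partly outside" counts: the mate may overlap the region as long as it
   overhangs it. Read-pairs are deduplicated by query name per region.
6. **Calling and scoring.** A region with ≥ `min_support` (default 1)
   distinct TD read-pairs is called. Identical coordinates reached through
   different genes collapse to one region annotated with all gene ids; the
   TD-score counts distinct called regions.

Reading-frame effect: the summed length of exons with transcription ordinal
inside the duplicated span, modulo 3 (`in_frame` iff 0). A region not
bounded by whole exons reports `NA`. A single duplicated exon of 239 bp is
therefore reported `out_of_frame`; published tables contain one such region
annotated as in-frame, a discrepancy we surface rather than reproduce, since
239 is not a multiple of 3.

## Cohort statistics

Positives are BRCA1-type samples; negatives pool BRCA2-type and HRP
(HR-proficient); unclassified samples are excluded. The classifier calls
BRCA1-type at TD-score ≥ `threshold` (default 2). AUC uses the Mann–Whitney
identity U/(n₁n₂) with ties counted half; the optional 95% CI is a
stratified percentile bootstrap (2000 resamples, seeded) — a package choice,
since no standard method is implied by the quantity itself. Group
comparisons use the Mann–Whitney U test, exact when n₁·n₂ ≤ 400 without
ties, otherwise the normal approximation with tie and continuity
corrections; fully degenerate input (every observation identical) returns
p = 1. Per-gene recurrence: a gene is recurrent when ≥ 2 distinct samples
carry a TD in it (a sample counts once per gene); counts are compared with
the two-sided Fisher exact test on a 2×2 of affected/unaffected by group,
and adjusted across recurrent genes with Hochberg's step-up procedure
(`p_adjusted_hochberg`; Benjamini–Hochberg available via `--adjust bh`).
Fisher, Mann–Whitney and the adjustment are delegated to scipy/statsmodels;
the test suite cross-checks them against independent enumeration oracles
(full margin enumeration for Fisher, rank-split enumeration for MWU,
pair enumeration for AUC, the direct step-up formula for Hochberg).

When reproducing a published recurrence table, the adjustment is applied to
the table's printed (3-decimal) p-values, since that is what the published
adjusted column was computed from; the library pipeline itself keeps full
precision, which can differ in the third decimal (e.g. 0.037 vs 0.034 for
the smallest value here). Group sizes 34 vs 221 were confirmed by
recomputation: all 17 printed nominal p-values match at three decimals only
under n₂ = 221.

## Synthetic data

The simulator emulates what the detector actually consumes: aligner output.
Junction reads are emitted directly as soft-clipped records against the
unmodified reference (e.g. `50M25S` ending at the region's 3′ boundary, the
clip spelling the region's first bases), with mates placed outside the
region for TD pairs, inside for circRNA pairs, and plain 75 bp paired reads
as exonic/intronic background (fragment length 300 ± 50, as for a typical
ribo-depleted library). Outside pairs cycle through all four qualifying
flag scenarios. Default read length is 75 bp and junction-read MAPQ is 255.
Genomes are uniform-random; any reference occurrence of a 10-mer spanning a
possible exon-boundary junction is removed by point mutation (occurrences
overlapping the junction's own one-base flanks are tautological and cannot
support a ≥ 10-base spurious match, so they are exempt). The bundled
PTEN-like gene has nine exons with exons 3–5 of 45, 44 and 239 bp and
introns chosen so the exon 3–5, 4–5 and 5-only duplication spans measure
7739, 2206 and 239 bp.

What the simulator does *not* model: sequencing errors, expression-level
variation, multi-mapping ambiguity, isoform diversity, or chimeric
artefacts of library preparation. Passing tests therefore demonstrate the
correctness of the detection logic under clean alignments — exact recovery
of planted regions and exact exclusion of circRNA configurations — not the
sensitivity/specificity attainable on real tumour RNA-seq, which depends on
depth and library quality.

The cohort simulator draws TD-scores from class-conditional Poisson
distributions (defaults: means 5 / 0.5 / 1 for BRCA1-type / BRCA2-type /
HRP, matching the reported medians of 5 / 0 / 1), and exposes the analytic
tail probabilities of any threshold under those distributions so empirical
classifier performance can be checked against closed-form expectations.

## Numerical and design choices

- Coordinates are 1-based inclusive end to end (GTF and SAM native); no
  conversions anywhere.
- Exons are merged per gene across transcripts into the union of distinct
  intervals, keeping every annotated boundary; ordinals follow genomic
  order, reversed on the minus strand. Where alternative ends make merged
  intervals overlap, ordinals still follow sorted genomic order.
- Detection is strand-agnostic at the genomic level (a TD junction reads
  end→start in forward coordinates regardless of gene strand); strand only
  drives exon numbering and frame arithmetic.
- `min_support` defaults to 1 TD read-pair; the smallest support printed in
  published calls is 2, but the method itself places no floor.
- Samples are held in memory as position-sorted per-chromosome read lists;
  region queries use binary search. This keeps SAM and BAM equivalent and
  the pipeline deterministic; cohort-scale inputs are processed one sample
  at a time.
- Determinism: identical inputs give byte-identical output tables; all
  simulation randomness flows from explicit seeds.

## Problem sizes used in the checks

The acceptance script and test suite run 50 randomized single-gene layouts
(3–7 exons of 60–300 bp, introns 200–1500 bp, 1–6 supporting pairs), 15
circRNA-only decoy layouts, the PTEN-like exemplar with 6 supporting pairs,
and a 500-sample simulated cohort (200/100/200 per class); statistical
oracles enumerate 500 random 2×2 tables (totals ≤ 300) and 100 random
cohorts (≤ 50 samples). These sizes exercise every code path while keeping
the whole suite in seconds.

## Known limitations

- Breakpoints inside introns are not assembled; a TD whose transcript-level
  junction does not coincide with annotated exon boundaries is invisible.
- The mate-outside test infers the mate's extent from its position and the
  read length, not its CIGAR; a spliced mate whose genomic footprint is
  larger behaves conservatively (it can only make an inside mate look
  outside in rare boundary cases).
- The recurrence test treats genes independently; co-occurring TDs across
  genes are not modelled.
- DNA-level validation (matching RNA calls to genomic breakpoints) is out
  of scope.
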