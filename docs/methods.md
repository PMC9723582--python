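# Methods

## The assay and its data

A 16S-ITS amplicon (~1.8–3 kb: full 16S gene, the internally transcribed
spacer, and the start of the 23S) is circularized with a splint and
amplified by rolling-circle polymerization, yielding a linear product of
the form `splint (insert splint) x k`. Nanopore sequencing of this product
gives one long read per molecule in which the same insert is observed k
times. Each insert copy carries the forward unique primer tail, a 5-bp
random molecular barcode, the 27F-derived annealing primer, the 16S-ITS
interior, the reverse annealing primer, a second 5-bp barcode, and the
reverse unique tail. Barcodes are identical across the repeats of one
molecule, which is what lets a mixed or chimeric concatemer be recognized.

The pipeline's unit of analysis is the per-read consensus ("RoC-ITS
sequence"): single-pass error (~2%, indel-rich) is uncorrelated across
repeats, so a plurality consensus over k ≥ 5 aligned sub-reads reduces the
error by more than an order of magnitude.

## Alignment engine

All pairwise alignment is unit-cost edit-distance alignment (edlib):
global (`NW`) for near-identical full-length sequences, infix (`HW`) for
locating the splint on a read and for cd-hit-style identity in which the
overhang of the longer sequence is not charged, and prefix (`SHW`) for the
chimera breakpoint score arrays. For sequences at ≥90% identity the
unit-cost optimum is, in practice, the same alignment an affine-gap scorer
would produce, and the bit-parallel implementation makes whole-pipeline
runs on hundreds of multi-kilobase reads take seconds.

Multiple alignments use a center-star construction: every sequence is
globally aligned to the median-length input (ties broken on sequence
content, making the result invariant to input order) and the pairwise
alignments are merged under "once a gap, always a gap". This is adequate
because every MSA in the pipeline is over near-identical sequences —
sub-reads of one molecule, or consensus sequences of one genus. Genus MSAs
additionally get a local repair pass: windows whose columns disagree beyond
20% and contain gaps are re-aligned against the window's own plurality
sequence, ironing out inconsistent gap placement between rows.

## Stage parameters

| stage | parameter | default | meaning |
|---|---|---|---|
| segment | `junction_max_error` | 0.35 | max edits/splint-length for a splint hit; tolerant because splint copies accumulate ~2% noise and partial end copies still anchor junctions |
| segment | `min_sub_len`/`max_sub_len` | 1500/3500 bp | valid sub-read size window (barcode- and primer-clipped) |
| segment | `barcode_consensus_cutoff` | 0.6 | per-column plurality needed to call a barcode base; below it the column is kept as an ambiguous N |
| consensus | `outlier_score_fraction` | 0.65 | sub-read kept iff its column score ≥ 0.65 × alignment width |
| consensus | `min_final_subreads` | 5 | support floor for a usable consensus |
| consensus | `stop_at_subreads` | 3 | pruning stops when this few rows remain |
| cluster | `genus_identity` | 0.95 | greedy 16S clustering threshold (≈ genus) |
| cluster | `min_cluster_members` | 5 | genus clusters below this are excluded |
| refine | `dominant_fraction` | 0.98 | column dominance needed to correct minorities |
| refine | `minority_to_N_fraction` | 0.02 | characters under this frequency in polymorphic columns are masked to N |
| refine | `max_correction_fraction` | 0.0005 | exclusion budget: > 0.05% × ungapped length prospective corrections |
| refine | `trim_nongap_fraction` | 0.98 | first/last columns at ≥98% non-gap bound the trimmed MSA |
| resolve | `variable_majority_fraction` | 0.95 | columns whose majority is under this are "variable" |
| resolve | `flank_columns` | 4 | context columns kept on each side of a variable column |
| resolve | `min_cluster_input_fraction` | 0.05 | sub-sequence clusters under 5% of input dropped as putative chimeras (`rescue_min_members` overrides for low-abundance isolates) |
| resolve | chimera margin | 4 edits and 1.5% | two-parent model must beat the best single parent by both margins |

## Procedure notes and tie-breaks

- **Column consensus.** Plurality over {A,C,G,T,N,-}; ties prefer a base
  over a gap (favoring sequence retention), then A<C<G<T<N. The sub-read
  score is 1 per agreeing column, 0.5 where the sub-read is gapped under a
  consensus base, 0 otherwise; scoring and removal iterate, and the MSA is
  rebuilt from the survivors after each round because removing a divergent
  row can shift columns.
- **Barcode consensus.** Observations (one exact-offset 5-mer per repeat)
  are multiply aligned; per column the plurality character is taken:
  gap-plurality columns are dropped, confident bases emitted, below-cutoff
  columns kept as N. A consensus longer than 5 bases means the repeats mix
  barcodes from different molecules and the read is discarded. Barcode
  fields are cut at their exact expected offsets rather than with slack:
  the flanking construct bases are identical in every repeat, so any slack
  would be confidently called into the consensus and push every read over
  the length limit. A known blind spot: two same-length barcode sets whose
  alignment does not stagger yield an all-N length-5 consensus and pass the
  length rule; in practice indel noise staggers genuinely mixed reads.
- **Two-pass correction.** Pass 1 only counts prospective corrections per
  sequence and excludes those over the 0.05%×length budget (large-indel and
  chimeric artifacts); pass 2 recomputes column statistics on the survivors
  and applies corrections, so excluded outliers never influence the final
  result. Gap characters participate in column tallies exactly like bases
  (a dominant gap can overwrite a minority base); N never counts as
  dominant and is never itself corrected. The correction budget is measured
  against the ungapped sequence length. Applying the procedure to its own
  output produces zero further corrections.
- **Identity sweep.** Sub-sequence identity is computed column-wise on the
  already-aligned windows (Hamming over characters including gaps, N
  wildcard) — the windows are MSA slices, and re-aligning 9-column strings
  would erase exactly the signal being measured. Gap-only differences
  between clusters are preserved: operon copies distinct by a single-base
  deletion stay distinct. When a target cluster count is supplied the call
  uses the lowest identity achieving it; unsupervised runs report the modal
  count across the ladder, while genome-structure summaries read the count
  held at the top of the ladder (0.995), where corrected data plateaus at
  the true copy number.
- **Chimera model.** Best two-parent score = min over breakpoints of
  (prefix edit distance to any reference's prefixes) + (suffix distance to
  any reference's suffixes), evaluated on a 25-bp grid and refined to
  single-base resolution around the optimum. The margin rule (≥4 edits and
  ≥1.5% of the candidate length saved versus the best single parent) makes
  near-end breakpoints undetectable in principle — a 20-bp swapped tail is
  within the margin for any method — so screening performance is evaluated
  on chimeras whose breakpoints leave each parent ≥10% of the insert.

## The simulator

`rocits.simulate` generates the study conditions end to end: synthetic
16S-ITS templates carrying concrete instances of the conserved 27F, 1492R,
and V4 (515F/806R) primer sites at their biological positions; multi-copy
rrn sets diverging by single SNPs up to tRNA-sized (80–100 bp) ITS
insertions; communities with abundance weights spread over orders of
magnitude, sampled proportional to weight × rrn copy number; concatemer
geometry with per-read repeat counts k ~ k_min − 1 + Geometric(p = 0.25),
so short reads dominate and the ≥5-sub-read filter is the main loss, as in
real runs; an error process with 2% total rate split 40/30/30 between
mismatches, insertions, and deletions, an optional homopolymer indel
multiplier, and per-read rate jitter (relative SD 0.5) giving sub-read
identities of 98% ± 1%; and single-breakpoint template-swap chimeras at a
configurable rate. Every read is paired with a truth row (template, repeat
count, barcodes, strand, chimera breakpoint, and splint coordinates mapped
through the error process), and fixed seeds give byte-identical output.

Two bundled template sets encode the rrn structure of well-characterized
genomes on synthetic sequence: `ecoli_like_rrn_set` (7 pairwise-distinct
operons, one with a tRNA-sized ITS insertion) and `bacillus_like_rrn_set`
(10 operons named A–J with 9 distinct sequences: F and G identical, I equal
to F minus a 2-bp deletion). They are synthetic stand-ins, not genomic
sequence; what passing tests show is that the pipeline recovers a known
copy-number structure from reads, not anything about the real genomes.

What the simulator does *not* emulate: sequence composition of real rRNA
(templates are random DNA between conserved sites, so inter-taxon identity
is far lower than the ~80–90% of real genera, making genus clustering
easier than in real data), signal-level artifacts, quality-score structure,
context-dependent error beyond homopolymer enrichment, and PCR-cycle
amplification bias. Results on simulated communities therefore bound the
pipeline's mechanics, not its field performance.

## Problem sizes

Simulation-backed tests and the acceptance script run at desk scale chosen
to keep the full suite in the low minutes on one CPU while leaving
comfortable statistical margins: 140–200 reads per genome run (k ≥ 5,
giving ~135–190 usable consensus sequences, i.e. ≥11 per rrn copy), 100–200
replicates for per-read properties, and 40+40 candidates for the chimera
screen. The bundled community benchmark table (8 genera) is input data, not
simulation.

## Known limitations

- Greedy clustering depends on input order (mitigated by length-descending
  canonical order) and the k-mer prefilter assumes ≥30%×identity shared
  12-mers, which holds for amplicons but not for heavily truncated input.
- The center-star MSA is built against a single center; for clusters with
  deep splits (well under 90% identity) a guide-tree aligner would place
  gaps better. Such inputs do not arise after the genus-level 95% cut.
- Within-genome chimeras (parents ≥99% identical) fall inside the chimera
  margin rule and are only caught by the small-cluster exclusion, mirroring
  the method's design.
- `trim_msa`'s optional end-motif masking assumes primer remnants survive
  at ≥50% of rows; the default pipeline relies on the non-gap rule alone.
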