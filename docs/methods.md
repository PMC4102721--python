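# Methods

## Problem and model

An allopolyploid (amphidiploid, AACC) genome carries two homoeologous
copies of every region, diverged by a few percent. Building a BAC contig
for one such region therefore requires markers that both *find*
homoeologous clones and *tell the two subgenome copies apart*.
Intergenomic SNPs — positions where the A and C (sub)genomes carry
different nucleotides — do both: in a two-colour genotyping assay the two
assay nucleotides report the two subgenomes as opposite ends of the
allele-frequency axis.

The package models the complete screening workflow:

1. **Assay-site discovery.** Alignment blocks between progenitor
   sequences are filtered for suitability (length >= 500 bp, identity
   >= 95%, no off-target hit >= 150 bp at >= 90% identity outside the
   target region). Within a pairwise alignment, a substitution column is
   an assay candidate when its flanks are identical over at least 20
   bases, at most one further mismatch occurs within 25 bases and only
   beyond the 15-base clearance, no gap falls inside the 25-base
   oligonucleotide footprint, and a 60-base window is extractable on
   each side. A designability surrogate (1 minus the fraction of window
   bases in homopolymer runs >= 6 or in a 21-base neighbourhood with GC
   outside [0.25, 0.75]) must exceed 0.6; it replaces a proprietary
   vendor score and is a pluggable hook, not a reimplementation of it.
   Survey-sequence contigs are assembled conservatively: any column on
   which overlapping reads disagree is masked and never hosts a site or
   counts toward flank identity.

2. **Pool calling.** Each of the 82,944 library coordinates belongs to
   exactly one pool in each of seven screening dimensions. Per (pool,
   assay), vendor-style normalised signals are thresholded: R < 0.2 is
   negative; otherwise Theta <= 0.05 calls nucleotide 1, Theta >= 0.95
   nucleotide 2, and intermediate values mean the pool contains clones
   of both nucleotides. All thresholds are inclusive.

3. **Deconvolution.** A coordinate is reported for nucleotide k iff all
   seven of its pools are positive for k, where "both" pools count for
   either nucleotide (a pool holding clones of both subgenomes shows
   both fluorophores; any stricter rule would discard true
   coordinates). Coordinates decoded for both nucleotides are emitted
   once with class "both" and treated downstream as unassignable. The
   production decoder intersects per-dimension candidate sets on a
   precomputed membership matrix; an exhaustive per-coordinate scan that
   recomputes each coordinate's pools arithmetically is kept as the
   definitional oracle and compared in tests at full library size.
   Group testing with ~10 positives per nucleotide in this design
   necessarily produces *shadow* coordinates (false positives whose
   seven pools are covered by the union of true positives); they are the
   reason the selection and validation stages exist, and their count is
   reported rather than suppressed.

4. **Subgenome assignment.** Reference-panel evidence (two accessions
   plus a WGS source per progenitor, a survey-sequence source for the
   C progenitor, and the amphidiploid genotyping call and amplicon
   sequence) classifies each assay: category 1 (both sides concordant),
   2 (one side concordant — that side fixes both assignments), 3
   (neither side concordant), 4 (only one nucleotide detected in the
   amphidiploid), 5 (site monomorphic in the amphidiploid — never
   assigned, because such assays sweep up clones of both subgenomes).
   Heterozygous and missing evidence values are non-informative and
   never contradict. Categories 3 and 4 are resolved by majority vote
   over the subgenome labels of clones co-identified by category-1/2
   markers; the quorum (fraction >= 0.8 over >= 3 labelled clones) is a
   package choice exposed as configuration — the source procedure is
   described only qualitatively. Clones then receive the consensus
   subgenome of their category-1..4 scores; mixed implications are
   reported, never silently resolved.

5. **Selection, validation, contigs.** Clones are selected when scored
   by >= 4 assays (ignoring assays with > 3000 hits), or by two markers
   with >= 2 intervening markers, or by the whole block of 3 markers at
   a region end ("two or three markers at the very ends" is resolved as
   an `end_marker_count` parameter, default 3, and the block must be
   complete — a looser reading floods the selection with single-assay
   shadows). Validation tests every score of a selected clone against a
   per-clone oracle standing in for PCR-amplicon analysis; untestable
   amplicons (subgenome-specific, like a C-genome-specific amplicon
   that cannot confirm A-genome scores) are excluded from the
   false-positive denominator. Contigs are connected components under
   the shared-confirmed-marker relation — marker content is the only
   overlap evidence used; fingerprint-style overlap is out of scope.
   Refinement runs to a fixed point per clone: interior markers of the
   confirmed interval first, then stepwise end extension; every
   recovered presence is a false-negative score of the screen. The
   iteration terminates because the confirmed interval grows
   monotonically within a finite marker list. Bridging examines
   unselected putative clones scored within a 3-marker window of any
   contig end (gap-facing or outer); a confirmed clone sharing markers
   with two contigs merges them, one sharing markers with one contig
   extends it. Marker-order conflicts are reported, never
   auto-corrected.

## Synthetic data

The generator's defaults emulate the study conditions: ~1 Mbp progenitor
regions at 3.7% substitution divergence plus geometric indels (mean 3 bp
at rate 5e-4), giving a realised alignment identity near 96%;
accession-level SNP rates drawn uniformly from 0.82–1.98% per subgenome;
a 216-plate 16x24 library (82,944 coordinates, one clone per well) with
Normal(142.5 kbp, 15 kbp) inserts truncated at 20 kbp and the genome
length rescaled so realised coverage is 10x; 52 assays placed evenly on
clean intergenomic SNP sites and then given the category mix
(0.44, 0.25, 0.12, 0.13, 0.06) — category 2/3 pathologies live in the
evidence panel, category 4 receives an interfering substitution inside
one subgenome's footprint, category 5 sites are made monomorphic; and a
seven-dimension design of the three base-6 plate digits, row, column,
a diagonal (plate + well) mod 23 and one pool per plate. Noise defaults:
2% pool dropout, 0.5% nucleotide flip, Theta jitter sd 0.01, residual
intensity Normal(0.05, 0.03) clipped at zero, positive intensity
Normal(0.6, 0.15) truncated at the 0.2 threshold — sub-threshold
positives are modelled exclusively by the dropout probability, so the
configured rate is exact. All randomness flows from one seed through
per-stage substreams.

Only the two homoeologous regions are represented at sequence level; the
background genome hosting off-target clones is coordinate-only, since
decoding, validation and contig logic depend on interval/marker overlap
alone. The regions sit on their own "chromosomes" with one-insert
margins, so clones never straddle region and unrelated background.

What the generator does *not* emulate: the triplicated paleopolyploid
structure of real Brassica genomes, chromosome-scale context, empty or
cross-contaminated wells (available as options, default zero, no rates
are published), sequencing reads, or the composition of the original
pooling scheme (unpublished; the default design preserves only the
seven-dimension partition contract that the decoder relies on). Passing
tests therefore demonstrate the logic of calling, decoding, assignment
and contig building under realistic group-testing load — not performance
on real Brassica data, where repeat structure and assay chemistry add
failure modes the simulator does not model.

## Numerical and design choices

- Thresholds are inclusive exactly as printed; classification is a total
  function partitioning the (R, Theta) half-plane (property-tested).
- Coordinates are 0-based half-open internally; 1-based only in rendered
  reports. Percent rendering uses round-half-up (9.11 -> 9.1,
  72.03 -> 72); raw ratios are kept alongside.
- Clone ordering inside a contig breaks ties by leftmost marker, then
  rightmost marker, then clone index.
- The dropout false-negative expectation is 1 − ((1−d)(1−f))^7; it
  treats every flip as a loss and is therefore an upper bound — flips of
  pools containing both nucleotides are harmless, which is visible as
  the simulated fraction running a few points below the bound when flip
  noise is on.
- The subgenome-conflict estimate is a Monte-Carlo replay of the noise
  process on the ideal pool-call truth, decoded with the true
  nucleotide-to-subgenome maps. It shares the decoder with the pipeline
  but bypasses signal synthesis, evidence classification, inference and
  selection, so agreement between the two routes checks the whole
  assignment chain.
- Degenerate inputs: empty libraries, empty call tables and empty HSP
  lists yield empty outputs, not errors; zero-length regions,
  non-partitioning pool dimensions, inconsistent read overlaps, unknown
  pool/clone/assay ids and non-finite signals raise with a located
  message.

## Known limitations

- Noiseless end-to-end tiling recall is ~0.99, not 1.0: clones covered
  only by category-4-undetectable or promiscuous category-5 markers are
  reachable by no selection criterion; the source screen reports the
  same escape behaviour for its own loci.
- Real screens would feed vendor-normalised signals and tabular
  alignment hits into the same entry points; the simulator's alignment
  truth stands in for an external aligner, whose parameters are
  metadata here.
- Category-3/4 inference needs enough co-identified labelled clones; at
  very low coverage or tiny libraries it returns "unassigned" rather
  than guessing.
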