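# Methods

## Problem setting

Multiplexed CRISPR/Cas9 mutagenesis of a panel of tumor-suppressor genes
(TSGs) in mouse liver produces tumors whose cells carry heterogeneous
mixtures of small indel alleles at each target site. Two observations
drive the analyses this package implements: (i) the type and frequency of
targeted mutations *oscillate* between a parental single-cell clone and
its subclones, across time points, and in grafts, without ongoing editing;
and (ii) the cells generate small extrachromosomal circular DNA (eccDNA),
some of which carries target-site alleles — a plausible vehicle for the
oscillation. The package quantifies editing outcomes from targeted
amplicon deep sequencing, tracks allele oscillation across related
samples, and detects eccDNA circularization junctions from
rolling-circle-amplified (RCA) libraries, with a synthetic-data layer that
generates all inputs with known ground truth.

## Coordinates and the cut convention

All internal coordinates are 0-based, half-open; `cut_pos` is an
inter-base coordinate. SpCas9 with an NGG PAM is modelled as cutting
bluntly 3 bp 5' of the PAM on the protospacer strand, i.e. between
protospacer bases 17 and 18 (1-based). For minus-strand targets the cut
maps to plus-strand coordinate `protospacer_start + 3`. Every target site
is validated against the reference (protospacer identity on the stated
strand, NGG PAM immediately 3', cut strictly inside the protospacer
footprint) at load time. All allele labels for minus-strand targets are
reported in protospacer-strand orientation, so "left of the break" always
means 5' on the protospacer strand.

## Allele classification

Outcomes are named `Del a|b` (a bases deleted 5' and b bases 3' of the
break), `Ins n seq` (n-bp insertion at the break), their combination, or
`WT`. Classification of a read proceeds in three stages:

1. **Alignment.** Global alignment against the local amplicon
   (protospacer-strand oriented, default 240 bp around the cut) with
   affine gap scores: match +2, mismatch −4, gap open −10, gap extend −1
   (a k-bp gap scores −10 − k). Reference end gaps are free so a read may
   cover part of the amplicon. Reads scoring below 0.4 × 2 × read length
   are discarded (`poor_alignment`); reads whose alignment does not span
   the full classification window (default ±25 bp around the cut,
   covering the longest expected deletion with margin) are discarded
   (`incomplete_window`). Both orientations are tried and the better
   score wins.
2. **Window decomposition.** The optimal affine path is not a reliable
   event description: a combined deletion+insertion is often spelled as
   two short gaps with mismatches between them. The edit inside the
   window is therefore re-derived: exact matching is extended inward from
   both window edges, absorbing an isolated substitution only when the
   next 8 bases re-anchor exactly (so extension stops at any
   length-changing edit but not at sequencing errors); whatever remains
   is one deleted-interval / inserted-string event. If the alignment
   shows two indel clusters separated by ≥ 8 reference bases, the read is
   discarded as `complex` rather than given a guessed composite label.
3. **Reduction and canonical placement.** The event is reduced to minimal
   form: shared bases between the deleted and inserted strings are
   trimmed (again tolerantly); an unequal-length leftover that equals one
   pure indel plus at most one substitution is represented that way (a
   sequencing error abutting an indel, not a compound allele); an
   equal-length leftover is a substitution run, counted as unedited with
   a substitution flag. Pure indels inside repeats have several
   score-equivalent placements; the placement closest to the cut wins and
   residual ties go to the leftmost (5') placement. `canonical_label()`
   applies the same reduction to any (a, b, seq) recipe, so ground-truth
   labels and classifier output are always compared in the same canonical
   form — note that a repeat-shiftable edit such as a 22|5 deletion next
   to a 1-bp repeat may legitimately canonicalise to 23|4.

Substitution-only reads count as unedited in all frequency math (the
spectra report indel classes only); the flag is retained for QC.
Discarded reads are excluded from numerator and denominator everywhere.

## Frequency tables and thresholds

Per sample and target: allelic frequency = label count / retained reads ×
100; gene mutation frequency = 100 − WT frequency. A non-WT allele is a
*true mutation* when its frequency is ≥ 5% (inclusive) — the noise filter
that keeps substitution/alignment artifacts out of the tables. Sites with
fewer than 100 retained reads (configurable) are no-calls rather than 0%.
Library-size normalisation expresses each target's reads as a percentage
of its library's combined target reads; the eccDNA/gDNA *relative read
ratio* divides the eccDNA percentage by the gDNA percentage per target
(undefined when the gDNA side is zero or invalid), which cancels
per-target PCR efficiency since both libraries share primer pairs. Sites
drawing < 0.1% (strict) of a library's reads are flagged invalid.

## Lineage comparison

Allele tables across related samples are joined into a (gene, allele) ×
sample percentage matrix (union of labels, zeros filled). An allele is
*present* at ≥ τ (τ = 5%, the same threshold as the true-mutation rule; a
hysteresis band is available but defaults to 0). Gain/loss events between
a parent and child are threshold crossings in either direction, WT
participating like any allele; time courses are compared consecutively.
Allelic richness is the number of present alleles (WT included) per gene
and sample; richness > 2 in a single-cell clone flags more copies of the
locus than a diploid genotype explains. No statistical test is attached —
events are reported descriptively, as in the source analyses. The √
frequency transform is provided for rendering (it keeps minor alleles
visible next to dominant ones).

## eccDNA junction detection

A circle formed from reference interval [start, end) is evidenced by
reads in which sequence ending at `end` continues with sequence starting
at `start` (suffix→prefix, same chromosome and strand; translocation- or
inversion-joined circles are out of scope). Reads are located by exact
20-mer seeding (k-mers unique in the reference) with mismatch-tolerant
extension, giving a segmentation of each read; a backward jump between
consecutive segments is a junction candidate. The exact junction column
is re-derived by a two-anchor sweep minimising mismatches, so a
sequencing error at the seam does not shift the breakpoints. Candidates
are canonicalised under microhomology and clustered exactly by coordinate
pair; clusters with ≥ 2 supporting reads (distinct reads; configurable)
become circles. Junctions spanning < 100 bp are treated as ordinary
indels, not circles. Junction reads with fewer than ~20 bp on one side of
the seam cannot be anchored and do not contribute support — at realistic
depths this does not prevent recovery (measured 100% of circles with ≥ 4
junction-spanning reads under the default simulation conditions, with
zero false calls on junction-free libraries).

**Microhomology.** When the bases entering the circle at one boundary
equal the bases leaving it at the other, placements (start+s, end+s)
describe the same circular sequence and the junction coordinate is
ambiguous within the homology length. Microhomology is defined as exactly
this shift-equivalence; the canonical placement is the leftmost shift,
`mh_len` is the shift range measured from it (capped at 20 bp for
degenerate homopolymer junctions), and all support clustering happens
after canonicalisation. Simulated circles with nominal `mh_len = 0` can
still carry natural microhomology from the random reference, so recovery
is always judged at canonical coordinates.

**Characterisation.** Circle size is end − start (the median of an even
set is the lower middle value, so reported medians are observed sizes).
Distances from a Cas9 cut to the two junction points are reported as
proximal/distal with log10 values for distances ≥ 1 bp; when the cut lies
inside the circle they sum to the circle size. Genic annotation follows
the circle midpoint with priority promoter > 5'UTR > exon > 3'UTR >
intron, else "distal intergenic" (an any-overlap variant would be a small
code change; midpoint is the documented default). Target sites inside a
circle are genotyped by classifying the library reads that span the
site's window and reporting the modal retained label ("uncalled" if
uncovered). Sanger-style junction clones are aligned to a doubled copy of
the circle's reference sequence so both the junction and the target
window are interior, and both loci are labelled with the same allele
grammar ("WT" at the junction means the ends joined accurately).

## Synthetic data

The generators define the study conditions and produce byte-identical
output under a fixed seed (one explicitly passed NumPy generator, no
global state):

* **Amplicon reads** are drawn multinomially from a specified allele
  mixture; each read is a window-spanning substring of the mutated
  amplicon with uniform substitution errors (default 0.3%, an
  Illumina-like rate; indel errors are off by default so ground truth
  stays unambiguous). Qualities are constant Q30-equivalent and never
  used. The published p53 spectrum (41.88 / 28.12 / 16.13 / 13.87%) is
  the reference mixture for recovery checks at depth 50,000.
* **Lineages** derive subclones from a parent by per-allele loss
  (probability p_loss, drawn conditioned on one allele surviving — a
  clone always retains a genotype; forced events bypass the guard and may
  raise), gain of a dormant allele to a uniform frequency in [0.15,
  0.35], truncated Gaussian drift (σ = 0.01), and renormalisation, with
  every event logged. The generative model is a stand-in: the source
  analyses infer events from data and state no mechanism, so event
  probabilities are not literature-derived. Recovery tests enforce a ±1
  percentage-point guard band around the 5% threshold, because threshold
  crossings caused by drift alone are not well-defined events.
* **eccDNA libraries** concatemerise each circle (≥ 3 tandem copies, as
  RCA does), fragment uniformly (default 300 bp fragments, 150 bp
  paired-end reads, 60 fragments per circle copy), and record which reads
  span a tandem-copy boundary; requested microhomology is engineered into
  the reference by copying the start-side bases over the end-side flank
  and breaking accidental equivalence one base beyond each side. Circle
  sizes follow the observed small-eccDNA range (150–10,000 bp,
  log-uniform for background circles).

What the generators do not emulate — RCA chimeras, PCR duplicates,
quality-score structure, indel sequencing errors (except as an option),
real mouse genome context, mappability and repeat families — bounds what
green tests show: the pipeline is correct on clean-to-moderately-noisy
data of the stated error model, not validated against genome-scale
repeat structure.

## Problem sizes and numerical choices

Default test and acceptance runs use: 50,000 reads for frequency
recovery; 5,525 exhaustive single-indel edits (all deletions with a+b ≤
10, all insertions ≤ 6 bp) against an independent placement-enumeration
oracle; 8 subclones × 30 genes × 3 alleles for oscillation recovery; and
50 circles (10 carrying target alleles) for circle recovery — sizes
chosen to keep the full suite around a minute on one CPU while leaving
every statistical check at ≥ 3-SE resolution. Classification is memoised
on read sequence (amplicon read sets are highly redundant). Tie-breaks
are deterministic everywhere: cut-proximal then leftmost for indel
placement, leftmost for microhomology, smallest junction column in the
two-anchor sweep, label-lexicographic for modal-allele votes.

## Known limitations

* Only simple same-strand circles are called; inverted or
  translocation-joined junctions are ignored by design.
* The `Del a|b` label for a deletion that does not touch the cut loses
  its offset (it reads like a cut-anchored deletion of the same split);
  within the ±25 bp window and Cas9-induced edits this is the intended
  cut-anchored naming.
* Junction reads with < 20 bp on one side of the seam are invisible to
  the seed-based caller; support counts are therefore conservative.
* The eccDNA/gDNA relative read ratio assumes both libraries share the
  per-target amplification; the simulator does not model PCR efficiency
  differences, so this normalisation is exercised but not stress-tested.
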