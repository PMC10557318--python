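"""eccDNA circularization-junction detection and circle characterisation.

A circle formed from reference interval ``[start, end)`` leaves a
diagnostic signature in its reads: sequence at the high coordinate (the
circle's distal end) continues directly into sequence at the low
coordinate.  Reads are located on the (few-kb, synthetic) reference by
exact k-mer seeding with mismatch-tolerant extension; a backward jump
between consecutive read segments is a junction candidate.  Short
microhomology shared by the two joined ends makes the exact junction
coordinate ambiguous within the homology length, so every candidate is
canonicalised to its leftmost shift-equivalent placement before support
clustering.  Only same-chromosome, same-strand suffix->prefix joins are
called (simple circles).
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import (
    AlleleCall,
    CATEGORY_DISCARD,
    _classify_oriented,
    align_read,
    make_aligner,
)
from .reference import ANNOTATION_CATEGORIES, Reference, TargetSite, revcomp

log = logging.getLogger(__name__)

DEFAULT_MIN_SEG = 20
DEFAULT_MIN_SUPPORT = 2
#: junctions spanning less than this are treated as ordinary indels
DEFAULT_MIN_CIRCLE_SIZE = 100
MAX_MICROHOMOLOGY = 20


@dataclass
class CircleRecord:
    """One detected eccDNA circle."""

    circle_id: str
    chrom: str
    start: int
    end: int
    support: int
    mh_len: int = 0
    mh_seq: str = ""
    target_hits: list = field(default_factory=list)  # (gene_id, label)
    annotation: str | None = None

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class JunctionDistance:
    gene_id: str
    circle_id: str
    dist_proximal: int
    dist_distal: int
    log10_proximal: float | None
    log10_distal: float | None


# ---------------------------------------------------------------------------
# microhomology canonicalisation
# ---------------------------------------------------------------------------

def microhomology_at_junction(ref_seq: str, start: int, end: int,
                              max_mh: int = MAX_MICROHOMOLOGY):
    """Canonicalise a junction under microhomology shift-equivalence.

    Placements ``(start+s, end+s)`` describe the same circular sequence
    whenever the bases entering the circle at one boundary equal the bases
    leaving it at the other; the canonical placement is the leftmost shift
    and the microhomology is the shared k-mer governing the ambiguity.
    Returns ``(mh_len, mh_seq, canonical_start, canonical_end)``; shifts
    are capped at ``max_mh`` with a warning for degenerate (homopolymer)
    junctions.
    """
    s, e = start, end
    left = 0
    while left < max_mh and s > 0 and ref_seq[s - 1] == ref_seq[e - 1]:
        s, e = s - 1, e - 1
        left += 1
    c_start, c_end = s, e
    # the homology length is the full shift range measured from the
    # canonical placement (the left walk only locates that placement)
    mh_len = 0
    while mh_len < max_mh and c_end + mh_len < len(ref_seq) \
            and ref_seq[c_start + mh_len] == ref_seq[c_end + mh_len]:
        mh_len += 1
    if mh_len >= max_mh or left >= max_mh:
        log.warning("microhomology at %d-%d capped at %d bp", start, end, max_mh)
        mh_len = max_mh
    mh_seq = ref_seq[c_start : c_start + mh_len]
    return mh_len, mh_seq, c_start, c_end


def reads_from_sam(path):
    """Yield ``(read_id, sequence)`` from a SAM/BAM file (external mapper).

    Sequences of reverse-strand alignments are flipped back to the
    original read orientation; junction detection scans both orientations
    anyway, so only the raw sequence matters.  Unmapped reads are kept.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary or rec.query_sequence is None:
                continue
            seq = rec.query_sequence
            if rec.is_reverse:
                seq = revcomp(seq)
            yield rec.query_name, seq


# ---------------------------------------------------------------------------
# read segmentation on the reference
# ---------------------------------------------------------------------------

def build_seed_index(ref: Reference, k: int = DEFAULT_MIN_SEG):
    """k-mer -> (chrom, pos) for k-mers unique within the whole reference."""
    index: dict[str, tuple] = {}
    dupes: set[str] = set()
    for chrom, seq in ref.sequences.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if kmer in dupes:
                continue
            if kmer in index:
                del index[kmer]
                dupes.add(kmer)
            else:
                index[kmer] = (chrom, i)
    return index


def _extend(read: str, seq: str, i: int, p: int, lookahead: int = 8) -> tuple[int, int]:
    """Extend a match from (read[i], seq[p]) tolerating isolated mismatches.

    Returns (read_end, ref_end) exclusive.  A mismatch is absorbed only if
    the next ``lookahead`` bases realign exactly, so extension stops at
    indels and at circularization junctions rather than at sequencing
    errors.
    """
    L, M = len(read), len(seq)
    while i < L and p < M:
        if read[i] == seq[p]:
            i += 1
            p += 1
            continue
        la = min(lookahead, L - i - 1, M - p - 1)
        if la > 0 and read[i + 1 : i + 1 + la] == seq[p + 1 : p + 1 + la]:
            i += 1
            p += 1
            continue
        break
    return i, p


def segment_read(read: str, ref: Reference, index, k: int = DEFAULT_MIN_SEG):
    """Greedy left-to-right decomposition of a read into reference segments.

    Returns ``[(read_start, read_end, chrom, ref_start, ref_end), ...]``.
    """
    segs = []
    i = 0
    L = len(read)
    while i + k <= L:
        hit = index.get(read[i : i + k])
        if hit is None:
            i += 1
            continue
        chrom, pos = hit
        j, q = _extend(read, ref.sequences[chrom], i, pos)
        segs.append((i, j, chrom, pos, q))
        i = j if j > i else i + 1
    return segs


def _junction_candidates(segs, read: str, ref: Reference, min_size: int,
                         slack: int = 8):
    """Backward jumps between consecutive same-chromosome segments.

    The exact junction column is re-derived by a two-anchor sweep: with the
    upstream segment anchored at (i1 -> p1) and the downstream one at
    (i2 -> p2), every candidate column b splits the read into a prefix
    explained from p1 and a suffix explained from p2; the b minimising
    mismatches wins (ties to the smallest b; microhomology ambiguity is
    resolved later by canonicalisation).  This keeps a sequencing error
    next to the seam from shifting both breakpoint coordinates.
    """
    out = []
    for (i1, j1, c1, p1, q1), (i2, j2, c2, p2, q2) in zip(segs, segs[1:]):
        if c1 != c2:
            continue
        if p2 - (i2 - j1) >= q1 - 2:  # forward jump: indel, not a junction
            continue
        seq = ref.sequences[c1]
        lo_b = max(i1 + 1, j1 - slack)
        hi_b = min(j2 - 1, i2 + slack)
        best = None
        for b in range(lo_b, hi_b + 1):
            end = p1 + (b - i1)
            start = p2 - (i2 - b)
            if start < 0 or end > len(seq):
                continue
            mm = 0
            for x in range(lo_b - 1, hi_b + 1):
                if x < b:
                    y = p1 + (x - i1)
                else:
                    y = p2 - (i2 - x)
                if not (0 <= y < len(seq)) or read[x] != seq[y]:
                    mm += 1
            if best is None or mm < best[0]:
                best = (mm, start, end)
        if best is None:
            continue
        _, start, end = best
        if start < 0 or end - start < min_size:
            continue  # collinear continuation, small indel, or noise
        out.append((c1, start, end))
    return out


def detect_junctions(
    reads,
    ref: Reference,
    min_seg: int = DEFAULT_MIN_SEG,
    min_support: int = DEFAULT_MIN_SUPPORT,
    min_size: int = DEFAULT_MIN_CIRCLE_SIZE,
    index=None,
) -> list[CircleRecord]:
    """Call circles from junction-spanning reads.

    ``reads`` is an iterable of ``(read_id, sequence)`` pairs (or objects
    with ``read_id``/``seq`` attributes).  Both read orientations are
    scanned; candidates are canonicalised under microhomology and clustered
    exactly by coordinate pair; clusters with support >= ``min_support``
    are emitted sorted by coordinate.  Support counts distinct reads.
    """
    index = index if index is not None else build_seed_index(ref, min_seg)
    support: dict[tuple, set] = defaultdict(set)
    mh_info: dict[tuple, tuple] = {}
    n_scanned = n_junction_reads = 0
    for item in reads:
        if hasattr(item, "seq"):
            rid, seq = item.read_id, item.seq
        else:
            rid, seq = item
        n_scanned += 1
        found = set()
        for oriented in (seq, revcomp(seq)):
            for chrom, start, end in _junction_candidates(
                segment_read(oriented, ref, index, min_seg), oriented, ref, min_size
            ):
                mh_len, mh_seq, cs, ce = microhomology_at_junction(
                    ref.sequences[chrom], start, end
                )
                key = (chrom, cs, ce)
                found.add(key)
                mh_info[key] = (mh_len, mh_seq)
        for key in found:
            support[key].add(rid)
        n_junction_reads += bool(found)
    log.info("scanned %d reads, %d junction-spanning", n_scanned, n_junction_reads)

    records = []
    for n, (chrom, cs, ce) in enumerate(sorted(support, key=lambda t: (t[0], t[1], t[2]))):
        if len(support[(chrom, cs, ce)]) < min_support:
            continue
        mh_len, mh_seq = mh_info[(chrom, cs, ce)]
        records.append(
            CircleRecord(
                circle_id=f"ecc{n:04d}", chrom=chrom, start=cs, end=ce,
                support=len(support[(chrom, cs, ce)]), mh_len=mh_len, mh_seq=mh_seq,
            )
        )
    for i, rec in enumerate(records):
        rec.circle_id = f"ecc{i:04d}"
    return records


# ---------------------------------------------------------------------------
# circle characterisation
# ---------------------------------------------------------------------------

def assign_target_alleles(
    circle: CircleRecord,
    reads,
    sites: list[TargetSite],
    ref: Reference,
    aligner=None,
    min_coverage: int = 1,
    index=None,
    min_seg: int = DEFAULT_MIN_SEG,
) -> list[tuple[str, str]]:
    """Classify the allele carried at each target site inside the circle.

    Reads overlapping a contained site's classification window are
    classified against the reference-derived local amplicon; the consensus
    (modal retained) label is reported per site, or ``"uncalled"`` when the
    site is uncovered.  Fills and returns ``circle.target_hits``.
    """
    aligner = aligner or make_aligner()
    index = index if index is not None else build_seed_index(ref, min_seg)
    inside = [
        s for s in sites
        if s.chrom == circle.chrom and circle.start <= s.cut_pos < circle.end
    ]
    hits = []
    for site in inside:
        win_lo, win_hi = site.window()
        ref_seq = ref.sequences[site.chrom]
        probe_lo = max(0, win_lo - 200)
        probe_hi = min(len(ref_seq), win_hi + 200)
        probes = {
            ref_seq[i : i + min_seg]
            for i in range(probe_lo, probe_hi - min_seg + 1)
        }
        votes: dict[str, int] = defaultdict(int)
        for item in reads:
            rid, seq = (item.read_id, item.seq) if hasattr(item, "seq") else item
            # cheap k-mer prefilter before segmenting/aligning
            if not any(
                seq[i : i + min_seg] in probes or revcomp(seq[i : i + min_seg]) in probes
                for i in range(0, len(seq) - min_seg + 1, min_seg)
            ):
                continue
            for oriented in (seq, revcomp(seq)):
                segs = [
                    s for s in segment_read(oriented, ref, index, min_seg)
                    if s[2] == site.chrom
                ]
                # the read must reach past both window edges (an indel at the
                # cut splits it into segments, so coverage is judged jointly);
                # the classifier itself enforces full-window alignment
                if not segs or min(s[3] for s in segs) > win_lo \
                        or max(s[4] for s in segs) < win_hi:
                    continue
                call = _classify_site_window(oriented, site, ref, aligner)
                if call.retained:
                    votes[call.label] += 1
                break
        if not votes or sum(votes.values()) < min_coverage:
            hits.append((site.gene_id, "uncalled"))
        else:
            top = max(votes, key=lambda l: (votes[l], l))
            hits.append((site.gene_id, top))
    circle.target_hits = hits
    return hits


def _classify_site_window(seq: str, site: TargetSite, ref: Reference, aligner) -> AlleleCall:
    from .reference import site_on_protospacer_strand

    amp, cut = site_on_protospacer_strand(site, ref, halfwidth=200)
    return _classify_oriented(seq, amp, cut, site.window_halfwidth, aligner, "", site.gene_id)


def junction_distance_to_cut(circle: CircleRecord, site: TargetSite) -> JunctionDistance:
    """Distances from the Cas9 break to the circle's two junction points.

    The nearer junction coordinate is the proximal distance, the farther
    the distal one; log10 values are defined only for distances >= 1 bp.
    When the cut lies inside the circle the two distances sum to the circle
    size.
    """
    if circle.chrom != site.chrom:
        raise ValueError(
            f"site {site.gene_id} on {site.chrom} but circle on {circle.chrom}"
        )
    d_start = abs(site.cut_pos - circle.start)
    d_end = abs(site.cut_pos - circle.end)
    prox, dist = min(d_start, d_end), max(d_start, d_end)
    return JunctionDistance(
        gene_id=site.gene_id,
        circle_id=circle.circle_id,
        dist_proximal=prox,
        dist_distal=dist,
        log10_proximal=math.log10(prox) if prox >= 1 else None,
        log10_distal=math.log10(dist) if dist >= 1 else None,
    )


def circle_length_stats(circles: list[CircleRecord], bins: int = 20) -> dict:
    """Size summary: count, range, median, %<1 kb, %<2 kb, histogram.

    The median of an even-sized set is the lower middle value (so the
    reported median is always an observed circle size).
    """
    if not circles:
        raise ValueError("no circles")
    sizes = np.sort([c.size for c in circles])
    n = len(sizes)
    counts, edges = np.histogram(sizes, bins=bins)
    return {
        "count": n,
        "min": int(sizes[0]),
        "max": int(sizes[-1]),
        "median": int(sizes[(n - 1) // 2]),
        "pct_lt_1kb": float((sizes < 1000).mean() * 100.0),
        "pct_lt_2kb": float((sizes < 2000).mean() * 100.0),
        "histogram": (counts.tolist(), edges.tolist()),
    }


def annotate_circle(circle: CircleRecord, annotation) -> str:
    """Genic category of the circle midpoint under fixed priority.

    Priority promoter > 5'UTR > exon > 3'UTR > intron; a midpoint
    overlapping nothing is "distal intergenic".
    """
    tree = annotation.get(circle.chrom) if annotation else None
    cats = {iv.data for iv in tree[circle.midpoint]} if tree is not None else set()
    for cat in ANNOTATION_CATEGORIES:
        if cat in cats:
            circle.annotation = cat
            return cat
    circle.annotation = "distal intergenic"
    return "distal intergenic"


def annotation_breakdown(circles: list[CircleRecord], annotation) -> pd.Series:
    cats = [annotate_circle(c, annotation) for c in circles]
    order = ANNOTATION_CATEGORIES + ["distal intergenic"]
    counts = pd.Series(cats).value_counts().reindex(order).fillna(0).astype(int)
    return counts


# ---------------------------------------------------------------------------
# Sanger-style junction clones
# ---------------------------------------------------------------------------

class JunctionCloneError(ValueError):
    pass


def classify_junction_clone(
    seq: str,
    circle: CircleRecord,
    site: TargetSite,
    ref: Reference,
    aligner=None,
    junction_halfwidth: int = 15,
) -> tuple[str, str]:
    """Classify a Sanger-sequenced junction clone.

    The clone must span both the circularization junction and the target
    window.  The sequence is aligned to a doubled copy of the circle's
    reference-derived sequence (so both landmarks are interior), the target
    window is classified in the usual allele grammar, and the junction is
    classified against the canonical junction string with the same grammar
    ("WT" meaning the two ends joined accurately).
    """
    aligner = aligner or make_aligner()
    if circle.chrom != site.chrom:
        raise JunctionCloneError("circle and site on different sequences")
    C = ref.sequences[circle.chrom][circle.start : circle.end]
    D = C + C
    L = len(C)
    t_local = site.cut_pos - circle.start
    if not 0 <= t_local < L:
        raise JunctionCloneError("target cut not inside the circle")

    best = None
    for oriented in (seq, revcomp(seq)):
        aln = align_read(oriented, D, aligner)
        if aln is not None and (best is None or aln.score > best.score):
            best = aln
    if best is None:
        raise JunctionCloneError("sequence does not align to the circle")

    span_lo, span_hi = best.amp_span
    wj = junction_halfwidth
    if not (span_lo <= L - wj and span_hi >= L + wj):
        raise JunctionCloneError("sequence does not span the circularization junction")
    wt = site.window_halfwidth
    target_cut = None
    for cand in (t_local, t_local + L):
        if span_lo <= cand - wt and span_hi >= cand + wt:
            target_cut = cand
            break
    if target_cut is None:
        raise JunctionCloneError("sequence does not span the target window")

    from .align import classify_edit

    junction_call = classify_edit(best, L, wj)
    target_call = classify_edit(best, target_cut, wt)
    if target_call.category == CATEGORY_DISCARD or junction_call.category == CATEGORY_DISCARD:
        raise JunctionCloneError("clone sequence too complex to classify")
    return target_call.label, junction_call.label


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def circles_to_bed(circles: list[CircleRecord], path, header_lines=()) -> None:
    """BED6+ export: chrom start end id support strand size mh_len annotation."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for c in circles:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.circle_id}\t{c.support}\t+"
                f"\t{c.size}\t{c.mh_len}\t{c.annotation or '.'}\n"
            )
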