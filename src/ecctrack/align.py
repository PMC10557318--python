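"""Read-to-amplicon alignment and cut-anchored edit classification.

Editing outcomes are named in the ``Del a|b`` / ``Ins n seq`` notation:
``a`` bases deleted 5' (left) and ``b`` bases 3' (right) of the Cas9 break
on the protospacer strand, and ``Ins n seq`` for an n-bp insertion at the
break.  A combined outcome is written ``Del a|b Ins n seq``.

Reads are aligned globally with affine gap penalties (match +2, mismatch
-4, gap open -10, gap extend -1; reference end-gaps free so a read may
cover only part of the amplicon).  The aligner's optimal path can spell a
combined deletion+insertion as several small gaps interleaved with
mismatches, so the edit inside the classification window is re-derived by
a cut-anchored decomposition: extend exact matches inward from both window
edges (absorbing isolated substitutions that re-anchor within a few
bases), take what is left as one deleted-interval / inserted-string event,
and reduce it to its minimal form.  Indel placement inside repeats is
ambiguous among score-equivalent shifts; the placement closest to the cut
wins and residual ties go to the leftmost (5') placement, which makes the
a|b labels deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from functools import lru_cache

from Bio import Align

from .reference import Reference, TargetSite, revcomp, site_on_protospacer_strand

CATEGORY_WT = "WT"
CATEGORY_DEL = "DEL"
CATEGORY_INS = "INS"
CATEGORY_DELINS = "DELINS"
CATEGORY_DISCARD = "DISCARD"

DISCARD_POOR_ALIGNMENT = "poor_alignment"
DISCARD_INCOMPLETE_WINDOW = "incomplete_window"
DISCARD_COMPLEX = "complex"

#: indel clusters separated by at least this many reference bases are
#: treated as disjoint events (and more than one of them as complex)
EVENT_MERGE_DISTANCE = 8
#: an isolated mismatch is absorbed during match extension only when this
#: many following bases re-anchor exactly
EXTEND_LOOKAHEAD = 8

_LABEL_RE = re.compile(
    r"^(?:WT|(?:Del(?P<a>\d+)\|(?P<b>\d+))?"
    r"(?(a) ?)(?:Ins(?P<n>\d+)(?P<seq>[ACGT]+))?)$"
)


class LabelError(ValueError):
    """Allele label outside the Del a|b / Ins n seq grammar."""


# ---------------------------------------------------------------------------
# label grammar
# ---------------------------------------------------------------------------

def format_label(del_left: int, del_right: int, ins_seq: str) -> str:
    """Canonical allele label as a pure function of (a, b, seq)."""
    parts = []
    if del_left or del_right:
        parts.append(f"Del{del_left}|{del_right}")
    if ins_seq:
        parts.append(f"Ins{len(ins_seq)}{ins_seq}")
    return " ".join(parts) if parts else "WT"


def parse_label(label: str) -> tuple[int, int, str]:
    """Inverse of :func:`format_label`; raises :class:`LabelError`."""
    if label == "WT":
        return 0, 0, ""
    m = _LABEL_RE.match(label)
    if not m or (m.group("a") is None and m.group("n") is None):
        raise LabelError(f"unparseable allele label {label!r}")
    a = int(m.group("a")) if m.group("a") else 0
    b = int(m.group("b")) if m.group("b") else 0
    seq = m.group("seq") or ""
    if m.group("n") is not None and int(m.group("n")) != len(seq):
        raise LabelError(f"insertion length mismatch in {label!r}")
    if (a, b, seq) == (0, 0, ""):
        raise LabelError(f"empty edit label {label!r}")
    return a, b, seq


def apply_allele(amplicon: str, cut: int, label: str) -> str:
    """Apply an allele label at the cut to produce the mutated amplicon."""
    a, b, seq = parse_label(label)
    if cut - a < 0 or cut + b > len(amplicon):
        raise LabelError(
            f"allele {label!r} extends past the amplicon (cut {cut}, len {len(amplicon)})"
        )
    return amplicon[: cut - a] + seq + amplicon[cut + b :]


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleCall:
    """A single read's classified editing outcome."""

    read_id: str
    gene_id: str
    category: str
    del_left: int = 0
    del_right: int = 0
    ins_seq: str = ""
    label: str | None = "WT"
    has_substitution: bool = False
    discard_reason: str | None = None

    @property
    def retained(self) -> bool:
        return self.category != CATEGORY_DISCARD

    @property
    def net_length_change(self) -> int:
        return len(self.ins_seq) - self.del_left - self.del_right


@dataclass
class ReadAlignment:
    """Aligned blocks of a read against an amplicon.

    ``blocks`` lists ``(amp_start, amp_end, read_start, read_end)``
    gap-free aligned segments in increasing coordinate order; the gaps
    between consecutive blocks are deletions (amplicon-only bases) and/or
    insertions (read-only bases).
    """

    read: str
    amplicon: str
    score: float
    blocks: list[tuple[int, int, int, int]]

    @property
    def amp_span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


def make_aligner(match: float = 2, mismatch: float = -4,
                 gap_open: float = -10, gap_extend: float = -1) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # affine convention: a k-bp gap scores gap_open + k * gap_extend;
    # Biopython's open_gap_score is the score of the first gap column
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    # free end gaps: the read may cover only part of the amplicon
    try:
        aligner.open_end_gap_score = 0
        aligner.extend_end_gap_score = 0
    except AttributeError:  # older attribute spelling
        aligner.end_open_gap_score = 0
        aligner.end_extend_gap_score = 0
    return aligner


_DEFAULT_ALIGNER = make_aligner()


def align_read(read: str, amplicon: str,
               aligner: Align.PairwiseAligner | None = None,
               score_floor_fraction: float = 0.4) -> ReadAlignment | None:
    """Globally align ``read`` to ``amplicon``.

    Returns ``None`` when the optimal score falls below
    ``score_floor_fraction * match_score * len(read)`` (an unrelated read).
    """
    if not read or not amplicon:
        raise ValueError("read and amplicon must be non-empty")
    aligner = aligner or _DEFAULT_ALIGNER
    aln = aligner.align(amplicon, read)[0]
    floor = score_floor_fraction * aligner.match_score * len(read)
    if aln.score < floor:
        return None
    amp_blocks, read_blocks = aln.aligned
    blocks = [
        (int(a0), int(a1), int(r0), int(r1))
        for (a0, a1), (r0, r1) in zip(amp_blocks, read_blocks)
    ]
    return ReadAlignment(read=read, amplicon=amplicon, score=float(aln.score), blocks=blocks)


# ---------------------------------------------------------------------------
# canonical placement of indels
# ---------------------------------------------------------------------------

def _canonical_deletion(amp: str, ds: int, de: int, cut: int) -> tuple[int, int]:
    """Cut-proximal, then leftmost, placement among shift-equivalent ones."""
    placements = [(ds, de)]
    s, e = ds, de
    while s > 0 and amp[s - 1] == amp[e - 1]:
        s, e = s - 1, e - 1
        placements.append((s, e))
    s, e = ds, de
    while e < len(amp) and amp[e] == amp[s]:
        s, e = s + 1, e + 1
        placements.append((s, e))

    def key(p):
        s, e = p
        dist = max(s - cut, cut - e, 0)
        return (dist, s)

    return min(placements, key=key)


def _canonical_insertion(amp: str, pos: int, seq: str, cut: int) -> tuple[int, str]:
    placements = [(pos, seq)]
    p, s = pos, seq
    while p > 0 and s and s[-1] == amp[p - 1]:
        p, s = p - 1, amp[p - 1] + s[:-1]
        placements.append((p, s))
    p, s = pos, seq
    while p < len(amp) and s and s[0] == amp[p]:
        p, s = p + 1, s[1:] + amp[p]
        placements.append((p, s))
    return min(placements, key=lambda ps: (abs(ps[0] - cut), ps[0]))


def _reduce_event(amp: str, ds: int, de: int, ins: str, cut: int,
                  lookahead: int | None = None):
    """Minimal canonical form of one (deleted interval, inserted seq) event.

    Trims bases shared between the deleted and inserted strings at either
    end — tolerantly, so an isolated sequencing substitution flanking a
    real indel is split off as a substitution instead of inflating the
    event into a spurious deletion+insertion — then canonicalises
    placement: equal-length leftovers vanish (a pure substitution run),
    pure indels get the cut-proximal leftmost placement.  Returns
    ``(ds, de, ins, n_substitutions)``.
    """
    if lookahead is None:
        lookahead = EXTEND_LOOKAHEAD
    deleted = amp[ds:de]
    t, subs_t = _tolerant_extend(deleted, ins, lookahead)
    u, subs_u = _tolerant_extend(deleted[::-1], ins[::-1], lookahead)
    u = min(u, min(len(deleted), len(ins)) - t)
    ds, de = ds + t, de - u
    ins = ins[t : len(ins) - u] if u else ins[t:]
    # parsimony: a leftover deletion+insertion of unequal lengths that is one
    # pure indel plus at most one substitution is represented that way (a
    # sequencing error directly abutting an indel, not a compound allele)
    if de > ds and ins and de - ds != len(ins):
        D, I = amp[ds:de], ins
        m, n = len(D), len(I)
        if m > n:
            longer, shorter, gap = D, I, m - n
        else:
            longer, shorter, gap = I, D, n - m
        best_g = best_cost = None
        for g in range(len(shorter) + 1):
            cost = sum(shorter[i] != longer[i] for i in range(g)) + sum(
                shorter[i] != longer[i + gap] for i in range(g, len(shorter))
            )
            if best_cost is None or cost < best_cost:
                best_g, best_cost = g, cost
        if best_cost <= 1:
            if m > n:  # net deletion: keep only the gapped block deleted
                ds, de, ins = ds + best_g, ds + best_g + gap, ""
            else:  # net insertion
                ds = de = ds + best_g
                ins = I[best_g : best_g + gap]
            subs_t += best_cost
    if de > ds and not ins:
        ds, de = _canonical_deletion(amp, ds, de, cut)
    elif ins and de == ds:
        ds, ins = _canonical_insertion(amp, ds, ins, cut)
        de = ds
    return ds, de, ins, subs_t + subs_u


def canonical_label(amp: str, cut: int, label: str) -> str:
    """The label this pipeline reports for an edit applied at the cut.

    Two different (a, b, seq) recipes can mutate an amplicon identically
    when the cut sits in a repeat; this maps any recipe to the canonical
    representative so ground-truth labels and classifier output are
    comparable.  An equal-length deletion+insertion reduces to "WT" (it is
    a substitution run, which the frequency tables count as unedited).
    """
    a, b, seq = parse_label(label)
    ds, de, ins, _ = _reduce_event(amp, cut - a, cut + b, seq, cut)
    return format_label(*_split_at_cut(ds, de, cut), ins)


def _split_at_cut(ds: int, de: int, cut: int) -> tuple[int, int]:
    if de <= ds:
        return 0, 0
    if ds >= cut:
        return 0, de - ds
    if de <= cut:
        return de - ds, 0
    return cut - ds, de - cut


# ---------------------------------------------------------------------------
# window decomposition
# ---------------------------------------------------------------------------

def _indel_positions(aln: ReadAlignment) -> list[tuple[int, int]]:
    """Reference-coordinate extents ``(start, end)`` of each alignment gap."""
    out = []
    for (a0, a1, r0, r1), (b0, b1, s0, s1) in zip(aln.blocks, aln.blocks[1:]):
        if b0 > a1:  # deletion
            out.append((a1, b0))
        if s0 > r1:  # insertion (zero-width in reference space)
            out.append((b0, b0))
    return out


def _cluster_extents(extents, merge_distance):
    clusters = []
    for s, e in sorted(extents):
        if clusters and s - clusters[-1][1] < merge_distance:
            clusters[-1][1] = max(clusters[-1][1], e)
        else:
            clusters.append([s, e])
    return clusters


def _window_read_segment(aln: ReadAlignment, win_lo: int, win_hi: int) -> str:
    """Read bases aligned across the reference window (insertions included)."""
    r_lo = r_hi = None
    for a0, a1, r0, r1 in aln.blocks:
        lo, hi = max(a0, win_lo), min(a1, win_hi)
        if lo < hi:
            if r_lo is None:
                r_lo = r0 + (lo - a0)
            r_hi = r0 + (hi - a0)
    return aln.read[r_lo:r_hi] if r_lo is not None else ""


def _tolerant_extend(a: str, b: str, lookahead: int = EXTEND_LOOKAHEAD) -> tuple[int, int]:
    """Longest lockstep match of two strings absorbing isolated mismatches.

    A mismatch is absorbed (counted, not stopped at) only when the next
    ``lookahead`` bases of both strings re-anchor exactly, so extension
    stops at any length-changing edit.  Returns (matched_length,
    n_substitutions).
    """
    i = subs = 0
    n = min(len(a), len(b))
    while i < n:
        if a[i] == b[i]:
            i += 1
            continue
        la = min(lookahead, n - i - 1)
        if la > 0 and a[i + 1 : i + 1 + la] == b[i + 1 : i + 1 + la]:
            subs += 1
            i += 1
            continue
        break
    return i, subs


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_edit(aln: ReadAlignment | None, site_cut: int, window_halfwidth: int,
                  read_id: str = "", gene_id: str = "",
                  merge_distance: int = EVENT_MERGE_DISTANCE) -> AlleleCall:
    """Classify one aligned read into the paper-style allele call.

    ``site_cut`` is the cut's inter-base coordinate in amplicon space (the
    amplicon must already be oriented to the protospacer strand).  Reads
    whose alignment does not cover the window are DISCARD:incomplete_window;
    more than one indel cluster (clusters separated by >=
    ``merge_distance`` reference bases) inside the window is
    DISCARD:complex.
    """
    def discard(reason):
        return AlleleCall(read_id=read_id, gene_id=gene_id, category=CATEGORY_DISCARD,
                          label=None, discard_reason=reason)

    if aln is None:
        return discard(DISCARD_POOR_ALIGNMENT)
    w = window_halfwidth
    win_lo, win_hi = site_cut - w, site_cut + w
    span_lo, span_hi = aln.amp_span
    if span_lo > win_lo or span_hi < win_hi:
        return discard(DISCARD_INCOMPLETE_WINDOW)

    amp = aln.amplicon
    clusters = _cluster_extents(_indel_positions(aln), merge_distance)
    in_window = [
        (s, e) for s, e in clusters
        if (s < win_hi and e > win_lo) or (s == e and win_lo <= s < win_hi)
    ]
    if len(in_window) > 1:
        return discard(DISCARD_COMPLEX)

    A = amp[win_lo:win_hi]
    R = _window_read_segment(aln, win_lo, win_hi)
    if not R:
        return discard(DISCARD_INCOMPLETE_WINDOW)

    if not in_window:
        # gap-free window: any divergence is substitution only
        return AlleleCall(read_id=read_id, gene_id=gene_id, category=CATEGORY_WT,
                          label="WT", has_substitution=A != R)

    # single indel cluster: cut-anchored decomposition of the window
    p, subs_p = _tolerant_extend(A, R)
    s, subs_s = _tolerant_extend(A[::-1], R[::-1])
    s = min(s, len(A) - p, len(R) - p)
    ds, de = win_lo + p, win_lo + len(A) - s
    ins = R[p : len(R) - s]
    ds, de, ins, subs_e = _reduce_event(amp, ds, de, ins, site_cut)
    has_sub = subs_p + subs_s + subs_e > 0

    if de == ds and not ins:
        return AlleleCall(read_id=read_id, gene_id=gene_id, category=CATEGORY_WT,
                          label="WT", has_substitution=True)
    if de > ds and ins and de - ds == len(ins):
        # equal-length replacement is a substitution run, not an indel
        return AlleleCall(read_id=read_id, gene_id=gene_id, category=CATEGORY_WT,
                          label="WT", has_substitution=True)

    del_left, del_right = _split_at_cut(ds, de, site_cut)
    category = (
        CATEGORY_DELINS if (de > ds and ins)
        else CATEGORY_DEL if de > ds
        else CATEGORY_INS
    )
    return AlleleCall(
        read_id=read_id, gene_id=gene_id, category=category,
        del_left=del_left, del_right=del_right, ins_seq=ins,
        label=format_label(del_left, del_right, ins),
        has_substitution=has_sub,
    )


def classify_read(read: str, site: TargetSite, ref: Reference,
                  aligner: Align.PairwiseAligner | None = None,
                  read_id: str = "", amp_halfwidth: int = 120) -> AlleleCall:
    """Orientation-normalise and classify one read against its target."""
    amp, cut = site_on_protospacer_strand(site, ref, amp_halfwidth)
    return _classify_oriented(read, amp, cut, site.window_halfwidth,
                              aligner, read_id, site.gene_id)


def _classify_oriented(read, amp, cut, w, aligner, read_id, gene_id) -> AlleleCall:
    fwd = align_read(read, amp, aligner)
    rev = align_read(revcomp(read), amp, aligner)
    best = max((a for a in (fwd, rev) if a is not None),
               key=lambda a: a.score, default=None)
    return classify_edit(best, cut, w, read_id=read_id, gene_id=gene_id)


class ReadClassifier:
    """Memoising batch classifier for one target site.

    Amplicon deep-sequencing read sets are highly redundant (error-free
    reads from the same allele are identical), so calls are cached on the
    read sequence.
    """

    def __init__(self, site: TargetSite, ref: Reference,
                 aligner: Align.PairwiseAligner | None = None,
                 amp_halfwidth: int = 120, cache_size: int = 200_000):
        self.site = site
        self.amp, self.cut = site_on_protospacer_strand(site, ref, amp_halfwidth)
        self.aligner = aligner or _DEFAULT_ALIGNER

        @lru_cache(maxsize=cache_size)
        def _cached(seq: str) -> AlleleCall:
            return _classify_oriented(seq, self.amp, self.cut,
                                      site.window_halfwidth, self.aligner,
                                      "", site.gene_id)

        self._cached = _cached

    def __call__(self, read: str, read_id: str = "") -> AlleleCall:
        call = self._cached(read)
        if read_id and call.read_id != read_id:
            call = replace(call, read_id=read_id)
        return call

    def classify_all(self, reads) -> list[AlleleCall]:
        """Classify ``(read_id, sequence)`` pairs (or bare sequences)."""
        out = []
        for item in reads:
            rid, seq = item if isinstance(item, tuple) else ("", item)
            out.append(self(seq, rid))
        return out


def alignment_to_cigar(aln: ReadAlignment) -> tuple[int, str]:
    """(1-based reference position, CIGAR) of a read alignment."""
    ops = []
    prev = None
    for a0, a1, r0, r1 in aln.blocks:
        if prev is not None:
            pa, pr = prev
            if a0 > pa:
                ops.append(f"{a0 - pa}D")
            if r0 > pr:
                ops.append(f"{r0 - pr}I")
        ops.append(f"{a1 - a0}M")
        prev = (a1, r1)
    r_lo, r_hi = aln.blocks[0][2], aln.blocks[-1][3]
    if r_lo > 0:
        ops.insert(0, f"{r_lo}S")
    if r_hi < len(aln.read):
        ops.append(f"{len(aln.read) - r_hi}S")
    return aln.blocks[0][0] + 1, "".join(ops)


def write_sam(alignments, amplicon_name: str, amplicon_len: int, path) -> None:
    """Minimal single-reference SAM export of read alignments for
    inspection in a genome browser; ``alignments`` is an iterable of
    ``(read_id, ReadAlignment | None)``."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{amplicon_name}\tLN:{amplicon_len}\n")
        for read_id, aln in alignments:
            if aln is None:
                fh.write(f"{read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")
                continue
            pos, cigar = alignment_to_cigar(aln)
            fh.write(
                f"{read_id}\t0\t{amplicon_name}\t{pos}\t255\t{cigar}\t*\t0\t0"
                f"\t{aln.read}\t*\n"
            )


def frameshift_phenotype(net_len_change: int) -> str:
    """NHEJ frame-shift reporter arithmetic.

    The reporter encodes GFP one base out of frame, so an indel with a net
    length change of +1 modulo 3 reframes GFP and scores positive.
    """
    return "reporter_positive" if net_len_change % 3 == 1 else "reporter_negative"
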