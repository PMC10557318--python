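"""Alignment and cut-anchored classification of editing outcomes."""

import numpy as np
import pytest

from ecctrack.align import (
    CATEGORY_DELINS,
    CATEGORY_DISCARD,
    CATEGORY_WT,
    DISCARD_COMPLEX,
    DISCARD_INCOMPLETE_WINDOW,
    DISCARD_POOR_ALIGNMENT,
    apply_allele,
    align_read,
    canonical_label,
    classify_edit,
    classify_read,
    frameshift_phenotype,
    make_aligner,
)
from ecctrack.reference import Reference, TargetSite, infer_cut_site, revcomp


def _nw_affine_score(a, b, match=2, mismatch=-4, gap_open=-10, gap_extend=-1):
    """Independent Gotoh dynamic program (free end gaps) for score checking."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # free end gaps
    for j in range(1, m + 1):
        Y[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open + gap_extend, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open + gap_extend, Y[i][j - 1] + gap_extend)
    # free end gaps on the closing side as well
    best = max(M[n][m], X[n][m], Y[n][m])
    for i in range(n + 1):
        best = max(best, M[i][m], Y[i][m])
    for j in range(m + 1):
        best = max(best, M[n][j], X[n][j])
    return best


def test_identical_read_is_all_match(plus_amplicon):
    amp, _ = plus_amplicon
    aln = align_read(amp, amp)
    assert aln.blocks == [(0, len(amp), 0, len(amp))]
    assert aln.score == 2 * len(amp)


def test_single_deletion_alignment_matches_dp_oracle(plus_amplicon):
    """One base removed at the cut: one 1-bp deletion, score per the DP."""
    amp, cut = plus_amplicon
    amp = amp[:200]
    read = amp[: cut - 1] + amp[cut:]
    aln = align_read(read, amp)
    gaps = [(a1, b0) for (a0, a1, r0, r1), (b0, b1, s0, s1)
            in zip(aln.blocks, aln.blocks[1:]) if b0 > a1]
    assert len(gaps) == 1 and gaps[0][1] - gaps[0][0] == 1
    assert abs(gaps[0][0] - cut) <= 2  # placement within the local repeat
    assert aln.score == _nw_affine_score(amp, read)


def test_unrelated_read_discarded(plus_site):
    ref, site = plus_site
    rng = np.random.default_rng(7)
    for _ in range(5):
        junk = "".join(rng.choice(list("ACGT"), 150))
        call = classify_read(junk, site, ref)
        assert call.category == CATEGORY_DISCARD
        assert call.discard_reason == DISCARD_POOR_ALIGNMENT


@pytest.mark.parametrize(
    "label,category",
    [
        ("Del1|0", "DEL"),
        ("Del0|7", "DEL"),
        ("Ins1A", "INS"),
        ("Del8|0 Ins4CCCG", "DELINS"),
        ("Del11|16", "DEL"),
        ("WT", "WT"),
    ],
)
def test_printed_allele_labels_recovered(plus_site, plus_amplicon, label, category):
    """The in-print example alleles come back under their own names."""
    ref, site = plus_site
    amp, cut = plus_amplicon
    # precondition (not tuned): these labels are canonical on this fixture
    assert canonical_label(amp, cut, label) == label
    mut = apply_allele(amp, cut, label)
    call = classify_read(mut, site, ref)
    assert call.label == label
    assert call.category == category


def test_large_deletion_recovered_on_nonshiftable_fixture():
    """A 22|5 deletion around the cut keeps its name when not shiftable."""
    # handcrafted amplicon: distinct flanks so the deletion cannot slide
    rng = np.random.default_rng(1234)
    for attempt in range(50):
        seq = "".join(rng.choice(list("ACGT"), 300))
        seq = seq[:120] + "T" + "GG" + seq[123:]
        ref = Reference({"c": seq})
        site = TargetSite("rb1like", "c", "+", seq[100:120], seq[120:123],
                          100, infer_cut_site("+", 100), window_halfwidth=30)
        from ecctrack.reference import site_on_protospacer_strand

        amp, cut = site_on_protospacer_strand(site, ref)
        if canonical_label(amp, cut, "Del22|5") == "Del22|5":
            break
    else:
        pytest.fail("no non-shiftable fixture found")
    mut = apply_allele(amp, cut, "Del22|5")
    assert classify_read(mut, site, ref).label == "Del22|5"


def test_substitution_only_read_is_wt_with_flag(plus_site, plus_amplicon):
    ref, site = plus_site
    amp, cut = plus_amplicon
    mut = amp[:cut] + ("A" if amp[cut] != "A" else "C") + amp[cut + 1 :]
    call = classify_read(mut, site, ref)
    assert call.category == CATEGORY_WT and call.label == "WT"
    assert call.has_substitution


def test_incomplete_window_discarded(plus_site, plus_amplicon):
    ref, site = plus_site
    amp, cut = plus_amplicon
    short = amp[cut - 5 : cut + 40]  # covers only part of the window
    call = classify_read(short, site, ref)
    assert call.discard_reason == DISCARD_INCOMPLETE_WINDOW


def test_two_disjoint_deletions_are_complex(plus_amplicon):
    amp, cut = plus_amplicon
    # two deletions 12 bp apart inside the window
    read = amp[: cut - 12] + amp[cut - 10 : cut] + amp[cut + 3 :]
    aln = align_read(read, amp)
    call = classify_edit(aln, cut, 25)
    assert call.category == CATEGORY_DISCARD
    assert call.discard_reason == DISCARD_COMPLEX


def test_indel_outside_window_ignored(plus_site, plus_amplicon):
    ref, site = plus_site
    amp, cut = plus_amplicon
    mut = amp[: cut - 60] + amp[cut - 58 :]  # 2-bp deletion far 5' of the cut
    call = classify_read(mut, site, ref)
    assert call.label == "WT"


def test_error_adjacent_to_indel_stays_single_indel(plus_site, plus_amplicon):
    """A substitution flanking a deletion must not inflate it to a delins."""
    ref, site = plus_site
    amp, cut = plus_amplicon
    mut = apply_allele(amp, cut, "Del0|7")
    pos = cut - 3
    mut = mut[:pos] + ("A" if mut[pos] != "A" else "C") + mut[pos + 1 :]
    call = classify_read(mut, site, ref)
    assert call.label == "Del0|7"
    assert call.has_substitution


def test_strand_invariance(plus_site):
    """A read classifies identically in either orientation."""
    ref, site = plus_site
    from ecctrack.reference import site_on_protospacer_strand

    amp, cut = site_on_protospacer_strand(site, ref)
    for label in ("Del2|1", "Ins3ACT", "WT"):
        mut = apply_allele(amp, cut, label)
        assert classify_read(mut, site, ref).label == \
               classify_read(revcomp(mut), site, ref).label


@pytest.mark.parametrize("a,b,seq", [
    (1, 0, ""), (0, 1, ""), (3, 2, ""), (0, 0, "A"), (0, 0, "ACGT"),
    (5, 0, "GG"), (0, 6, ""),
])
def test_canonical_label_preserves_the_mutation(plus_amplicon, a, b, seq):
    """Canonicalisation may rename an edit but never changes its product,
    and the canonical form is a fixed point."""
    amp, cut = plus_amplicon
    from ecctrack.align import format_label

    label = format_label(a, b, seq)
    got = canonical_label(amp, cut, label)
    assert apply_allele(amp, cut, got) == apply_allele(amp, cut, label)
    assert canonical_label(amp, cut, got) == got


@pytest.mark.parametrize("shift,expected", [
    (+1, "reporter_positive"),
    (+3, "reporter_negative"),
    (-2, "reporter_positive"),
])
def test_frameshift_reporter_examples(shift, expected):
    assert frameshift_phenotype(shift) == expected


def test_frameshift_reporter_brute_force():
    """Positive exactly when the net shift is +1 modulo 3, over -6..+6."""
    for shift in range(-6, 7):
        expected = "reporter_positive" if shift % 3 == 1 else "reporter_negative"
        assert frameshift_phenotype(shift) == expected


def test_sam_round_trip(plus_amplicon, tmp_path):
    """Exported alignments are valid SAM that pysam parses back."""
    from ecctrack.align import write_sam
    from ecctrack.circles import reads_from_sam

    amp, cut = plus_amplicon
    read1 = amp[20:170]
    read2 = amp[: cut - 2] + amp[cut:]  # 2-bp deletion
    alns = [("r1", align_read(read1, amp)), ("r2", align_read(read2, amp)),
            ("junk", None)]
    p = tmp_path / "out.sam"
    write_sam(alns, "amp", len(amp), p)
    back = dict(reads_from_sam(p))
    assert back["r1"] == read1 and back["r2"] == read2
    text = p.read_text()
    assert "\t150M\t" in text  # full-length match for r1
    assert "2D" in text  # the deletion appears in r2's CIGAR
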