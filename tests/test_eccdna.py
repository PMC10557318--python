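"""Circularization-junction detection and circle characterisation."""

import numpy as np
import pytest

from ecctrack.align import canonical_label
from ecctrack.circles import (
    CircleRecord,
    JunctionCloneError,
    annotate_circle,
    assign_target_alleles,
    build_seed_index,
    circle_length_stats,
    classify_junction_clone,
    detect_junctions,
    junction_distance_to_cut,
    microhomology_at_junction,
)
from ecctrack.reference import Reference, revcomp, site_on_protospacer_strand
from ecctrack.sim import (
    CircleSpec,
    FastqRead,
    make_mini_genome,
    simulate_eccdna_library,
)


@pytest.fixture(scope="module")
def genome():
    return make_mini_genome(n_targets=6, seed=77)


def junction_reads(seq, start, end, n=30, read_len=120, rng_seed=0):
    """Hand-built reads spanning the (end -> start) seam."""
    rng = np.random.default_rng(rng_seed)
    circle = seq[start:end]
    doubled = circle + circle
    reads = []
    for i in range(n):
        off = int(rng.integers(len(circle) - read_len + 30, len(circle) - 30))
        reads.append(FastqRead(f"j{i}", doubled[off : off + read_len]))
    return reads


class TestDetection:
    def test_simulated_circle_recovered(self, genome):
        ref, sites = genome
        edited, reads, truth = simulate_eccdna_library(
            [CircleSpec("mini1", 1000, 1400)], ref,
            frag_len=300, read_len=120, depth_per_copy=40, err=0.0, seed=2,
        )
        recs = detect_junctions(reads, edited)
        assert len(recs) == 1
        r = recs[0]
        mh, _, cs, ce = microhomology_at_junction(edited.sequences["mini1"], 1000, 1400)
        assert (r.start, r.end) == (cs, ce)
        assert r.size == r.end - r.start == 400
        assert r.support >= 2

    def test_collinear_reads_yield_nothing(self, genome):
        ref, _ = genome
        seq = ref.sequences["mini1"]
        rng = np.random.default_rng(5)
        reads = [
            FastqRead(f"lin{i}", seq[s : s + 150])
            for i, s in enumerate(rng.integers(0, len(seq) - 150, size=500))
        ]
        assert detect_junctions(reads, ref) == []

    def test_two_circles_sharing_a_start(self, genome):
        ref, _ = genome
        seq = ref.sequences["mini1"]
        reads = junction_reads(seq, 2000, 2400, n=20, rng_seed=1) + \
                junction_reads(seq, 2000, 2900, n=20, rng_seed=2)
        recs = detect_junctions(reads, ref)
        canon = {
            microhomology_at_junction(seq, 2000, e)[2:] for e in (2400, 2900)
        }
        assert {(r.start, r.end) for r in recs} == canon
        assert len(recs) == 2

    def test_support_threshold(self, genome):
        ref, _ = genome
        seq = ref.sequences["mini1"]
        reads = junction_reads(seq, 3000, 3500, n=1)
        assert detect_junctions(reads, ref, min_support=2) == []
        assert len(detect_junctions(reads, ref, min_support=1)) == 1


class TestMicrohomology:
    @staticmethod
    def _brute_force(seq, start, end, max_shift=30):
        """Enumerate shift-equivalent placements by comparing circular
        sequences directly: placement (start+d, end+d) explains the same
        reads exactly when its circle equals the original circle rotated
        by d.  Returns (leftmost placement, ambiguity length)."""
        base = seq[start:end]
        L = len(base)

        def equivalent(d):
            s, e = start + d, end + d
            if s < 0 or e > len(seq):
                return False
            rotated = base[d % L :] + base[: d % L]
            return seq[s:e] == rotated

        lo = 0
        while lo > -max_shift and equivalent(lo - 1):
            lo -= 1
        hi = 0
        while hi < max_shift and equivalent(hi + 1):
            hi += 1
        return start + lo, end + lo, hi - lo

    def test_against_brute_force_enumeration(self):
        rng = np.random.default_rng(17)
        seq = "".join(rng.choice(list("ACGT"), 4000))
        for start, end in [(500, 900), (1000, 2000), (2500, 2810), (3000, 3700)]:
            mh, mh_seq, cs, ce = microhomology_at_junction(seq, start, end)
            bs, be, bmh = self._brute_force(seq, start, end)
            assert (cs, ce, mh) == (bs, be, bmh)
            assert mh_seq == seq[cs : cs + mh]

    def test_engineered_three_base_homology(self, genome):
        ref, _ = genome
        edited, _, _ = simulate_eccdna_library(
            [CircleSpec("mini1", 4000, 4300, mh_len=3)], ref,
            depth_per_copy=1, seed=0,
        )
        mh, mh_seq, cs, ce = microhomology_at_junction(edited.sequences["mini1"], 4000, 4300)
        assert (mh, cs, ce) == (3, 4000, 4300)
        assert len(mh_seq) == 3

    def test_no_shared_base(self):
        # flanks constructed to share nothing
        seq = "A" * 50 + "C" * 50 + "G" * 50 + "T" * 50
        mh, mh_seq, cs, ce = microhomology_at_junction(seq, 50, 100)
        assert mh == 0 and mh_seq == "" and (cs, ce) == (50, 100)

    def test_homopolymer_capped(self, caplog):
        import logging

        seq = "A" * 400
        with caplog.at_level(logging.WARNING):
            mh, mh_seq, cs, ce = microhomology_at_junction(seq, 100, 300)
        assert mh == 20  # configured cap
        assert any("capped" in r.message for r in caplog.records)


class TestDistances:
    def test_symmetric_cut(self):
        c = CircleRecord("e1", "c", 1000, 1400, support=5)
        site = _site_at("c", 1200)
        d = junction_distance_to_cut(c, site)
        assert (d.dist_proximal, d.dist_distal) == (200, 200)
        assert d.log10_distal == pytest.approx(2.301, abs=1e-3)

    def test_cut_at_junction_coordinate(self):
        c = CircleRecord("e1", "c", 1000, 1400, support=5)
        d = junction_distance_to_cut(c, _site_at("c", 1000))
        assert d.dist_proximal == 0 and d.log10_proximal is None

    def test_asymmetric_and_sum_rule(self):
        c = CircleRecord("e1", "c", 1000, 1400, support=5)
        d = junction_distance_to_cut(c, _site_at("c", 1100))
        assert (d.dist_proximal, d.dist_distal) == (100, 300)
        assert d.dist_proximal + d.dist_distal == c.size

    def test_chromosome_mismatch_raises(self):
        c = CircleRecord("e1", "c", 1000, 1400, support=5)
        with pytest.raises(ValueError):
            junction_distance_to_cut(c, _site_at("other", 1200))


def _site_at(chrom, cut):
    from ecctrack.reference import TargetSite

    return TargetSite("g", chrom, "+", "A" * 20, "AGG", cut - 17, cut)


class TestLengthStats:
    def test_examples(self):
        recs = [CircleRecord(f"e{i}", "c", 0, s, support=2)
                for i, s in enumerate([200, 300, 400, 5000])]
        stats = circle_length_stats(recs)
        assert stats["median"] == 300  # lower middle of an even count
        assert stats["pct_lt_1kb"] == pytest.approx(75.0)
        assert stats["pct_lt_2kb"] == pytest.approx(75.0)
        assert (stats["min"], stats["max"]) == (200, 5000)

    def test_single_circle(self):
        stats = circle_length_stats([CircleRecord("e", "c", 0, 344, support=2)])
        assert stats["median"] == 344

    def test_all_small(self):
        recs = [CircleRecord(f"e{i}", "c", 0, 150 + i, support=2) for i in range(5)]
        assert circle_length_stats(recs)["pct_lt_1kb"] == 100.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            circle_length_stats([])


class TestAnnotation:
    def test_priority_and_fallback(self, genome):
        ref, sites = genome
        tree = ref.annotation["mini1"]
        pos = 1500  # first target; exon covers [1050, 1650)
        c = CircleRecord("e1", "mini1", pos - 60, pos + 60, support=2)
        assert annotate_circle(c, ref.annotation) == "exon"
        # promoter overlaps intron in a constructed overlap
        from intervaltree import IntervalTree

        ann = {"mini1": IntervalTree()}
        ann["mini1"].addi(0, 1000, "intron")
        ann["mini1"].addi(0, 1000, "promoter")
        c2 = CircleRecord("e2", "mini1", 100, 300, support=2)
        assert annotate_circle(c2, ann) == "promoter"
        far = CircleRecord("e3", "mini1", len(ref.sequences["mini1"]) - 400,
                           len(ref.sequences["mini1"]) - 100, support=2)
        assert annotate_circle(far, ref.annotation) == "distal intergenic"


class TestTargetAlleles:
    @pytest.mark.parametrize("label", ["Del22|5", "WT", "Del3|0"])
    def test_contained_allele_reported(self, genome, label):
        ref, sites = genome
        site = sites[0]
        circle = CircleSpec(site.chrom, site.cut_pos - 150, site.cut_pos + 150,
                            copy_number=2, allele_at_target=label)
        edited, reads, _ = simulate_eccdna_library(
            [circle], ref, frag_len=300, read_len=150, depth_per_copy=40,
            err=0.0, seed=6, sites=sites,
        )
        recs = detect_junctions(reads, edited)
        assert len(recs) == 1
        hits = assign_target_alleles(recs[0], reads, sites, edited)
        amp, cut = site_on_protospacer_strand(site, edited)
        assert hits == [(site.gene_id, canonical_label(amp, cut, label))]

    def test_circle_without_target_has_no_hits(self, genome):
        ref, sites = genome
        edited, reads, _ = simulate_eccdna_library(
            [CircleSpec("mini1", 9000, 9400)], ref,
            frag_len=300, read_len=150, depth_per_copy=30, err=0.0, seed=7,
        )
        recs = detect_junctions(reads, edited)
        assert len(recs) == 1
        assert assign_target_alleles(recs[0], reads, sites, edited) == []


class TestJunctionClones:
    def _setup(self, genome, allele, circle_span=(150, 150)):
        ref, sites = genome
        site = sites[0]
        lo, hi = circle_span
        spec = CircleSpec(site.chrom, site.cut_pos - lo, site.cut_pos + hi,
                          allele_at_target=allele)
        from ecctrack.sim import circle_sequence

        cseq = circle_sequence(spec, ref, sites)
        circle = CircleRecord("e1", site.chrom, spec.start, spec.end, support=4)
        return ref, site, circle, cseq

    def test_wt_site_with_insertion_at_junction(self, genome):
        ref, site, circle, cseq = self._setup(genome, "WT")
        # Sanger clone: full circle opened 40 bp before the seam, with 1 G
        # inserted exactly at the seam
        seam = len(cseq)
        clone = cseq[seam - 60 :] + "G" + cseq[: seam - 60]
        target_label, junction_label = classify_junction_clone(clone, circle, site, ref)
        assert (target_label, junction_label) == ("WT", "Ins1G")

    def test_mutant_site_with_accurate_junction(self, genome):
        ref, site, circle, cseq = self._setup(genome, "Del3|0")
        clone = cseq[-60:] + cseq[:-60]
        target_label, junction_label = classify_junction_clone(clone, circle, site, ref)
        amp, cut = site_on_protospacer_strand(site, ref)
        assert target_label == canonical_label(amp, cut, "Del3|0")
        assert junction_label == "WT"

    def test_random_sequence_raises(self, genome):
        ref, site, circle, _ = self._setup(genome, "WT")
        junk = "".join(np.random.default_rng(3).choice(list("ACGT"), 200))
        with pytest.raises(JunctionCloneError):
            classify_junction_clone(junk, circle, site, ref)
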