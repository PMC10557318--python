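#!/usr/bin/env python
"""Detect eccDNA circles, characterise them, and compare with the truth.

Runs the junction caller on the simulated Circle-Seq-style library, then:
size statistics (range, median, fraction under 1/2 kb), genic annotation
of each circle, junction distance to the nearest Cas9 cut, microhomology
lengths, contained target alleles, and the per-target eccDNA/gDNA
relative read ratio with the <0.1% invalid-site rule.
"""

from pathlib import Path

import pandas as pd

from ecctrack.circles import (
    annotation_breakdown,
    assign_target_alleles,
    build_seed_index,
    circle_length_stats,
    circles_to_bed,
    detect_junctions,
    junction_distance_to_cut,
    microhomology_at_junction,
)
from ecctrack.quantify import (
    flag_invalid_sites,
    libsize_percentages,
    read_allele_tables,
    relative_read_ratio,
)
from ecctrack.reference import load_reference, load_targets
from ecctrack.sim import read_fastq

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main():
    edited = load_reference(SCRATCH / "mini_genome.edited.fasta")
    plain = load_reference(SCRATCH / "mini_genome.fasta")
    sites = load_targets(RESULTS / "target_panel.tsv", edited)
    # re-attach the generated annotation (FASTA carries no intervals)
    from ecctrack.sim import make_mini_genome

    ann_ref, _ = make_mini_genome(n_targets=35, seed=2026, extra_chrom_len=200_000)
    reads = read_fastq(SCRATCH / "eccdna.fastq")
    index = build_seed_index(edited, 20)

    circles = detect_junctions(reads, edited, min_support=2, index=index)
    for c in circles:
        assign_target_alleles(c, reads, sites, edited, index=index)
    annotation_breakdown(circles, ann_ref.annotation).rename("n_circles") \
        .to_csv(RESULTS / "circle_annotation_breakdown.tsv", sep="\t")
    circles_to_bed(circles, RESULTS / "circles_detected.bed",
                   header_lines=["source=analysis/04_eccdna_circles.py"])

    stats = circle_length_stats(circles)
    pd.Series({k: v for k, v in stats.items() if k != "histogram"}) \
        .to_csv(RESULTS / "circle_length_stats.tsv", sep="\t", header=False)

    dist_rows = []
    for c in circles:
        for s in sites:
            if s.chrom != c.chrom:
                continue
            d = junction_distance_to_cut(c, s)
            if d.dist_distal <= 5000:  # report only circles near a target
                dist_rows.append({
                    "circle_id": c.circle_id, "gene_id": s.gene_id,
                    "dist_proximal": d.dist_proximal, "dist_distal": d.dist_distal,
                    "log10_proximal": d.log10_proximal, "log10_distal": d.log10_distal,
                })
    pd.DataFrame(dist_rows).to_csv(RESULTS / "junction_distances.tsv",
                                   sep="\t", index=False)

    hits = [(c.circle_id, g, l) for c in circles for g, l in c.target_hits]
    pd.DataFrame(hits, columns=["circle_id", "gene_id", "label"]) \
        .to_csv(RESULTS / "circle_target_alleles.tsv", sep="\t", index=False)

    # recovery vs truth
    truth = pd.read_csv(RESULTS / "circle_truth.tsv", sep="\t")
    canonical = set()
    for _, t in truth.iterrows():
        _, _, cs, ce = microhomology_at_junction(edited.sequences[t.chrom], t.start, t.end)
        canonical.add((t.chrom, cs, ce))
    detected = {(c.chrom, c.start, c.end) for c in circles}
    print(f"circles detected: {len(circles)} of {len(truth)} simulated; "
          f"exact-coordinate matches: {len(detected & canonical)}; "
          f"false: {len(detected - canonical)}")
    print(f"size: min {stats['min']}, median {stats['median']}, max {stats['max']} bp; "
          f"{stats['pct_lt_1kb']:.0f}% < 1 kb, {stats['pct_lt_2kb']:.0f}% < 2 kb")

    # relative read ratio eccDNA/gDNA per target: eccDNA counts from library
    # reads overlapping each target window, gDNA counts from the parental
    # amplicon tables
    tables = read_allele_tables(SCRATCH / "allele_tables_full.tsv")
    g_counts = {t.gene_id: t.total_reads for t in tables if t.sample_id == "parent"}
    e_counts = dict.fromkeys(g_counts, 0)
    win = {s.gene_id: (s.chrom, *s.window()) for s in sites}
    from ecctrack.circles import segment_read
    from ecctrack.reference import revcomp

    for r in reads:
        for oriented in (r.seq, revcomp(r.seq)):
            segs = segment_read(oriented, edited, index, 20)
            done = False
            for _, _, chrom, p, q in segs:
                for gene, (c, lo, hi) in win.items():
                    if chrom == c and p < hi and q > lo:
                        e_counts[gene] += 1
                        done = True
                        break
                if done:
                    break
            if done:
                break
    ratios = relative_read_ratio(
        libsize_percentages(g_counts, "gDNA"),
        libsize_percentages(e_counts, "eccDNA"),
        flag_invalid_sites(g_counts),
        flag_invalid_sites(e_counts),
    )
    ratios.to_csv(RESULTS / "relative_read_ratios.tsv", sep="\t", index=False)
    covered = ratios[~ratios.invalid_eccDNA]
    print(f"targets with valid eccDNA coverage: {len(covered)} of {len(ratios)} "
          f"(others < 0.1% of library reads -> invalid)")


if __name__ == "__main__":
    main()
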