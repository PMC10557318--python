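#!/usr/bin/env python
"""Simulate the study cohort: mini-genome, target panel, and read sets.

Builds a 35-target mini-genome (34 tumor-suppressor sites plus one editing
control), then generates with known ground truth:

* amplicon deep-sequencing reads for a parental single-cell clone and four
  subclones whose allele frequencies oscillate through gain/loss events;
* a gDNA-vs-eccDNA library pair: a rolling-circle-amplified eccDNA read
  set of 50 circles (ten of them carrying target sites with edited or
  intact alleles) plus a junction-free gDNA control.

Large FASTQ intermediates go to scratch/analysis/; the panel definition,
lineage ground truth, and circle truth tables go to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ecctrack.reference import write_reference, write_targets, targets_to_bed
from ecctrack.sim import (
    AlleleSpec,
    CircleSpec,
    LineageSpec,
    make_mini_genome,
    simulate_amplicon_reads,
    simulate_eccdna_library,
    simulate_lineage,
    write_fastq,
)

SEED = 2026
DEPTH = 4000          # reads per target per sample
ERR = 0.003           # Illumina-like substitution rate
READ_LEN = 150

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    ref, sites = make_mini_genome(n_targets=35, seed=SEED, extra_chrom_len=200_000)
    write_reference(ref, SCRATCH / "mini_genome.fasta")
    write_targets(sites, RESULTS / "target_panel.tsv")
    targets_to_bed(sites, RESULTS / "target_windows.bed")

    # ---- parental clone: a mixed mutation landscape over the panel ----
    # ground-truth labels are stored in canonical form for each target's
    # amplicon (a repeat-shiftable edit is named by its cut-proximal
    # leftmost placement, exactly as the classifier reports it); the first
    # target whose amplicon keeps the published p53 spectrum canonical
    # carries that spectrum verbatim, the rest get random indel spectra
    # with 1-3 alleles above the 5% rule
    from ecctrack.align import canonical_label
    from ecctrack.reference import site_on_protospacer_strand

    def canon(site, label):
        amp, cut = site_on_protospacer_strand(site, ref)
        return canonical_label(amp, cut, label)

    p53_mix = [("WT", 0.4188), ("Del1|0", 0.2812), ("Del0|7", 0.1613),
               ("Ins1A", 0.1387)]
    p53_gene = next(
        s.gene_id for s in sites
        if all(canon(s, l) == l for l, _ in p53_mix)
    )
    parent, pool = {}, {}
    candidates = ["Del1|0", "Del0|7", "Ins1A", "Ins1T", "Del2|0", "Del5|2",
                  "Del11|16", "Ins1G", "Del4|0", "Del22|5"]
    for s in sites:
        if s.gene_id == p53_gene:
            parent[s.gene_id] = [AlleleSpec(l, f) for l, f in p53_mix]
            pool[s.gene_id] = [canon(s, "Del7|3")]
            continue
        # unique canonical candidate labels on this amplicon
        cands = sorted({canon(s, l) for l in candidates} - {"WT"})
        k = int(rng.integers(1, 4))
        labels = list(rng.choice(cands, size=k, replace=False))
        f = rng.dirichlet(np.ones(k + 1) * 6)
        f = 0.12 + 0.76 * f
        f = f / f.sum()
        parent[s.gene_id] = [AlleleSpec("WT", float(f[0]))] + [
            AlleleSpec(l, float(fi)) for l, fi in zip(labels, f[1:])
        ]
        pool[s.gene_id] = [l for l in cands if l not in labels][:2]

    pd.DataFrame([{"key": "p53_style_gene", "value": p53_gene},
                  {"key": "seed", "value": SEED},
                  {"key": "depth", "value": DEPTH},
                  {"key": "err", "value": ERR}]) \
        .to_csv(RESULTS / "cohort_metadata.tsv", sep="\t", index=False)

    lineage = LineageSpec(parent=parent, n_subclones=4, p_loss=0.10, p_gain=0.12,
                          drift_sd=0.01, seed=SEED, gain_pool=pool,
                          gain_freq_range=(0.15, 0.35))
    samples, event_log = simulate_lineage(lineage)
    event_log.to_csv(RESULTS / "lineage_truth_events.tsv", sep="\t", index=False)

    site_by_gene = {s.gene_id: s for s in sites}
    for sample, genes in samples.items():
        reads, truths = [], []
        for gene in sorted(genes):
            r, t = simulate_amplicon_reads(
                site_by_gene[gene], ref, genes[gene], depth=DEPTH,
                read_len=READ_LEN, err=ERR, rng=rng, sample_id=sample,
            )
            reads += r
            truths.append(t)
        write_fastq(reads, SCRATCH / f"{sample}.fastq")
        pd.concat(truths, ignore_index=True).to_csv(
            SCRATCH / f"{sample}.truth.tsv", sep="\t", index=False
        )
        print(f"{sample}: {len(reads)} amplicon reads")

    truth_freqs = [
        {"sample": sample, "gene": gene, "label": a.label,
         "frequency_pct": a.frequency * 100}
        for sample, genes in samples.items()
        for gene, mix in genes.items() for a in mix
    ]
    pd.DataFrame(truth_freqs).to_csv(RESULTS / "lineage_truth_frequencies.tsv",
                                     sep="\t", index=False)

    # ---- eccDNA library: 10 target-carrying circles + 40 background ----
    alleles = ["Del22|5", "Del1|0", "Ins1A", "Del8|0 Ins4CCCG", "WT",
               "Del3|0", "Del0|7", "Ins1T", "Del11|16", "Del2|0"]
    circles = []
    for i, lab in enumerate(alleles):
        s = sites[i * 3]
        circles.append(CircleSpec(
            s.chrom, s.cut_pos - int(rng.integers(100, 250)),
            s.cut_pos + int(rng.integers(100, 300)),
            copy_number=2, mh_len=int(rng.integers(0, 6)), allele_at_target=lab,
        ))
    sizes = np.exp(rng.uniform(np.log(150), np.log(10_000), size=40)).astype(int)
    cursor = 200
    for sz in sizes:
        circles.append(CircleSpec("mini1_bg", cursor, cursor + int(sz),
                                  mh_len=int(rng.integers(0, 6))))
        cursor += int(sz) + 353
    edited, ecc_reads, ecc_truth = simulate_eccdna_library(
        circles, ref, frag_len=300, read_len=READ_LEN, depth_per_copy=60,
        err=ERR, rng=rng, sites=sites,
    )
    write_reference(edited, SCRATCH / "mini_genome.edited.fasta")
    write_fastq(ecc_reads, SCRATCH / "eccdna.fastq")
    # per-read truth is bulky; keep it with the reads, summarise in results
    ecc_truth.to_csv(SCRATCH / "eccdna_truth.tsv", sep="\t", index=False)
    ecc_truth.groupby("circle_id")["spans_junction"].sum() \
        .rename("junction_spanning_reads") \
        .to_csv(RESULTS / "eccdna_junction_read_counts.tsv", sep="\t")
    circle_rows = [
        {"circle_id": f"circle{i:03d}", "chrom": c.chrom, "start": c.start,
         "end": c.end, "size": c.size, "mh_len": c.mh_len,
         "copy_number": c.copy_number, "allele_at_target": c.allele_at_target or ""}
        for i, c in enumerate(circles)
    ]
    pd.DataFrame(circle_rows).to_csv(RESULTS / "circle_truth.tsv", sep="\t", index=False)
    print(f"eccDNA library: {len(circles)} circles, {len(ecc_reads)} reads")

    # gDNA control for the relative read ratio: every target at its
    # lineage-parent spectrum but from the same DNA (no circles)
    print("done; FASTQ under scratch/analysis/, truth tables under results/")


if __name__ == "__main__":
    main()
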