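#!/usr/bin/env python
"""Track allele oscillation from the parental clone to its subclones.

Builds the (gene, allele) x sample frequency matrix from the quantified
allele tables, detects gain/loss events against the parent, computes
allelic richness (flagging loci with more than two alleles above the
threshold, a copy-number signal in a single-cell clone), and compares the
detected events with the lineage simulator's ground-truth log.
"""

from pathlib import Path

import pandas as pd

from ecctrack.heterogeneity import (
    allele_richness,
    clone_count_per_type,
    matrix_long,
    oscillation_events,
    profile_matrix,
)
from ecctrack.quantify import read_allele_tables, sqrt_transform

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


SCRATCH = ROOT / "scratch" / "analysis"


def main():
    tables = read_allele_tables(SCRATCH / "allele_tables_full.tsv")
    profile = profile_matrix(tables)
    children = [s for s in profile.samples if s != "parent"]
    events = oscillation_events(profile, "parent", children)
    richness = allele_richness(profile)
    counts = clone_count_per_type(profile).rename("n_clones").reset_index()

    # exports keep alleles reaching 1% somewhere (noise labels stay in the
    # profile for the computations above but would swamp the tables)
    visible = profile.matrix[(profile.matrix >= 1.0).any(axis=1)]
    long = matrix_long(profile)
    long[long.groupby(["gene_id", "label"])["frequency"].transform("max") >= 1.0] \
        .to_csv(RESULTS / "lineage_matrix_long.tsv", sep="\t", index=False)
    sqrt_transform(visible / 100.0).to_csv(RESULTS / "lineage_sqrt_matrix.tsv", sep="\t")
    events.to_csv(RESULTS / "oscillation_events.tsv", sep="\t", index=False)
    richness.to_csv(RESULTS / "allele_richness.tsv", sep="\t", index=False)
    counts[counts.n_clones > 0].to_csv(RESULTS / "clone_counts_per_type.tsv",
                                       sep="\t", index=False)

    truth = pd.read_csv(RESULTS / "lineage_truth_events.tsv", sep="\t")
    detected = set(map(tuple, events[["sample", "gene", "label", "event"]].values))
    simulated = set(map(tuple, truth[["sample", "gene", "label", "event"]].values))
    tp = len(detected & simulated)
    print(f"samples: {profile.samples}")
    print(f"events detected: {len(detected)} (gain "
          f"{(events.event == 'gain').sum()}, loss {(events.event == 'loss').sum()})")
    print(f"ground-truth events: {len(simulated)}; matched: {tp}; "
          f"missed: {len(simulated - detected)}; extra: {len(detected - simulated)}")
    flagged = richness[richness.exceeds_diploid]
    print(f"gene/sample pairs with >2 alleles at the 5% rule: {len(flagged)} "
          f"(copy-number signal)")


if __name__ == "__main__":
    main()
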