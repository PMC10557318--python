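"""Allele-frequency comparison across related samples.

Builds the (gene, allele) x sample frequency matrix for a set of related
samples — a parental single-cell clone and its subclones, a time course of
one clone, or clones re-derived from grafts — and reports:

* gain/loss ("oscillation") events: an allele crossing the presence
  threshold tau between parent and child in either direction;
* per-sample allelic richness: how many alleles (WT included) a gene
  carries at >= tau, with a flag when richness exceeds 2 — more alleles
  than a diploid locus in a single-cell clone can explain;
* clone counts per mutation type: in how many samples an allele is present
  at >= tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .quantify import AlleleTable, TRUE_MUTATION_TAU


@dataclass
class LineageProfile:
    """Frequency matrix over related samples plus detected events."""

    samples: list[str]
    relations: dict[str, str]  # sample -> parent/subclone/timepoint/graft
    matrix: pd.DataFrame  # MultiIndex (gene_id, label) x samples, percent
    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample", "gene", "label", "event"])
    )


def profile_matrix(tables: list[AlleleTable],
                   relations: dict[str, str] | None = None) -> LineageProfile:
    """Union-of-labels frequency matrix; absent labels filled with 0%.

    Column order follows first appearance of each sample.  Raises on a
    duplicated (sample, gene) table or on samples with mismatched target
    sets.
    """
    samples: list[str] = []
    seen = set()
    genes_by_sample: dict[str, set] = {}
    for t in tables:
        key = (t.sample_id, t.gene_id)
        if key in seen:
            raise ValueError(f"duplicated sample/gene table {key}")
        seen.add(key)
        if t.sample_id not in samples:
            samples.append(t.sample_id)
        genes_by_sample.setdefault(t.sample_id, set()).add(t.gene_id)
    gene_sets = list(genes_by_sample.values())
    if any(gs != gene_sets[0] for gs in gene_sets[1:]):
        raise ValueError("samples do not share the same target set")

    records = {}
    for t in tables:
        if t.no_call:
            continue
        for _, row in t.rows.iterrows():
            records[(t.gene_id, row["label"], t.sample_id)] = row["frequency"]
    index = sorted({(g, l) for g, l, _ in records})
    matrix = pd.DataFrame(0.0, index=pd.MultiIndex.from_tuples(index, names=["gene_id", "label"]),
                          columns=samples)
    for (g, l, s), f in records.items():
        matrix.loc[(g, l), s] = f
    return LineageProfile(samples=samples, relations=relations or {}, matrix=matrix)


def clone_count_per_type(profile: LineageProfile, tau: float = TRUE_MUTATION_TAU) -> pd.Series:
    """Per (gene, label): number of samples carrying it at >= tau percent."""
    return (profile.matrix >= tau).sum(axis=1)


def proportion_per_type(profile: LineageProfile, tau: float = TRUE_MUTATION_TAU) -> pd.Series:
    """Per (gene, label): percent of samples carrying it at >= tau."""
    return clone_count_per_type(profile, tau) / len(profile.samples) * 100.0


def allele_richness(profile: LineageProfile, tau: float = TRUE_MUTATION_TAU) -> pd.DataFrame:
    """Alleles (WT included) at >= tau per (gene, sample), with a >2 flag.

    Richness above 2 in a single-cell clone signals more than two copies of
    the target locus.
    """
    present = profile.matrix >= tau
    rows = []
    for gene, sub in present.groupby(level="gene_id"):
        for sample in profile.samples:
            r = int(sub[sample].sum())
            rows.append({"gene_id": gene, "sample_id": sample,
                         "richness": r, "exceeds_diploid": r > 2})
    return pd.DataFrame(rows)


def oscillation_events(profile: LineageProfile, parent: str,
                       children: list[str],
                       tau: float = TRUE_MUTATION_TAU,
                       hysteresis: float = 0.0) -> pd.DataFrame:
    """Gain/loss events of each allele between a parent and its children.

    loss: parent >= tau and child < tau; gain: parent < tau and child >=
    tau.  WT participates like any allele.  ``hysteresis`` widens the band:
    a loss requires child < tau - hysteresis and a gain child >= tau +
    hysteresis, suppressing flicker near the threshold.
    """
    for s in [parent, *children]:
        if s not in profile.matrix.columns:
            raise ValueError(f"sample {s!r} not in profile")
    rows = []
    pcol = profile.matrix[parent]
    for child in children:
        ccol = profile.matrix[child]
        for (gene, label), pf in pcol.items():
            cf = ccol[(gene, label)]
            if pf >= tau and cf < tau - hysteresis:
                rows.append({"sample": child, "gene": gene, "label": label, "event": "loss"})
            elif pf < tau and cf >= tau + hysteresis:
                rows.append({"sample": child, "gene": gene, "label": label, "event": "gain"})
    events = pd.DataFrame(rows, columns=["sample", "gene", "label", "event"])
    profile.events = events
    return events


def consecutive_events(profile: LineageProfile, ordered_samples: list[str],
                       tau: float = TRUE_MUTATION_TAU) -> pd.DataFrame:
    """Chain comparison for time courses: each step treated as parent->child."""
    frames = [
        oscillation_events(profile, a, [b], tau)
        for a, b in zip(ordered_samples, ordered_samples[1:])
    ]
    events = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["sample", "gene", "label", "event"])
    profile.events = events
    return events


def matrix_long(profile: LineageProfile) -> pd.DataFrame:
    out = profile.matrix.stack().rename("frequency").reset_index()
    out.columns = ["gene_id", "label", "sample_id", "frequency"]
    return out


def render_heatmap(profile: LineageProfile, path, gene: str | None = None) -> None:
    """Optional presentation: sqrt-frequency heatmap (dark green high)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .quantify import sqrt_transform

    mat = profile.matrix if gene is None else profile.matrix.loc[gene]
    data = sqrt_transform(mat / 100.0)
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(data.columns)),
                                    max(3, 0.25 * len(data))))
    im = ax.imshow(data.values, aspect="auto", cmap="Greens", vmin=0, vmax=1)
    ax.set_xticks(range(len(data.columns)), data.columns, rotation=90, fontsize=7)
    labels = [" ".join(map(str, i)) if isinstance(i, tuple) else str(i)
              for i in data.index]
    ax.set_yticks(range(len(labels)), labels, fontsize=6)
    fig.colorbar(im, ax=ax, label="sqrt frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
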