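"""Per-target allele tables, mutation frequencies, thresholds and ratios.

The central quantities:

* allelic frequency — reads carrying one allele label divided by all
  retained reads of the gene, in percent;
* gene mutation frequency — total edited read count of a gene divided by
  its total read count (equivalently ``100 - frequency(WT)``);
* the "true mutation" rule — a non-WT allele counts as real only at a
  frequency of at least ``tau`` percent (default 5), the noise filter that
  keeps sequencing errors out of the tables;
* library-size percentages and the eccDNA/gDNA relative read ratio — each
  gene's share of its library's combined target reads, and the ratio of the
  eccDNA share to the gDNA share; genes drawing fewer than 0.1% of a
  library's reads are flagged invalid.

Discarded reads are excluded from numerator and denominator throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlleleCall

TRUE_MUTATION_TAU = 5.0  # percent
MIN_SITE_COVERAGE = 100  # retained reads; below this a site is a no-call
INVALID_SITE_FRACTION = 0.001  # < 0.1% of library reads -> invalid site


@dataclass
class AlleleTable:
    """Per-sample, per-gene allele counts and frequencies (percent)."""

    sample_id: str
    gene_id: str
    rows: pd.DataFrame  # columns: label, read_count, frequency, is_true_mutation
    total_reads: int
    gene_mutation_frequency: float | None
    no_call: bool = False
    n_discarded: int = 0

    def frequency_of(self, label: str) -> float:
        hit = self.rows.loc[self.rows["label"] == label, "frequency"]
        return float(hit.iloc[0]) if len(hit) else 0.0

    def true_mutations(self) -> pd.DataFrame:
        return self.rows[self.rows["is_true_mutation"]]


def build_allele_table(
    calls: "list[AlleleCall] | dict[str, int] | Counter",
    sample_id: str,
    gene_id: str,
    min_coverage: int = MIN_SITE_COVERAGE,
    tau: float = TRUE_MUTATION_TAU,
) -> AlleleTable:
    """Aggregate per-read calls (or a label->count mapping) into a table.

    Discarded calls are dropped; sites with fewer than ``min_coverage``
    retained reads become a no-call record with null frequencies rather
    than a spurious 0%.
    """
    n_discarded = 0
    if isinstance(calls, (dict, Counter)):
        counts = Counter(calls)
    else:
        counts = Counter()
        for call in calls:
            if call.retained:
                counts[call.label] += 1
            else:
                n_discarded += 1

    total = sum(counts.values())
    if total < min_coverage:
        rows = pd.DataFrame(columns=["label", "read_count", "frequency", "is_true_mutation"])
        return AlleleTable(sample_id, gene_id, rows, total, None,
                           no_call=True, n_discarded=n_discarded)

    labels = sorted(counts, key=lambda l: (-counts[l], l))
    rows = pd.DataFrame(
        {
            "label": labels,
            "read_count": [counts[l] for l in labels],
        }
    )
    rows["frequency"] = rows["read_count"] / total * 100.0
    rows["is_true_mutation"] = False
    table = AlleleTable(
        sample_id, gene_id, rows, total,
        gene_mutation_frequency=100.0 - (counts.get("WT", 0) / total * 100.0),
        n_discarded=n_discarded,
    )
    return apply_true_mutation_threshold(table, tau)


def apply_true_mutation_threshold(table: AlleleTable, tau: float = TRUE_MUTATION_TAU) -> AlleleTable:
    """Flag non-WT alleles at frequency >= tau percent (inclusive) as true."""
    if table.no_call:
        return table
    rows = table.rows
    rows["is_true_mutation"] = (rows["label"] != "WT") & (rows["frequency"] >= tau)
    return table


def sqrt_transform(frequency_matrix):
    """Elementwise square root of a frequency matrix with entries in [0, 1].

    Used for rendering lineage heatmaps, where the square-root scale keeps
    low-frequency alleles visible next to dominant ones.
    """
    arr = np.asarray(frequency_matrix, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("frequency matrix entries must lie in [0, 1]")
    out = np.sqrt(arr)
    if isinstance(frequency_matrix, pd.DataFrame):
        return pd.DataFrame(out, index=frequency_matrix.index,
                            columns=frequency_matrix.columns)
    return out


def libsize_percentages(read_counts: "dict[str, int] | pd.Series",
                        library_id: str = "") -> pd.Series:
    """Per-gene percentage of the library's combined target reads."""
    counts = pd.Series(read_counts, dtype=float)
    total = counts.sum()
    if len(counts) == 0 or total <= 0:
        raise ValueError(f"library {library_id!r} has no reads")
    pct = counts / total * 100.0
    pct.name = library_id or "pct_of_library"
    return pct


def flag_invalid_sites(read_counts: "dict[str, int] | pd.Series",
                       fraction: float = INVALID_SITE_FRACTION) -> pd.Series:
    """Boolean per gene: reads strictly below ``fraction`` of the library total."""
    counts = pd.Series(read_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("library total must be > 0")
    return counts < fraction * total


def relative_read_ratio(gdna_pcts: pd.Series, eccdna_pcts: pd.Series,
                        gdna_invalid: pd.Series | None = None,
                        eccdna_invalid: pd.Series | None = None) -> pd.DataFrame:
    """eccDNA% / gDNA% per gene, undefined where gDNA is invalid or zero.

    Both inputs come from :func:`libsize_percentages` over the same target
    panel; the ratio normalises away per-target PCR efficiency because both
    libraries share the primer pairs.
    """
    genes = gdna_pcts.index.union(eccdna_pcts.index)
    g = gdna_pcts.reindex(genes).fillna(0.0)
    e = eccdna_pcts.reindex(genes).fillna(0.0)
    gi = (gdna_invalid.reindex(genes).fillna(True).astype(bool)
          if gdna_invalid is not None else pd.Series(False, index=genes))
    ei = (eccdna_invalid.reindex(genes).fillna(True).astype(bool)
          if eccdna_invalid is not None else pd.Series(False, index=genes))
    defined = (~gi) & (g > 0)
    ratio = pd.Series(np.nan, index=genes, dtype=float)
    ratio[defined] = e[defined] / g[defined]
    return pd.DataFrame(
        {
            "gene_id": genes,
            "pct_of_library_gDNA": g.values,
            "pct_of_library_eccDNA": e.values,
            "relative_ratio": ratio.values,
            "invalid_gDNA": gi.values,
            "invalid_eccDNA": ei.values,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# tab-separated serialisation
# ---------------------------------------------------------------------------

def allele_tables_to_frame(tables: list[AlleleTable]) -> pd.DataFrame:
    """Long-format export: one row per (sample, gene, label)."""
    rows = []
    for t in tables:
        if t.no_call:
            rows.append({
                "sample_id": t.sample_id, "gene_id": t.gene_id, "label": None,
                "read_count": None, "frequency": None, "is_true_mutation": None,
                "total_reads": t.total_reads, "gene_mutation_frequency": None,
            })
            continue
        for _, r in t.rows.iterrows():
            rows.append({
                "sample_id": t.sample_id, "gene_id": t.gene_id,
                "label": r["label"], "read_count": r["read_count"],
                "frequency": r["frequency"],
                "is_true_mutation": r["is_true_mutation"],
                "total_reads": t.total_reads,
                "gene_mutation_frequency": t.gene_mutation_frequency,
            })
    return pd.DataFrame(rows, columns=[
        "sample_id", "gene_id", "label", "read_count", "frequency",
        "is_true_mutation", "total_reads", "gene_mutation_frequency",
    ])


def write_allele_tables(tables: list[AlleleTable], path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        allele_tables_to_frame(tables).to_csv(fh, sep="\t", index=False)


def read_allele_tables(path, tau: float = TRUE_MUTATION_TAU,
                       min_coverage: int = MIN_SITE_COVERAGE) -> list[AlleleTable]:
    df = pd.read_csv(path, sep="\t", comment="#")
    tables = []
    for (sample, gene), grp in df.groupby(["sample_id", "gene_id"], sort=False):
        if grp["label"].isna().all():
            t = build_allele_table({}, sample, gene, min_coverage, tau)
            t.total_reads = int(grp["total_reads"].iloc[0])
            tables.append(t)
            continue
        counts = dict(zip(grp["label"], grp["read_count"].astype(int)))
        tables.append(build_allele_table(counts, sample, gene, min_coverage, tau))
    return tables
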