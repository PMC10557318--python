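"""Reference sequences, sgRNA target sites, and the Cas9 cut coordinate.

A :class:`TargetSite` records one SpCas9 target: a 20-nt protospacer, its
NGG PAM, and the blunt double-strand-break coordinate placed 3 bp 5' of the
PAM on the protospacer strand.  All coordinates are 0-based and half-open;
``cut_pos`` is an inter-base coordinate on the plus strand of the named
reference sequence.  A :class:`Reference` bundles the (mini-)genome with an
optional genic annotation (promoter / UTR / exon / intron intervals) used to
categorise eccDNA origins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

#: column order of the tab-separated target-definition table
TARGET_COLUMNS = ["gene", "chrom", "strand", "protospacer", "pam", "protospacer_start"]

#: annotation categories, highest priority first
ANNOTATION_CATEGORIES = ["promoter", "5'UTR", "exon", "3'UTR", "intron"]

PROTOSPACER_LEN = 20
#: SpCas9 cuts bluntly between protospacer bases 17 and 18 (1-based),
#: i.e. 3 bp 5' of the PAM on the protospacer strand.
CUT_OFFSET = 17

_GFF_TYPE_MAP = {
    "promoter": "promoter",
    "five_prime_UTR": "5'UTR",
    "exon": "exon",
    "three_prime_UTR": "3'UTR",
    "intron": "intron",
}


class TargetValidationError(ValueError):
    """A target-site row is inconsistent with the reference."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _is_ngg(pam: str) -> bool:
    return len(pam) == 3 and pam[1:] == "GG" and pam[0] in "ACGTN"


@dataclass(frozen=True)
class TargetSite:
    """One sgRNA target site on a reference sequence.

    ``protospacer_start`` is the plus-strand offset of the protospacer's
    leftmost base regardless of strand; for minus-strand sites the stored
    ``protospacer`` / ``pam`` strings read 5'->3' on the minus strand.
    """

    gene_id: str
    chrom: str
    strand: str
    protospacer: str
    pam: str
    protospacer_start: int
    cut_pos: int
    window_halfwidth: int = 25

    def window(self) -> tuple[int, int]:
        """Classification window ``[cut - w, cut + w)`` on the plus strand."""
        return self.cut_pos - self.window_halfwidth, self.cut_pos + self.window_halfwidth


@dataclass
class Reference:
    """Named DNA sequences plus optional typed genic annotation."""

    sequences: dict[str, str]
    annotation: dict[str, IntervalTree] = field(default_factory=dict)

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def copy(self) -> "Reference":
        return Reference(dict(self.sequences), self.annotation)


def load_reference(fasta_path, annotation_path=None) -> Reference:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    ref = Reference(seqs)
    if annotation_path is not None:
        ref.annotation = load_annotation(annotation_path, ref)
    return ref


def write_reference(ref: Reference, fasta_path) -> None:
    with open(fasta_path, "w") as fh:
        for name, seq in ref.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def infer_cut_site(strand: str, protospacer_start: int) -> int:
    """Plus-strand inter-base cut coordinate for a validated protospacer.

    Plus strand: protospacer occupies ``[s, s+20)``, PAM ``[s+20, s+23)``,
    cut at ``s + 17``.  Minus strand: protospacer occupies plus-strand
    ``[s, s+20)`` with the PAM at ``[s-3, s)``; counting 17 bases along the
    protospacer strand (right to left) puts the cut at plus coordinate
    ``s + 3``.
    """
    if strand == "+":
        return protospacer_start + CUT_OFFSET
    if strand == "-":
        return protospacer_start + (PROTOSPACER_LEN - CUT_OFFSET)
    raise TargetValidationError(f"malformed strand {strand!r}")


def validate_site(site: TargetSite, ref: Reference) -> None:
    """Check protospacer/PAM identity against the reference, or raise."""
    if site.chrom not in ref.sequences:
        raise TargetValidationError(f"{site.gene_id}: unknown sequence {site.chrom!r}")
    seq = ref.sequences[site.chrom]
    s = site.protospacer_start
    if site.strand == "+":
        geno_proto = seq[s : s + PROTOSPACER_LEN]
        geno_pam = seq[s + PROTOSPACER_LEN : s + PROTOSPACER_LEN + 3]
    elif site.strand == "-":
        geno_proto = revcomp(seq[s : s + PROTOSPACER_LEN])
        geno_pam = revcomp(seq[s - 3 : s])
    else:
        raise TargetValidationError(f"{site.gene_id}: malformed strand {site.strand!r}")
    if geno_proto != site.protospacer.upper():
        raise TargetValidationError(
            f"{site.gene_id}: protospacer mismatch at {site.chrom}:{s} "
            f"({geno_proto!r} in reference vs {site.protospacer!r})"
        )
    if geno_pam != site.pam.upper():
        raise TargetValidationError(
            f"{site.gene_id}: PAM mismatch ({geno_pam!r} in reference vs {site.pam!r})"
        )
    if not _is_ngg(site.pam.upper()):
        raise TargetValidationError(f"{site.gene_id}: PAM {site.pam!r} does not match NGG")
    lo, hi = s, s + PROTOSPACER_LEN
    if not lo < site.cut_pos < hi:
        raise TargetValidationError(
            f"{site.gene_id}: cut_pos {site.cut_pos} outside protospacer footprint [{lo},{hi})"
        )


def load_targets(path, ref: Reference, window_halfwidth: int = 25) -> list[TargetSite]:
    """Read a tab-separated target table and return validated TargetSites.

    Required columns: gene, chrom, strand, protospacer, pam,
    protospacer_start.  Duplicate gene ids are rejected; two targets sharing
    a cut coordinate are both retained with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in TARGET_COLUMNS if c not in df.columns]
    if missing:
        raise TargetValidationError(f"target table missing columns: {missing}")
    sites: list[TargetSite] = []
    seen_genes: set[str] = set()
    cut_seen: dict[tuple[str, int], str] = {}
    for idx, row in df.iterrows():
        gene = str(row["gene"])
        if gene in seen_genes:
            raise TargetValidationError(f"row {idx}: duplicate gene_id {gene!r}")
        seen_genes.add(gene)
        strand = str(row["strand"])
        try:
            start = int(row["protospacer_start"])
        except (TypeError, ValueError) as exc:
            raise TargetValidationError(f"row {idx} ({gene}): bad protospacer_start") from exc
        site = TargetSite(
            gene_id=gene,
            chrom=str(row["chrom"]),
            strand=strand,
            protospacer=str(row["protospacer"]).upper(),
            pam=str(row["pam"]).upper(),
            protospacer_start=start,
            cut_pos=infer_cut_site(strand, start),
            window_halfwidth=window_halfwidth,
        )
        try:
            validate_site(site, ref)
        except TargetValidationError as exc:
            raise TargetValidationError(f"row {idx}: {exc}") from exc
        key = (site.chrom, site.cut_pos)
        if key in cut_seen:
            log.warning(
                "targets %s and %s share cut coordinate %s:%d",
                cut_seen[key], gene, site.chrom, site.cut_pos,
            )
        cut_seen[key] = gene
        sites.append(site)
    return sites


def write_targets(sites: list[TargetSite], path) -> None:
    rows = [
        {
            "gene": s.gene_id,
            "chrom": s.chrom,
            "strand": s.strand,
            "protospacer": s.protospacer,
            "pam": s.pam,
            "protospacer_start": s.protospacer_start,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=TARGET_COLUMNS).to_csv(path, sep="\t", index=False)


def targets_to_bed(sites: list[TargetSite], path) -> None:
    """Export classification windows as BED6 (0-based, half-open)."""
    with open(path, "w") as fh:
        for s in sites:
            lo, hi = s.window()
            fh.write(f"{s.chrom}\t{max(lo, 0)}\t{hi}\t{s.gene_id}\t0\t{s.strand}\n")


def load_annotation(path, ref: Reference) -> dict[str, IntervalTree]:
    """Load genic annotation intervals from BED (name = category) or GFF3.

    GFF3 feature types promoter / five_prime_UTR / exon / three_prime_UTR /
    intron are mapped onto the annotation categories; other types ignored.
    """
    path = str(path)
    trees: dict[str, IntervalTree] = {}

    def add(chrom, start, end, category):
        if category not in ANNOTATION_CATEGORIES:
            return
        if chrom not in ref.sequences:
            raise TargetValidationError(f"annotation on unknown sequence {chrom!r}")
        if not (0 <= start < end <= len(ref.sequences[chrom])):
            raise TargetValidationError(
                f"annotation interval {chrom}:{start}-{end} out of bounds"
            )
        trees.setdefault(chrom, IntervalTree()).addi(start, end, category)

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 8 and fields[3].isdigit() and fields[4].isdigit():
                # GFF3: seqid source type start end ... (1-based closed)
                chrom, _, ftype, start, end = fields[:5]
                cat = _GFF_TYPE_MAP.get(ftype)
                if cat:
                    add(chrom, int(start) - 1, int(end), cat)
            elif len(fields) >= 4:
                # BED: chrom start end name (0-based half-open)
                chrom, start, end, name = fields[:4]
                add(chrom, int(start), int(end), name)
            else:
                raise TargetValidationError(f"unparseable annotation line: {line!r}")
    return trees


def site_on_protospacer_strand(site: TargetSite, ref: Reference,
                               halfwidth: int = 120) -> tuple[str, int]:
    """Local amplicon around the cut, oriented to the protospacer strand.

    Returns ``(amplicon, cut_offset)`` where ``cut_offset`` is the cut's
    inter-base coordinate within the amplicon.  Used both by the read
    simulator and by classification, so allele labels for minus-strand
    targets are always reported in protospacer-strand orientation.
    """
    seq = ref.sequences[site.chrom]
    lo = max(0, site.cut_pos - halfwidth)
    hi = min(len(seq), site.cut_pos + halfwidth)
    amp = seq[lo:hi]
    cut = site.cut_pos - lo
    if site.strand == "-":
        amp = revcomp(amp)
        cut = len(amp) - cut
    return amp, cut


def with_window(site: TargetSite, window_halfwidth: int) -> TargetSite:
    return replace(site, window_halfwidth=window_halfwidth)
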