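"""Synthetic sequencing data with known ground truth.

Three generators emulate the study designs the pipeline consumes:

* :func:`simulate_amplicon_reads` — targeted PCR amplicon deep-sequencing
  read sets drawn multinomially from a specified allele mixture, with a
  uniform substitution error rate;
* :func:`simulate_lineage` — clonal lineages whose allele frequencies
  oscillate through discrete gain/loss events plus truncated Gaussian
  drift;
* :func:`simulate_eccdna_library` — rolling-circle-amplified eccDNA
  libraries: each circle is concatemerised (>=3 tandem copies), fragmented
  uniformly and sequenced paired-end, so a known subset of reads spans the
  circularization junction; optional junction microhomology is engineered
  into the reference.

All randomness flows through one explicitly passed seeded generator, and a
fixed seed yields byte-identical FASTQ output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import apply_allele, parse_label
from .reference import Reference, TargetSite, revcomp, site_on_protospacer_strand

#: constant Q30-equivalent base quality; qualities are never used downstream
QUAL_CHAR = "?"

BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class AlleleSpec:
    """One allele of a target site at a specified population frequency."""

    label: str
    frequency: float

    def __post_init__(self):
        parse_label(self.label) if self.label != "WT" else None
        if not 0.0 <= self.frequency <= 1.0:
            raise SimulationError(f"frequency {self.frequency} outside [0, 1]")


def check_allele_mix(alleles: list[AlleleSpec], tol: float = 1e-9) -> None:
    total = sum(a.frequency for a in alleles)
    if abs(total - 1.0) > tol:
        raise SimulationError(f"allele frequencies sum to {total}, not 1")
    labels = [a.label for a in alleles]
    if len(set(labels)) != len(labels):
        raise SimulationError("duplicate allele labels in mixture")


@dataclass
class FastqRead:
    read_id: str
    seq: str

    def to_fastq(self) -> str:
        return f"@{self.read_id}\n{self.seq}\n+\n{QUAL_CHAR * len(self.seq)}\n"


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(r.to_fastq())


def read_fastq(path) -> list[FastqRead]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            reads.append(FastqRead(header.strip()[1:].split()[0], seq))
    return reads


def _add_substitutions(seq: str, err: float, rng: np.random.Generator) -> str:
    if err <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < err)[0]
    for i in hits:
        orig = arr[i].decode()
        choices = [b for b in "ACGT" if b != orig]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# mini-genome construction
# ---------------------------------------------------------------------------

def make_mini_genome(
    n_targets: int = 35,
    spacing: int = 3000,
    seed: int = 0,
    window_halfwidth: int = 25,
    annotate: bool = True,
    chrom: str = "mini1",
    extra_chrom_len: int = 0,
):
    """A random mini-genome with validated sgRNA target sites planted in.

    Emulates the study panel: ``n_targets`` sites (by default 34 tumor
    suppressor targets named TSG01..TSG34 plus one editing control named
    CTRL), one per ``spacing`` bp, alternating strands, each with an NGG
    PAM written into the sequence.  With ``annotate`` a simple gene model
    (promoter, 5'UTR, exon, intron, 3'UTR) is laid around every target so
    eccDNA annotation has realistic categories.  Returns ``(ref, sites)``.
    """
    from .reference import (
        Reference,
        TargetSite,
        infer_cut_site,
        validate_site,
    )
    from intervaltree import IntervalTree

    rng = np.random.default_rng(seed)
    length = 1000 + n_targets * spacing + 1000
    seq = list("".join(rng.choice(BASES, size=length)))
    sites = []
    for i in range(n_targets):
        pos = 1500 + i * spacing
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            seq[pos + 21] = "G"
            seq[pos + 22] = "G"
        else:
            seq[pos - 3] = "C"
            seq[pos - 2] = "C"
        gene = f"TSG{i + 1:02d}" if i < n_targets - 1 else "CTRL"
        proto = "".join(seq[pos : pos + 20])
        if strand == "+":
            pam = "".join(seq[pos + 20 : pos + 23])
        else:
            proto = revcomp(proto)
            pam = revcomp("".join(seq[pos - 3 : pos]))
        sites.append(
            TargetSite(
                gene_id=gene, chrom=chrom, strand=strand, protospacer=proto,
                pam=pam, protospacer_start=pos,
                cut_pos=infer_cut_site(strand, pos),
                window_halfwidth=window_halfwidth,
            )
        )
    sequences = {chrom: "".join(seq)}
    if extra_chrom_len:
        # an unannotated, target-free sequence (e.g. for background eccDNA)
        sequences[chrom + "_bg"] = "".join(rng.choice(BASES, size=extra_chrom_len))
    ref = Reference(sequences)
    for s in sites:
        validate_site(s, ref)
    if annotate:
        tree = IntervalTree()
        for i in range(n_targets):
            pos = 1500 + i * spacing
            # promoter - 5'UTR - exon - intron - exon - 3'UTR around the site
            tree.addi(pos - 900, pos - 600, "promoter")
            tree.addi(pos - 600, pos - 450, "5'UTR")
            tree.addi(pos - 450, pos + 150, "exon")
            tree.addi(pos + 150, pos + 800, "intron")
            tree.addi(pos + 800, pos + 1000, "exon")
            tree.addi(pos + 1000, pos + 1150, "3'UTR")
        ref.annotation = {chrom: tree}
    return ref, sites


# ---------------------------------------------------------------------------
# amplicon reads
# ---------------------------------------------------------------------------

def simulate_amplicon_reads(
    site: TargetSite,
    ref: Reference,
    alleles: list[AlleleSpec],
    depth: int,
    read_len: int = 150,
    err: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    sample_id: str = "S",
    amp_halfwidth: int = 120,
) -> tuple[list[FastqRead], pd.DataFrame]:
    """Simulate one target's amplicon read set.

    Reads are drawn multinomially from the allele frequencies; each read is
    a ``read_len`` substring of the mutated amplicon guaranteed to span the
    site's classification window, with substitution errors at rate ``err``.
    Returns the reads and a ground-truth table (read_id, gene_id,
    true_label).
    """
    if depth < 1:
        raise SimulationError("depth must be >= 1")
    check_allele_mix(alleles)
    rng = rng if rng is not None else np.random.default_rng(seed)
    amp, cut = site_on_protospacer_strand(site, ref, amp_halfwidth)
    w = site.window_halfwidth

    mutated = {}
    for spec in alleles:
        a, b, ins = parse_label(spec.label)
        if cut - a < 0 or cut + b > len(amp):
            raise SimulationError(
                f"{site.gene_id}: allele {spec.label!r} extends past the amplicon"
            )
        mutated[spec.label] = (apply_allele(amp, cut, spec.label), a, b, len(ins))

    counts = rng.multinomial(depth, [a.frequency for a in alleles])
    reads: list[FastqRead] = []
    truth_rows = []
    idx = 0
    for spec, n in zip(alleles, counts):
        mut, a, b, n_ins = mutated[spec.label]
        net = n_ins - a - b
        # read must cover the (reference-frame) window [cut-w, cut+w),
        # which in mutated coordinates is [cut-w, cut+w+net] at most
        lo_req = cut - w - 1
        hi_req = cut + w + max(net, 0) + 1
        if read_len >= len(mut):
            starts = np.zeros(n, dtype=int)
            rl = len(mut)
        else:
            smin = max(0, hi_req - read_len)
            smax = min(lo_req, len(mut) - read_len)
            if smax < smin:
                raise SimulationError(
                    f"{site.gene_id}: read_len {read_len} cannot span the window"
                )
            starts = rng.integers(smin, smax + 1, size=n)
            rl = read_len
        for s in starts:
            seq = _add_substitutions(mut[s : s + rl], err, rng)
            rid = f"{sample_id}|{site.gene_id}|{idx:06d}"
            reads.append(FastqRead(rid, seq))
            truth_rows.append((rid, site.gene_id, spec.label))
            idx += 1
    truth = pd.DataFrame(truth_rows, columns=["read_id", "gene_id", "true_label"])
    return reads, truth


# ---------------------------------------------------------------------------
# clonal lineages
# ---------------------------------------------------------------------------

@dataclass
class LineageSpec:
    """Generative model of allele oscillation across subclones.

    The observed behaviour being emulated is that predominant alleles of a
    parental clone can vanish in a subclone while previously negligible
    alleles can rise above the detection threshold; mechanism (eccDNA
    reintegration, hyperploidy drift) is deliberately not modelled.
    """

    parent: dict[str, list[AlleleSpec]]  # gene -> allele mixture
    n_subclones: int
    p_loss: float = 0.0
    p_gain: float = 0.0
    drift_sd: float = 0.0
    seed: int | None = None
    #: candidate alleles that a gain event may introduce, per gene
    gain_pool: dict[str, list[str]] = field(default_factory=dict)
    #: gained alleles are drawn uniformly from this frequency range
    gain_freq_range: tuple[float, float] = (0.10, 0.40)
    #: forced (sample_index, gene, label, "gain"/"loss"[, freq]) events
    forced_events: list[tuple] = field(default_factory=list)

    def __post_init__(self):
        for p in (self.p_loss, self.p_gain):
            if not 0.0 <= p <= 1.0:
                raise SimulationError("event probabilities must lie in [0, 1]")
        for gene, mix in self.parent.items():
            check_allele_mix(mix)


def simulate_lineage(spec: LineageSpec) -> tuple[dict[str, dict[str, list[AlleleSpec]]], pd.DataFrame]:
    """Derive subclone allele mixtures from a parent by gain/loss events.

    Each subclone applies, per gene: independent loss (frequency -> 0) of
    each parental allele with probability ``p_loss``; gain of a dormant
    allele (from ``gain_pool``) with probability ``p_gain``; truncated
    Gaussian jitter of sd ``drift_sd``; then renormalisation to 1.  Every
    gain/loss is logged with its sample and allele.  Raises if a gene would
    lose all alleles in a sample.
    """
    rng = np.random.default_rng(spec.seed)
    samples: dict[str, dict[str, list[AlleleSpec]]] = {"parent": spec.parent}
    events = []
    forced = {}
    for ev in spec.forced_events:
        i, gene, label, kind = ev[:4]
        freq = ev[4] if len(ev) > 4 else None
        forced.setdefault(i, []).append((gene, label, kind, freq))

    for i in range(spec.n_subclones):
        name = f"subclone{i + 1}"
        clone: dict[str, list[AlleleSpec]] = {}
        this_forced = forced.get(i, [])
        for gene, mix in spec.parent.items():
            freqs = {a.label: a.frequency for a in mix}
            # losses: drawn per allele, conditioned on one allele surviving
            # (a clone always retains some genotype); forced losses are
            # applied unconditionally and may legitimately error below
            for label in list(freqs):
                force_loss = any(
                    g == gene and l == label and k == "loss"
                    for g, l, k, _ in this_forced
                )
                chance_loss = spec.p_loss and rng.random() < spec.p_loss
                if freqs[label] <= 0:
                    continue
                survivors = sum(1 for f in freqs.values() if f > 0)
                if force_loss or (chance_loss and survivors > 1):
                    freqs[label] = 0.0
                    events.append((name, gene, label, "loss"))
            # gains
            pool = [l for l in spec.gain_pool.get(gene, []) if freqs.get(l, 0.0) == 0.0]
            for g, label, kind, f in this_forced:
                if g == gene and kind == "gain":
                    lo, hi = spec.gain_freq_range
                    freqs[label] = f if f is not None else rng.uniform(lo, hi)
                    events.append((name, gene, label, "gain"))
            for label in pool:
                if spec.p_gain and rng.random() < spec.p_gain:
                    lo, hi = spec.gain_freq_range
                    freqs[label] = rng.uniform(lo, hi)
                    events.append((name, gene, label, "gain"))
            # drift
            if spec.drift_sd > 0:
                for label in freqs:
                    if freqs[label] > 0:
                        freqs[label] = max(0.0, freqs[label] + rng.normal(0, spec.drift_sd))
            total = sum(freqs.values())
            if total <= 0:
                raise SimulationError(f"{name}: all alleles lost at {gene}")
            clone[gene] = [
                AlleleSpec(label, f / total) for label, f in freqs.items() if f > 0
            ]
        samples[name] = clone
    log = pd.DataFrame(events, columns=["sample", "gene", "label", "event"])
    return samples, log


# ---------------------------------------------------------------------------
# eccDNA libraries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircleSpec:
    """One eccDNA to simulate: a reference interval joined into a circle."""

    chrom: str
    start: int
    end: int
    copy_number: int = 1
    mh_len: int = 0
    allele_at_target: str | None = None

    def __post_init__(self):
        size = self.end - self.start
        if not 150 <= size <= 10_000:
            raise SimulationError(
                f"circle size {size} outside the supported 150-10000 bp range"
            )
        if self.mh_len < 0:
            raise SimulationError("mh_len must be >= 0")

    @property
    def size(self) -> int:
        return self.end - self.start


def _engineer_microhomology(seq: list, start: int, end: int, mh: int) -> None:
    """Edit ``seq`` in place so the junction is shift-ambiguous by ``mh`` bp.

    Copies the ``mh`` bases at the circle's start onto the bases just after
    its end, making placements (start+s, end+s), s <= mh, sequence
    equivalent; then breaks any accidental equivalence one base beyond on
    either side so the canonical (leftmost) coordinates stay exactly
    (start, end) with microhomology length exactly ``mh``.
    """
    for k in range(mh):
        seq[end + k] = seq[start + k]
    if start > 0 and seq[start - 1] == seq[end - 1]:
        seq[start - 1] = _other_base(seq[end - 1])
    if end + mh < len(seq) and seq[start + mh] == seq[end + mh]:
        seq[end + mh] = _other_base(seq[start + mh])


def _other_base(b: str) -> str:
    return {"A": "C", "C": "A", "G": "T", "T": "G"}.get(b, "A")


def circle_sequence(circle: CircleSpec, ref: Reference,
                    sites: list[TargetSite] | None = None) -> str:
    """The circle's linearised sequence, with its target allele applied."""
    seq = ref.sequences[circle.chrom][circle.start : circle.end]
    if circle.allele_at_target:
        if not sites:
            raise SimulationError("allele_at_target requires target sites")
        inside = [
            s for s in sites
            if s.chrom == circle.chrom and circle.start < s.cut_pos < circle.end
        ]
        if not inside:
            raise SimulationError(
                f"no target site inside circle {circle.chrom}:{circle.start}-{circle.end}"
            )
        site = inside[0]
        cut_local = site.cut_pos - circle.start
        if site.strand == "-":
            seq = apply_allele(revcomp(seq), len(seq) - cut_local, circle.allele_at_target)
            seq = revcomp(seq)
        else:
            seq = apply_allele(seq, cut_local, circle.allele_at_target)
    return seq


def simulate_eccdna_library(
    circles: list[CircleSpec],
    ref: Reference,
    frag_len: int = 500,
    read_len: int = 150,
    depth_per_copy: int = 30,
    err: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    sites: list[TargetSite] | None = None,
    min_tandem_copies: int = 3,
) -> tuple[Reference, list[FastqRead], pd.DataFrame]:
    """Simulate a rolling-circle-amplified, paired-end eccDNA library.

    Returns ``(edited_ref, reads, truth)``.  ``edited_ref`` is a copy of
    the reference with any requested junction microhomology engineered in
    (detection must run against it).  The truth table maps each read to its
    circle and marks junction-spanning reads (``n_junctions`` counts how
    many tandem-copy boundaries the read crosses; >1 means the circle is
    shorter than the read and the read wraps).
    """
    if frag_len < read_len:
        raise SimulationError("frag_len must be >= read_len")
    rng = rng if rng is not None else np.random.default_rng(seed)

    edited = ref.copy()
    for c in circles:
        if not (0 <= c.start < c.end <= len(edited.sequences[c.chrom])):
            raise SimulationError(f"circle {c.chrom}:{c.start}-{c.end} outside reference")
        if c.mh_len > 0:
            seq = list(edited.sequences[c.chrom])
            _engineer_microhomology(seq, c.start, c.end, c.mh_len)
            edited.sequences[c.chrom] = "".join(seq)

    reads: list[FastqRead] = []
    rows = []
    for ci, c in enumerate(circles):
        cid = f"circle{ci:03d}"
        cs = circle_sequence(c, edited, sites)
        L = len(cs)
        n_copies = max(min_tandem_copies, math.ceil((frag_len + L) / L) + 1)
        cat = cs * n_copies
        junctions = [k * L for k in range(1, n_copies)]
        n_frags = depth_per_copy * c.copy_number
        starts = rng.integers(0, len(cat) - frag_len + 1, size=n_frags)
        for fi, fs in enumerate(starts):
            frag = cat[fs : fs + frag_len]
            r1 = frag[:read_len]
            r2 = revcomp(frag[-read_len:])
            for mate, seq, lo, hi in (
                (1, r1, fs, fs + read_len),
                (2, r2, fs + frag_len - read_len, fs + frag_len),
            ):
                nj = sum(1 for j in junctions if lo < j < hi)
                rid = f"{cid}|frag{fi:05d}/{mate}"
                reads.append(FastqRead(rid, _add_substitutions(seq, err, rng)))
                rows.append((rid, cid, c.chrom, c.start, c.end, mate, nj > 0, nj))
    truth = pd.DataFrame(
        rows,
        columns=["read_id", "circle_id", "chrom", "start", "end",
                 "mate", "spans_junction", "n_junctions"],
    )
    return edited, reads, truth
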