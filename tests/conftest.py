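"""Shared fixtures: a deterministic mini-genome with planted target sites."""

import numpy as np
import pytest

from ecctrack.reference import Reference, TargetSite, site_on_protospacer_strand
from ecctrack.sim import make_mini_genome


@pytest.fixture(scope="session")
def mini():
    """Full-size panel: 34 TSG targets + 1 control on a mini-genome."""
    ref, sites = make_mini_genome(n_targets=35, seed=123)
    return ref, sites


@pytest.fixture(scope="session")
def small_panel():
    """Six-target panel for cheaper end-to-end runs."""
    ref, sites = make_mini_genome(n_targets=6, seed=77)
    return ref, sites


def _plant_plus_site(seq: str, start: int, gene: str = "g1") -> TargetSite:
    from ecctrack.reference import infer_cut_site

    return TargetSite(
        gene_id=gene, chrom="chr", strand="+",
        protospacer=seq[start : start + 20],
        pam=seq[start + 20 : start + 23],
        protospacer_start=start,
        cut_pos=infer_cut_site("+", start),
    )


@pytest.fixture(scope="session")
def plus_site():
    """A single plus-strand site on a 3 kb random sequence.

    The sequence is fixed by seed; the printed-spectrum allele labels
    (Del1|0, Del0|7, Ins1A) are canonical (not repeat-shiftable) on it,
    asserted as a precondition where a test depends on that.
    """
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), 3000))
    seq = seq[:1020] + "A" + "GG" + seq[1023:]
    ref = Reference({"chr": seq})
    site = _plant_plus_site(seq, 1000, "p53like")
    return ref, site


@pytest.fixture(scope="session")
def plus_amplicon(plus_site):
    ref, site = plus_site
    amp, cut = site_on_protospacer_strand(site, ref)
    return amp, cut
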