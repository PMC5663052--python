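"""Shared fixtures: hand-built toy genes, small simulations, and an
independent brute-force read-classification oracle used to validate the
rule-based classifier."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

import splicenoise as sn
from splicenoise.annotation import GeneModel, GenomeAnnotation, Intron, PCI


def build_gene(pieces, strand="+", pad=10, contig="c1", gene_id="gA"):
    """Assemble a single-gene genome from coding-strand pieces.

    ``pieces`` is a list of ("exon"|"intron", sequence) in transcription
    order; CDS equals the exons. Returns (GenomeAnnotation, GeneModel).
    """
    region = "".join(seq for _, seq in pieces)
    oriented = region if strand == "+" else str(Seq(region).reverse_complement())
    forward = "A" * pad + oriented + "A" * pad
    start = pad
    exons = []
    off = 0
    for kind, seq in pieces:
        if kind == "exon":
            if strand == "+":
                exons.append((start + off, start + off + len(seq)))
            else:
                exons.append(
                    (start + len(region) - off - len(seq), start + len(region) - off)
                )
        off += len(seq)
    gene = GeneModel(
        id=gene_id, contig=contig, strand=strand, exons=exons, cds=list(exons)
    )
    genome = GenomeAnnotation(sequences={contig: forward}, genes=[gene])
    return genome, gene


@pytest.fixture(scope="session")
def small_sim():
    params = sn.TruthParams(n_genes=80, seed=7)
    genome, truth = sn.generate_genome(params)
    return params, genome, truth


@pytest.fixture(scope="session")
def mid_sim():
    params = sn.TruthParams(n_genes=600, seed=7)
    genome, truth = sn.generate_genome(params)
    return params, genome, truth


# ---------------------------------------------------------------------------
# brute-force oracle: a literal, set-based re-statement of the rules,
# sharing no code with splicenoise.events
# ---------------------------------------------------------------------------


def oracle_classify_intron(read, intron, genome, min_anchor=1):
    s, e = intron.interval
    if read.contig != intron.contig:
        return "not_spanning"
    covered = set()
    for bs, be in read.blocks:
        covered |= set(range(bs, be))
    has_left = any(p <= s - min_anchor for p in covered)
    has_right = any(p >= e + min_anchor - 1 for p in covered)
    if not (has_left and has_right):
        return "not_spanning"
    gaps = [
        (b1[1], b2[0]) for b1, b2 in zip(read.blocks, read.blocks[1:])
    ]
    intron_positions = set(range(s, e))
    overlapping = [g for g in gaps if set(range(*g)) & intron_positions]
    if not overlapping:
        return "IR" if intron_positions <= covered else "not_spanning"
    contig_seq = genome.sequences[read.contig]
    for gs, ge in overlapping:
        gap_seq = contig_seq[gs:ge]
        if intron.strand == "-":
            gap_seq = str(Seq(gap_seq).reverse_complement())
        if not (gap_seq[:2] == "GT" and gap_seq[-2:] == "AG"):
            return "discarded"
    if overlapping == [(s, e)]:
        return "canonical"
    return "ASSV"


def oracle_classify_pci(read, pci, min_anchor=1):
    s, e = pci.interval
    if read.contig != pci.contig:
        return "not_spanning"
    covered = set()
    for bs, be in read.blocks:
        covered |= set(range(bs, be))
    has_left = any(p <= s - min_anchor for p in covered)
    has_right = any(p >= e + min_anchor - 1 for p in covered)
    if not (has_left and has_right):
        return "not_spanning"
    gaps = [(b1[1], b2[0]) for b1, b2 in zip(read.blocks, read.blocks[1:])]
    if (s, e) in gaps:
        return "spliced"
    if set(range(s, e)) <= covered:
        return "unspliced"
    return "not_spanning"


def make_classification_instance(rng: np.random.Generator):
    """One random read x element instance on a random 240-nt contig.

    Plants a GT..AG intron at [100, 125) (coding strand of a random strand)
    and a PCI at [150, 172), then draws a read from a scenario mix covering
    exact, ungapped, shifted (with or without GT/AG), multi-gap, partial and
    off-target alignments.
    """
    strand = rng.choice(["+", "-"])
    seq = list(rng.choice(list("ACGT"), size=240))

    def plant(iv, donor, acceptor):
        if strand == "+":
            seq[iv[0] : iv[0] + 2] = list(donor)
            seq[iv[1] - 2 : iv[1]] = list(acceptor)
        else:  # coding strand reads right-to-left on the forward sequence
            seq[iv[1] - 2 : iv[1]] = list(str(Seq(donor).reverse_complement()))
            seq[iv[0] : iv[0] + 2] = list(str(Seq(acceptor).reverse_complement()))

    intron_iv = (100, 125)
    pci_iv = (150, 172)
    plant(intron_iv, "GT", "AG")
    plant(pci_iv, "GT", "AG")

    scenario = rng.integers(8)
    shift = int(rng.integers(1, 6))
    if scenario == 0:  # exact gap over the intron
        blocks = [(90, 100), (125, 135)]
    elif scenario == 1:  # ungapped (retention)
        blocks = [(92, 132)]
    elif scenario == 2:  # shifted gap, planted GT/AG (alternative splice site)
        gap = (100, 125 + shift)
        plant(gap, "GT", "AG")
        blocks = [(90, gap[0]), (gap[1], gap[1] + 10)]
    elif scenario == 3:  # shifted gap without planted signals
        gap = (100 - shift, 125)
        blocks = [(88 - shift, gap[0]), (gap[1], 135)]
    elif scenario == 4:  # read ends inside the intron
        blocks = [(80, 110)]
    elif scenario == 5:  # gap over the PCI
        blocks = [(140, 150), (172, 182)]
    elif scenario == 6:  # ungapped over the PCI
        blocks = [(145, 180)]
    else:  # two gaps, one over the intron, one elsewhere
        plant((140, 160), "GT", "AG")
        blocks = [(90, 100), (125, 140), (160, 170)]

    genome = GenomeAnnotation(sequences={"cX": "".join(seq)}, genes=[])
    intron_seq = genome.extract("cX", intron_iv, strand)
    intron = Intron(
        gene_id="gX", index=1, contig="cX", strand=strand,
        interval=intron_iv, seq=intron_seq, is_last=True,
    )
    pci = PCI(
        gene_id="gX", contig="cX", strand=strand, interval=pci_iv,
        seq=genome.extract("cX", pci_iv, strand),
    )
    read = sn.SplicedReadAlignment(read_id="r", contig="cX", blocks=blocks)
    return genome, intron, pci, read
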