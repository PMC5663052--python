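"""Genome + annotation model: genes, introns, and potential cryptic introns.

Internal coordinates are 0-based half-open on the forward genomic strand;
GFF3 I/O converts to and from the 1-based closed convention. All sequence
logic (splice signals, cryptic-intron scans, reading frames) operates on the
coding strand: minus-strand genes are reverse-complemented on extraction and
their exons are kept in transcription order (5' -> 3' of the transcript).

A "potential cryptic intron" (PCI) is any segment of an annotated coding
exon, 20-35 nt long, that starts with GT and ends with AG: a site the
spliceosome could erroneously excise. Short ciliate-like introns use the
extended consensus GTA..TAG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import gffutils
from Bio import SeqIO

from .genetics import revcomp

Interval = tuple[int, int]

PCI_MIN_LEN = 20
PCI_MAX_LEN = 35


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent genome annotations."""


@dataclass
class GeneModel:
    """One representative transcript model of a protein-coding gene.

    ``exons`` and ``cds`` are genomic 0-based half-open intervals listed in
    transcription order (for minus-strand genes, descending genomic
    coordinates).
    """

    id: str
    contig: str
    strand: str
    exons: list[Interval]
    cds: list[Interval]
    expression_rpkm: float = 0.0
    valid: bool = True

    @property
    def n_introns(self) -> int:
        return max(len(self.exons) - 1, 0)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> Interval:
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        return lo, hi


@dataclass
class Intron:
    """An annotated intron, with splice signals read on the coding strand."""

    gene_id: str
    index: int  # 1-based ordinal in transcription order
    contig: str
    strand: str
    interval: Interval
    seq: str
    is_last: bool

    @property
    def id(self) -> str:
        return f"{self.gene_id}.i{self.index}"

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def donor2(self) -> str:
        return self.seq[:2]

    @property
    def acceptor2(self) -> str:
        return self.seq[-2:]

    @property
    def signal_match(self) -> bool:
        """True when the intron matches the GTA..TAG extended consensus."""
        return self.seq[:3] == "GTA" and self.seq[-3:] == "TAG"

    @property
    def is_3n(self) -> bool:
        return self.length % 3 == 0


@dataclass
class PCI:
    """A potential cryptic intron inside a single annotated coding exon."""

    gene_id: str
    contig: str
    strand: str
    interval: Interval
    seq: str

    @property
    def id(self) -> str:
        return f"{self.gene_id}.p{self.interval[0]}-{self.interval[1]}"

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def is_3n(self) -> bool:
        return self.length % 3 == 0


@dataclass
class GenomeAnnotation:
    """Container for a genome sequence plus single-transcript gene models."""

    sequences: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gene in self.genes:
            if gene.id in seen:
                raise AnnotationError(f"duplicate gene identifier {gene.id!r}")
            seen.add(gene.id)
            if gene.contig not in self.sequences:
                raise AnnotationError(
                    f"gene {gene.id!r} references missing contig {gene.contig!r}"
                )
            lo, hi = gene.span
            if lo < 0 or hi > len(self.sequences[gene.contig]):
                raise AnnotationError(
                    f"gene {gene.id!r} extends outside contig {gene.contig!r}"
                )

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def extract(self, contig: str, interval: Interval, strand: str = "+") -> str:
        """Sequence of a genomic interval on the requested (coding) strand."""
        s, e = interval
        seq = self.sequences[contig][s:e]
        return seq if strand == "+" else revcomp(seq)


def coding_sequence(gene: GeneModel, genome: GenomeAnnotation) -> str:
    """Annotated CDS on the coding strand, concatenated in transcription order."""
    return "".join(genome.extract(gene.contig, iv, gene.strand) for iv in gene.cds)


# ---------------------------------------------------------------------------
# GFF3 / FASTA I/O
# ---------------------------------------------------------------------------


def _read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def _validate_gff_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise AnnotationError(
                    f"malformed GFF3 line {lineno}: expected 9 tab-separated "
                    f"columns, got {len(line.split(chr(9)))}"
                )


def _transcription_sort(intervals: list[Interval], strand: str) -> list[Interval]:
    ordered = sorted(intervals)
    return ordered if strand == "+" else ordered[::-1]


def parse_annotation(gff_path: str, fasta_path: str) -> GenomeAnnotation:
    """Parse a GFF3 + FASTA pair into a validated :class:`GenomeAnnotation`.

    Exactly one transcript model per gene is accepted (either exon/CDS
    features attached directly to the gene, or through a single mRNA);
    multi-isoform genes raise :class:`AnnotationError`. Genes whose CDS
    length is not a multiple of three are kept but flagged invalid, with a
    warning.
    """
    sequences = _read_fasta(fasta_path)
    _validate_gff_lines(gff_path)
    db = gffutils.create_db(
        gff_path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by="start"):
        if feat.seqid not in sequences:
            raise AnnotationError(
                f"GFF3 references contig {feat.seqid!r} absent from FASTA"
            )
        mrnas = list(db.children(feat, featuretype="mRNA"))
        if len(mrnas) > 1:
            raise AnnotationError(
                f"gene {feat.id!r} has {len(mrnas)} mRNAs; one transcript "
                "model per gene is required"
            )
        parent = mrnas[0] if mrnas else feat
        exons = [(f.start - 1, f.end) for f in db.children(parent, featuretype="exon")]
        cds = [(f.start - 1, f.end) for f in db.children(parent, featuretype="CDS")]
        if not exons:
            exons = list(cds)
        strand = feat.strand if feat.strand in "+-" else "+"
        gene = GeneModel(
            id=feat.id,
            contig=feat.seqid,
            strand=strand,
            exons=_transcription_sort(exons, strand),
            cds=_transcription_sort(cds, strand),
        )
        _check_gene(gene)
        genes.append(gene)
    return GenomeAnnotation(sequences=sequences, genes=genes)


def _check_gene(gene: GeneModel) -> None:
    ordered = sorted(gene.exons)
    for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
        if s2 < e1:
            raise AnnotationError(f"gene {gene.id!r} has overlapping exons")
    for c in gene.cds:
        if not any(c[0] >= s and c[1] <= e for s, e in gene.exons):
            raise AnnotationError(
                f"gene {gene.id!r}: CDS interval {c} not contained in an exon"
            )
    if gene.cds and gene.cds_length % 3 != 0:
        warnings.warn(
            f"gene {gene.id!r}: CDS length {gene.cds_length} is not a "
            "multiple of 3; gene flagged invalid",
            stacklevel=3,
        )
        gene.valid = False


def write_gff3(annotation: GenomeAnnotation, path: str, source: str = "splicenoise") -> None:
    """Serialize gene/exon/CDS features as GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in sorted(annotation.genes, key=lambda g: (g.contig, g.span)):
            lo, hi = gene.span
            fh.write(
                f"{gene.contig}\t{source}\tgene\t{lo + 1}\t{hi}\t.\t"
                f"{gene.strand}\t.\tID={gene.id}\n"
            )
            for s, e in sorted(gene.exons):
                fh.write(
                    f"{gene.contig}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                    f"{gene.strand}\t.\tParent={gene.id}\n"
                )
            phase = 0
            for s, e in gene.cds:  # transcription order for correct phase
                fh.write(
                    f"{gene.contig}\t{source}\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{gene.strand}\t{phase}\tParent={gene.id}\n"
                )
                phase = (3 - ((e - s) - phase) % 3) % 3


def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Derived elements
# ---------------------------------------------------------------------------


def derive_introns(gene: GeneModel, genome: GenomeAnnotation) -> list[Intron]:
    """Introns of a gene: the gaps between consecutive exons.

    Returns one :class:`Intron` per consecutive exon pair, in transcription
    order; a single-exon gene yields an empty list. A zero-length gap is an
    annotation inconsistency and raises :class:`AnnotationError`.
    """
    introns: list[Intron] = []
    n = gene.n_introns
    for idx in range(n):
        up, down = gene.exons[idx], gene.exons[idx + 1]
        if gene.strand == "+":
            iv = (up[1], down[0])
        else:
            iv = (down[1], up[0])
        if iv[1] <= iv[0]:
            raise AnnotationError(
                f"gene {gene.id!r}: zero-length gap between exons {idx} and {idx + 1}"
            )
        introns.append(
            Intron(
                gene_id=gene.id,
                index=idx + 1,
                contig=gene.contig,
                strand=gene.strand,
                interval=iv,
                seq=genome.extract(gene.contig, iv, gene.strand),
                is_last=(idx == n - 1),
            )
        )
    return introns


def enumerate_pcis(
    gene: GeneModel,
    genome: GenomeAnnotation,
    min_len: int = PCI_MIN_LEN,
    max_len: int = PCI_MAX_LEN,
) -> list[PCI]:
    """All GT..AG segments of length ``min_len``..``max_len`` inside coding exons.

    Every GT is paired with every in-window AG, so overlapping and nested
    PCIs are all reported. Scanning is restricted to single annotated coding
    exons (a PCI never crosses an exon boundary).
    """
    out: list[PCI] = []
    for exon in gene.cds:
        seq = genome.extract(gene.contig, exon, gene.strand)
        L = len(seq)
        for i in range(L - min_len + 1):
            if seq[i : i + 2] != "GT":
                continue
            for length in range(min_len, min(max_len, L - i) + 1):
                if seq[i + length - 2 : i + length] == "AG":
                    if gene.strand == "+":
                        iv = (exon[0] + i, exon[0] + i + length)
                    else:
                        iv = (exon[1] - i - length, exon[1] - i)
                    out.append(
                        PCI(
                            gene_id=gene.id,
                            contig=gene.contig,
                            strand=gene.strand,
                            interval=iv,
                            seq=seq[i : i + length],
                        )
                    )
    return out


def matches_consensus(intron: Intron) -> bool:
    """True iff the intron matches the GTA..TAG extended consensus."""
    if intron.length < 6:
        raise AnnotationError(
            f"intron {intron.id} is shorter than 6 nt; consensus undefined"
        )
    return intron.signal_match


def all_introns(genome: GenomeAnnotation, genes: Iterable[GeneModel] | None = None) -> list[Intron]:
    out: list[Intron] = []
    for gene in genes if genes is not None else genome.genes:
        out.extend(derive_introns(gene, genome))
    return out
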