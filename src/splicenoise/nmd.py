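"""Variant transcript reconstruction and NMD-visibility classification.

Every alternative-splicing event (intron retention, alternative splice-site
usage, cryptic-intron splicing) is applied to the annotated CDS to obtain the
variant coding sequence, which is then scanned for premature termination
codons (PTCs) under a configurable genetic code. Variants fall into a
trichotomy: PTC-inducing (NMD-visible), frame-preserving without PTC
("3n no PTC"), or frameshifting without PTC ("non-3n no PTC"); only the
first class is a substrate for nonsense-mediated decay.

Paramecium rule: any in-frame stop upstream of the annotated stop is a PTC.
Human rule: a PTC triggers NMD only when located more than 50 nt upstream of
the last exon-exon junction of the variant, and events affecting last introns
are NMD-invisible outright.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2_contingency

from .annotation import GeneModel, GenomeAnnotation, Interval, Intron, PCI
from .genetics import CILIATE_CODE, STANDARD_CODE, GeneticCode, first_stop

PTC_INDUCING = "PTC_inducing"
NO_PTC_3N = "no_PTC_3n"
NO_PTC_NON3N = "no_PTC_non3n"

#: Minimum distance (nt) of a PTC upstream of the last exon-exon junction for
#: NMD recognition in the mammalian rule.
HUMAN_PTC_JUNCTION_DISTANCE = 50


class NonClassifiableEvent(ValueError):
    """Event cannot be projected onto the coding sequence (e.g. pure-UTR)."""


@dataclass(frozen=True)
class Event:
    """An AS event expressed in genomic coordinates.

    kind is one of 'IR', 'ASSV', 'PCI'. ``interval`` is the annotated intron
    (IR/ASSV) or the PCI segment; ``alt_interval`` is the actually excised
    interval for ASSV events.
    """

    kind: str
    gene_id: str
    interval: Interval
    alt_interval: Interval | None = None
    intron_index: int | None = None
    is_last_intron: bool = False

    @staticmethod
    def ir(intron: Intron) -> "Event":
        return Event("IR", intron.gene_id, intron.interval,
                     intron_index=intron.index, is_last_intron=intron.is_last)

    @staticmethod
    def assv(intron: Intron, alt_interval: Interval) -> "Event":
        return Event("ASSV", intron.gene_id, intron.interval, alt_interval,
                     intron_index=intron.index, is_last_intron=intron.is_last)

    @staticmethod
    def pci_splice(pci: PCI) -> "Event":
        return Event("PCI", pci.gene_id, pci.interval)


@dataclass
class VariantTranscript:
    """A variant CDS produced by applying one AS event to a gene model."""

    gene_id: str
    event: Event
    variant_cds: str
    delta_length: int
    junction_positions: list[int]  # exon-exon junctions, variant CDS coords

    @property
    def frame_shifted(self) -> bool:
        return self.delta_length % 3 != 0


@dataclass(frozen=True)
class NmdCategory:
    category: str
    nmd_visible: bool
    ptc_position: int | None = None
    read_through: bool = False


def _local(iv: Interval, span: Interval, strand: str) -> Interval:
    """Map a genomic interval into coding-strand local coordinates."""
    lo, hi = span
    if strand == "+":
        return iv[0] - lo, iv[1] - lo
    return hi - iv[1], hi - iv[0]


def _cds_excisions(gene: GeneModel, span: Interval) -> list[Interval]:
    """Annotated intron excisions between consecutive CDS blocks (local)."""
    locs = sorted(_local(iv, span, gene.strand) for iv in gene.cds)
    return [(a_end, b_start) for (_, a_end), (b_start, _) in zip(locs, locs[1:])]


def _splice(premrna: str, excisions: list[Interval]) -> tuple[str, list[int]]:
    """Remove excised intervals; return mature sequence + junction offsets."""
    parts: list[str] = []
    junctions: list[int] = []
    pos = 0
    made = 0
    for s, e in sorted(excisions):
        if s < pos:
            raise NonClassifiableEvent("overlapping excisions")
        parts.append(premrna[pos:s])
        made += s - pos
        junctions.append(made)
        pos = e
    parts.append(premrna[pos:])
    return "".join(parts), junctions


def apply_event_to_cds(
    gene: GeneModel, event: Event, genome: GenomeAnnotation
) -> VariantTranscript:
    """Reconstruct the variant CDS for one AS event.

    IR keeps the intron sequence in place; a PCI splice deletes the PCI
    segment; ASSV replaces the annotated intron's excision by the alternate
    interval's excision. Events outside the CDS span (pure-UTR) raise
    :class:`NonClassifiableEvent`.
    """
    lo = min(s for s, _ in gene.cds)
    hi = max(e for _, e in gene.cds)
    span = (lo, hi)
    premrna = genome.extract(gene.contig, span, gene.strand)
    annotated = _cds_excisions(gene, span)
    target = _local(event.interval, span, gene.strand)
    if target[0] < 0 or target[1] > len(premrna):
        raise NonClassifiableEvent(
            f"event interval {event.interval} lies outside the CDS of {gene.id}"
        )

    if event.kind == "IR":
        if target not in annotated:
            raise NonClassifiableEvent(
                f"no annotated CDS-internal intron at {event.interval} in {gene.id}"
            )
        excisions = [iv for iv in annotated if iv != target]
    elif event.kind == "ASSV":
        if event.alt_interval is None:
            raise ValueError("ASSV event requires alt_interval")
        if target not in annotated:
            raise NonClassifiableEvent(
                f"no annotated CDS-internal intron at {event.interval} in {gene.id}"
            )
        alt = _local(event.alt_interval, span, gene.strand)
        excisions = [alt if iv == target else iv for iv in annotated]
    elif event.kind == "PCI":
        excisions = annotated + [target]
    else:
        raise ValueError(f"unknown event kind {event.kind!r}")

    variant, junctions = _splice(premrna, excisions)
    annotated_cds, _ = _splice(premrna, annotated)
    return VariantTranscript(
        gene_id=gene.id,
        event=event,
        variant_cds=variant,
        delta_length=len(variant) - len(annotated_cds),
        junction_positions=junctions,
    )


def classify_nmd(
    variant: VariantTranscript,
    mode: str = "paramecium",
    code: GeneticCode | None = None,
    force: bool = False,
) -> NmdCategory:
    """Assign the NMD-visibility trichotomy to a variant transcript.

    ``mode`` selects the organism rule set; the genetic code defaults to the
    ciliate code in paramecium mode and the standard code in human mode.
    Running paramecium mode under the standard code is rejected unless
    ``force`` is set (TAA/TAG encode glutamine in *P. tetraurelia*).
    """
    if mode not in ("paramecium", "human"):
        raise ValueError(f"unknown mode {mode!r}")
    if code is None:
        code = CILIATE_CODE if mode == "paramecium" else STANDARD_CODE
    if mode == "paramecium" and code is STANDARD_CODE and not force:
        raise ValueError(
            "paramecium mode with the standard genetic code would miscall "
            "PTCs (TAA/TAG encode Gln); pass force=True to override"
        )

    seq = variant.variant_cds
    stop = first_stop(seq, code)
    read_through = stop is None
    # The annotated stop occupies the final codon; an in-frame stop ending
    # before the end of the variant is premature.
    is_ptc = stop is not None and stop < len(seq) - 3

    if is_ptc and mode == "human":
        if variant.event.kind in ("IR", "ASSV") and variant.event.is_last_intron:
            is_ptc = False
        elif not variant.junction_positions:
            is_ptc = False
        else:
            last_junction = max(variant.junction_positions)
            if last_junction - stop <= HUMAN_PTC_JUNCTION_DISTANCE:
                is_ptc = False

    if is_ptc:
        return NmdCategory(PTC_INDUCING, True, ptc_position=stop)
    if variant.frame_shifted:
        return NmdCategory(NO_PTC_NON3N, False, read_through=read_through)
    return NmdCategory(NO_PTC_3N, False, read_through=read_through)


def consensus_by_nmd_class(
    introns: list[Intron], visible: list[bool]
) -> tuple[dict[str, float], float, float]:
    """Consensus-signal fractions in NMD-visible vs NMD-invisible introns.

    Returns per-class fractions of GTA..TAG consensus introns and the Pearson
    chi-squared statistic (no continuity correction) with its p-value on the
    2x2 count table.
    """
    if len(introns) != len(visible):
        raise ValueError("introns and visibility flags differ in length")
    table = {True: [0, 0], False: [0, 0]}  # class -> [match, no match]
    for intron, vis in zip(introns, visible):
        table[vis][0 if intron.signal_match else 1] += 1
    for cls, counts in table.items():
        if sum(counts) < 2:
            raise ValueError(
                f"NMD-{'visible' if cls else 'invisible'} class has fewer "
                "than 2 introns"
            )
    counts = [table[True], table[False]]
    chi2, p, _, _ = chi2_contingency(counts, correction=False)
    fractions = {
        "visible": table[True][0] / sum(table[True]),
        "invisible": table[False][0] / sum(table[False]),
    }
    return fractions, float(chi2), float(p)
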