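"""Junction-read classification and per-element count accumulation.

The unit of evidence is the junction-spanning read: a read aligned across an
intron (or potential cryptic intron) with zero or more alignment gaps. For
each annotated intron a spanning read is counted as canonical (gap exactly
matching the intron), intron retention (no gap over the intron), or an
alternative splice-site variant (gap overlapping but mismatching the
intron); for each PCI a spanning read is either spliced (gap exactly
matching the PCI) or unspliced. Any counted gap must match the GT/AG
consensus on the coding strand, otherwise the read is discarded for that
element (this removes e.g. IES-excision variants in Paramecium).

Rates per element: IR = n3/(n1+n2+n3), ASSV = n2/(n1+n2+n3) and, for PCIs,
splice rate = m2/(m1+m2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, Interval, Intron, PCI
from .genetics import revcomp

CANONICAL = "canonical"
IR = "IR"
ASSV = "ASSV"
NOT_SPANNING = "not_spanning"
DISCARDED = "discarded"
SPLICED = "spliced"
UNSPLICED = "unspliced"

#: WT read-depth threshold below which an intron's canonical form is undefined.
MIN_CANONICAL_READS = 10


@dataclass
class SplicedReadAlignment:
    """A (possibly gapped) read alignment as sorted genomic blocks.

    ``gap_signals`` optionally carries the forward-strand terminal
    dinucleotides of each gap, for use when no genome sequence is at hand;
    with a genome they are looked up directly.
    """

    read_id: str
    contig: str
    blocks: list[Interval]
    gap_signals: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if s2 < e1:
                raise ValueError(f"read {self.read_id}: blocks overlap or unsorted")

    @property
    def gaps(self) -> list[Interval]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:])]

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def covers(self, interval: Interval) -> bool:
        """True when every position of ``interval`` is inside an aligned block."""
        s, e = interval
        for bs, be in self.blocks:
            if bs <= s and e <= be:
                return True
        return False


def _gap_matches_gt_ag(
    read: SplicedReadAlignment,
    gap_index: int,
    strand: str,
    genome: GenomeAnnotation | None,
) -> bool:
    gs, ge = read.gaps[gap_index]
    if genome is not None:
        left = genome.sequences[read.contig][gs : gs + 2]
        right = genome.sequences[read.contig][ge - 2 : ge]
    elif read.gap_signals is not None:
        left, right = read.gap_signals[gap_index]
    else:
        raise ValueError("GT/AG filter needs a genome or per-gap signals")
    if strand == "+":
        donor, acceptor = left, right
    else:
        donor, acceptor = revcomp(right), revcomp(left)
    return donor == "GT" and acceptor == "AG"


def _spans(read: SplicedReadAlignment, interval: Interval, min_anchor: int) -> bool:
    s, e = interval
    return read.start <= s - min_anchor and read.end >= e + min_anchor


def classify_read_for_intron(
    read: SplicedReadAlignment,
    intron: Intron,
    genome: GenomeAnnotation | None = None,
    min_anchor: int = 1,
) -> str:
    """Classify one read against one annotated intron.

    Returns 'canonical', 'IR', 'ASSV', 'not_spanning' or 'discarded'
    (a gap overlapping the intron that fails the GT/AG filter).
    """
    if read.contig != intron.contig or not _spans(read, intron.interval, min_anchor):
        return NOT_SPANNING
    s, e = intron.interval
    overlapping = [
        i for i, (gs, ge) in enumerate(read.gaps) if gs < e and ge > s
    ]
    if not overlapping:
        return IR if read.covers(intron.interval) else NOT_SPANNING
    for i in overlapping:
        if not _gap_matches_gt_ag(read, i, intron.strand, genome):
            return DISCARDED
    if len(overlapping) == 1 and read.gaps[overlapping[0]] == intron.interval:
        return CANONICAL
    return ASSV


def detect_cryptic_splicing(
    read: SplicedReadAlignment,
    pci: PCI,
    min_anchor: int = 1,
) -> str:
    """Classify one read against one PCI: 'spliced', 'unspliced' or 'not_spanning'.

    A read is spliced only when a gap matches the PCI interval exactly (the
    GT/AG signals are guaranteed by the PCI definition); unspliced when it
    covers the whole PCI without a gap.
    """
    if read.contig != pci.contig or not _spans(read, pci.interval, min_anchor):
        return NOT_SPANNING
    if pci.interval in read.gaps:
        return SPLICED
    if read.covers(pci.interval):
        return UNSPLICED
    return NOT_SPANNING


def classify_alignments(
    reads: list[SplicedReadAlignment],
    introns: list[Intron],
    pcis: list[PCI],
    genome: GenomeAnnotation | None = None,
    min_anchor: int = 1,
) -> pd.DataFrame:
    """Classify every read against every intron and PCI it spans.

    A read contributes independently to every element it spans. Returns a
    tidy observation table (read_id, element_type, element_id, form) without
    not-spanning pairs.
    """
    rows = []
    for read in reads:
        for intron in introns:
            form = classify_read_for_intron(read, intron, genome, min_anchor)
            if form != NOT_SPANNING:
                rows.append((read.read_id, "intron", intron.id, form))
        for pci in pcis:
            form = detect_cryptic_splicing(read, pci, min_anchor)
            if form != NOT_SPANNING:
                rows.append((read.read_id, "pci", pci.id, form))
    return pd.DataFrame(rows, columns=["read_id", "element_type", "element_id", "form"])


@dataclass
class JunctionCounts:
    """Per-element read tallies for one condition.

    ``introns``: index element_id, columns n1 (canonical), n2 (ASSV),
    n3 (retained). ``pcis``: index element_id, columns m1 (unspliced),
    m2 (spliced).
    """

    introns: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["n1", "n2", "n3"])
    )
    pcis: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["m1", "m2"])
    )


_INTRON_FORM_COL = {CANONICAL: "n1", ASSV: "n2", IR: "n3"}
_PCI_FORM_COL = {UNSPLICED: "m1", SPLICED: "m2"}


def accumulate_counts(
    observations: pd.DataFrame,
    intron_ids: list[str] | None = None,
    pci_ids: list[str] | None = None,
) -> JunctionCounts:
    """Tally classified observations into per-element counts.

    Discarded observations are dropped. Elements listed in ``intron_ids`` /
    ``pci_ids`` but absent from the observations get all-zero rows.
    """
    intron_obs = observations[observations["element_type"] == "intron"]
    intron_obs = intron_obs[intron_obs["form"].isin(_INTRON_FORM_COL)]
    itab = (
        intron_obs.assign(col=intron_obs["form"].map(_INTRON_FORM_COL))
        .pivot_table(index="element_id", columns="col", values="form",
                     aggfunc="count", fill_value=0)
        .reindex(columns=["n1", "n2", "n3"], fill_value=0)
    )
    pci_obs = observations[observations["element_type"] == "pci"]
    pci_obs = pci_obs[pci_obs["form"].isin(_PCI_FORM_COL)]
    ptab = (
        pci_obs.assign(col=pci_obs["form"].map(_PCI_FORM_COL))
        .pivot_table(index="element_id", columns="col", values="form",
                     aggfunc="count", fill_value=0)
        .reindex(columns=["m1", "m2"], fill_value=0)
    )
    if intron_ids is not None:
        itab = itab.reindex(intron_ids, fill_value=0)
    if pci_ids is not None:
        ptab = ptab.reindex(pci_ids, fill_value=0)
    itab.columns.name = None
    ptab.columns.name = None
    return JunctionCounts(introns=itab.astype(int), pcis=ptab.astype(int))


REFERENCE = "reference"
LOW_COVERAGE = "low_coverage"
NEVER_SPLICED = "never_spliced"
MINOR_FORM = "minor_form"


def determine_canonical_forms(
    counts_wt: JunctionCounts,
    min_reads: int = MIN_CANONICAL_READS,
    minor_cutoff: float = 0.5,
) -> pd.Series:
    """Assign a canonical-form status to each intron from WT counts only.

    low_coverage: fewer than ``min_reads`` WT spanning reads; never_spliced:
    no spliced read (n1+n2 == 0); minor_form: the annotated spliced form is
    not the major WT form (IR fraction >= ``minor_cutoff``); otherwise the
    intron enters the reference set.
    """
    tab = counts_wt.introns
    total = tab.sum(axis=1)
    status = pd.Series(REFERENCE, index=tab.index, dtype=object)
    spliced = tab["n1"] + tab["n2"]
    ir_frac = tab["n3"] / total.replace(0, 1)
    status[ir_frac >= minor_cutoff] = MINOR_FORM
    status[spliced == 0] = NEVER_SPLICED
    status[total < min_reads] = LOW_COVERAGE
    status.name = "status"
    return status


def rates_from_counts(counts: JunctionCounts) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-element AS rates; zero-denominator elements are flagged excluded."""
    it = counts.introns.copy()
    total = it.sum(axis=1)
    it["total"] = total
    it["excluded"] = total == 0
    denom = total.astype(float).replace(0.0, np.nan)
    it["ir_rate"] = it["n3"] / denom
    it["assv_rate"] = it["n2"] / denom

    pt = counts.pcis.copy()
    ptotal = pt.sum(axis=1)
    pt["total"] = ptotal
    pt["excluded"] = ptotal == 0
    pt["splice_rate"] = pt["m2"] / ptotal.astype(float).replace(0.0, np.nan)
    return it, pt


def assv_frequency_human(
    n_e1e2: int, n_eae2: int, n_e1ea: int, min_total: int = 10
) -> float | None:
    """Per-tissue human ASSV frequency from junction counts.

    ASSV = (nEaE2 + nE1Ea) / (nE1E2 + nEaE2 + nE1Ea), computed only when the
    total is strictly greater than ``min_total``; otherwise None (excluded).
    """
    if min(n_e1e2, n_eae2, n_e1ea) < 0:
        raise ValueError("junction counts must be non-negative")
    total = n_e1e2 + n_eae2 + n_e1ea
    if total <= min_total:
        return None
    return (n_eae2 + n_e1ea) / total
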