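"""Synthetic genomes, junction reads and SNPs with known ground truth.

The generator emulates a Paramecium-like genome: very short introns
(20-35 nt, GT..AG, a configurable fraction matching the GTA..TAG extended
consensus), 0-8 introns per gene, A/T-rich coding sequence free of in-frame
stops under the ciliate code, CDS lengths divisible by 3. A human-like mode
uses the standard code instead.

Junction evidence follows a drift-barrier error model: each intron's
intrinsic error rate is eps0 * RPKM^(-alpha) * n_introns^(-beta) (clipped),
split 5:1 between intron retention and alternative splice-site usage, plus a
constant functional-AS floor. PTC-bearing variants are degraded by NMD with
per-condition efficiency d and frequencies renormalized (steady-state
polyA-pool sampling); spanning reads are Poisson in depth and multinomial
across forms. The alternative splice-site variant of every intron uses a
donor 3 nt inside the intron (the intron carries a planted secondary GT),
which changes transcript length without shifting the frame.

SNPs are placed per-site Bernoulli: splice-site density pi3_base * g(RPKM)
with a configurable non-increasing g, third-codon-position density pi3_base
independent of expression.

All outputs are reproducible bit-exactly from (params, seed).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import polymorphism
from .annotation import (
    GeneModel,
    GenomeAnnotation,
    Intron,
    PCI,
    all_introns,
    enumerate_pcis,
)
from .events import JunctionCounts, SplicedReadAlignment
from .genetics import CILIATE_CODE, STANDARD_CODE, GeneticCode, revcomp

_BASES = np.array(list("ATCG"))
_AT_RICH = np.array([0.35, 0.35, 0.15, 0.15])  # Paramecium-like composition


@dataclass
class TruthParams:
    """Ground-truth model parameters; the defaults define the study conditions.

    read_depth_per_rpkm is the expected number of junction-spanning reads
    per element per RPKM unit; the default yields a mean depth of ~50
    reads/intron under the default expression law (log-uniform RPKM 1-1000).
    """

    n_genes: int = 200
    intron_count_weights: dict[int, float] = field(
        default_factory=lambda: {0: 0.20, 1: 0.22, 2: 0.19, 3: 0.13,
                                 4: 0.09, 5: 0.07, 6: 0.05, 7: 0.03, 8: 0.02}
    )
    expression_log10_range: tuple[float, float] = (0.0, 3.0)
    epsilon0: float = 0.15
    alpha: float = 0.5
    beta: float = 0.3
    rate_floor: float = 1e-6
    rate_cap: float = 0.5
    functional_as_rate: float = 0.001
    ir_assv_ratio: float = 5.0
    pci_error_scale: float = 0.01
    nmd_efficiency: dict[str, float] = field(
        default_factory=lambda: {"WT": 0.9, "NMD": 0.0}
    )
    read_depth_per_rpkm: float = 0.346
    consensus_fraction: float = 0.75
    codons_range: tuple[int, int] = (80, 800)
    genes_per_contig: int = 25
    mode: str = "paramecium"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("exponents must be non-negative")
        if not 0 <= self.rate_floor <= self.rate_cap <= 1:
            raise ValueError("need 0 <= floor <= cap <= 1")
        if self.functional_as_rate < 0:
            raise ValueError("functional AS rate must be non-negative")
        for cond, d in self.nmd_efficiency.items():
            if not 0 <= d <= 1:
                raise ValueError(f"NMD efficiency for {cond!r} outside [0, 1]")
        if any(w < 0 for w in self.intron_count_weights.values()):
            raise ValueError("intron-count weights must be non-negative")
        if sum(self.intron_count_weights.values()) <= 0:
            raise ValueError("intron-count weights must have positive mass")

    @property
    def code(self) -> GeneticCode:
        return CILIATE_CODE if self.mode == "paramecium" else STANDARD_CODE

    @property
    def functional_pci_rate(self) -> float:
        return self.functional_as_rate * self.pci_error_scale


def intrinsic_error_rate(
    expression: float | np.ndarray,
    n_introns: int | np.ndarray,
    params: TruthParams,
) -> float | np.ndarray:
    """Per-intron intrinsic error rate eps0 * E^(-alpha) * n^(-beta), clipped.

    Monotonically non-increasing in both expression and intron number.
    """
    expression = np.asarray(expression, dtype=float)
    if np.any(expression <= 0):
        raise ValueError("expression must be positive")
    n = np.asarray(n_introns, dtype=float)
    if np.any(n < 1):
        raise ValueError("intron number must be >= 1")
    rate = params.epsilon0 * expression ** (-params.alpha) * n ** (-params.beta)
    out = np.clip(rate, params.rate_floor, params.rate_cap)
    return float(out) if out.ndim == 0 else out


def pci_intrinsic_rate(
    expression: float | np.ndarray,
    cds_length: int | np.ndarray,
    params: TruthParams,
) -> float | np.ndarray:
    """Intrinsic splice rate of a PCI, scaled down and decreasing in CDS length."""
    expression = np.asarray(expression, dtype=float)
    length_kb = np.asarray(cds_length, dtype=float) / 1000.0
    rate = (
        params.pci_error_scale
        * params.epsilon0
        * expression ** (-params.alpha)
        * length_kb ** (-params.beta)
    )
    out = np.clip(rate, params.rate_floor * params.pci_error_scale, params.rate_cap)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# fast PTC checks on the coding strand (generator-side truth labels)
# ---------------------------------------------------------------------------


def _stop_in_window(seq: str, code: GeneticCode, start: int, end: int) -> bool:
    """Any stop codon with start offset in [start, end) (full codons only)."""
    for i in range(start, min(end, len(seq) - 2), 3):
        if code.is_stop(seq[i : i + 3]):
            return True
    return False


def _insertion_creates_ptc(cds: str, insert: str, pos: int, code: GeneticCode) -> bool:
    """PTC status of inserting ``insert`` at CDS offset ``pos`` (paramecium rule)."""
    variant = cds[:pos] + insert + cds[pos:]
    a = 3 * (pos // 3)
    if len(insert) % 3 == 0:
        # frame preserved: only codons overlapping the insertion can change
        return _stop_in_window(variant, code, a, pos + len(insert))
    for i in range(a, len(variant) - 2, 3):
        if code.is_stop(variant[i : i + 3]):
            return i < len(variant) - 3
    return False


def _deletion_creates_ptc(cds: str, pos: int, length: int, code: GeneticCode) -> bool:
    """PTC status of deleting ``length`` nt at CDS offset ``pos``."""
    variant = cds[:pos] + cds[pos + length :]
    a = 3 * (pos // 3)
    if length % 3 == 0:
        # only the codon spanning the junction can become a stop
        return _stop_in_window(variant, code, a, pos + 1)
    for i in range(a, len(variant) - 2, 3):
        if code.is_stop(variant[i : i + 3]):
            return i < len(variant) - 3
    return False


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------


def _sample_codons(rng: np.random.Generator, n: int, code: GeneticCode) -> np.ndarray:
    """n sense codons (no in-frame stop) with A/T-rich composition."""
    letters = rng.choice(_BASES, size=(n, 3), p=_AT_RICH)
    codons = np.char.add(np.char.add(letters[:, 0], letters[:, 1]), letters[:, 2])
    while True:
        bad = np.isin(codons, list(code.stop_codons))
        if not bad.any():
            return codons
        repl = rng.choice(_BASES, size=(int(bad.sum()), 3), p=_AT_RICH)
        codons[bad] = np.char.add(np.char.add(repl[:, 0], repl[:, 1]), repl[:, 2])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n, p=_AT_RICH))


def _intron_seq(rng: np.random.Generator, length: int, consensus: bool) -> str:
    """One intron: donor trinucleotide + planted alternate GT + filler + acceptor."""
    if consensus:
        d3, a3 = "GTA", "TAG"
    else:
        which = rng.integers(3)  # break donor, acceptor, or both
        d3 = "GT" + rng.choice(list("CGT")) if which != 1 else "GTA"
        a3 = rng.choice(list("ACG")) + "AG" if which != 0 else "TAG"
    return d3 + "GT" + _random_seq(rng, length - 8) + a3


@dataclass
class SimTruth:
    """Deterministic ground truth: intrinsic rates and NMD-visibility labels.

    ``introns`` and ``pcis`` carry, per element, the pre-NMD variant
    frequencies (p_*), their error components (e_*) and visibility flags;
    ``genes`` carries expression and structure.
    """

    params: TruthParams
    genes: pd.DataFrame
    introns: pd.DataFrame
    pcis: pd.DataFrame

    def observed_intron_frequencies(self, condition: str) -> pd.DataFrame:
        """Expected post-NMD frequencies of each intron's variant forms.

        Degradation multiplies PTC-bearing variant frequencies by (1 - d)
        and the steady-state pool renormalizes. Returns per-intron expected
        observed IR/ASSV frequencies and their error components.
        """
        d = self.params.nmd_efficiency[condition]
        t = self.introns
        w_ir = np.where(t["ir_visible"], 1 - d, 1.0)
        w_assv = np.where(t["assv_visible"], 1 - d, 1.0)
        z = (1 - t["p_ir"] - t["p_assv"]) + t["p_ir"] * w_ir + t["p_assv"] * w_assv
        return pd.DataFrame(
            {
                "q_ir": t["p_ir"] * w_ir / z,
                "q_assv": t["p_assv"] * w_assv / z,
                "q_ir_err": t["e_ir"] * w_ir / z,
                "q_assv_err": t["e_assv"] * w_assv / z,
                "depth": self.params.read_depth_per_rpkm * t["expression"],
            },
            index=t.index,
        )

    def observed_pci_frequencies(self, condition: str) -> pd.DataFrame:
        d = self.params.nmd_efficiency[condition]
        t = self.pcis
        w = np.where(t["visible"], 1 - d, 1.0)
        z = (1 - t["p_spl"]) + t["p_spl"] * w
        return pd.DataFrame(
            {
                "q_spl": t["p_spl"] * w / z,
                "q_spl_err": t["e_spl"] * w / z,
                "depth": self.params.read_depth_per_rpkm * t["expression"],
            },
            index=t.index,
        )

    def true_error_proportion(
        self, condition: str, intron_ids: pd.Index | list[str] | None = None
    ) -> float:
        """Expected proportion of errors among observed AS reads (P^e).

        Read-weighted over the given introns: expected error reads divided
        by expected variant reads under the condition's NMD efficiency.
        """
        q = self.observed_intron_frequencies(condition)
        if intron_ids is not None:
            q = q.loc[intron_ids]
        err = (q["depth"] * (q["q_ir_err"] + q["q_assv_err"])).sum()
        var = (q["depth"] * (q["q_ir"] + q["q_assv"])).sum()
        return float(err / var)


def generate_genome(params: TruthParams) -> tuple[GenomeAnnotation, SimTruth]:
    """Generate the synthetic genome + annotation and its ground truth.

    Deterministic for a fixed ``params.seed``. Genes have no UTRs (CDS equals
    the exons), introns sit at least 30 nt from CDS ends and from each other,
    and each intron carries a planted alternate donor 3 nt inside.
    """
    rng = np.random.default_rng(params.seed)
    counts = sorted(params.intron_count_weights)
    weights = np.array([params.intron_count_weights[c] for c in counts], dtype=float)
    weights /= weights.sum()
    lo_c, hi_c = params.codons_range
    code = params.code

    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    gene_rows = []
    intron_rows = []
    contig_parts: list[str] = []
    contig_pos = 0
    contig_idx = 1
    cds_strings: dict[str, str] = {}
    intron_local: dict[str, tuple[int, str]] = {}  # id -> (cds offset, seq)

    for gi in range(params.n_genes):
        gene_id = f"g{gi + 1:05d}"
        n_introns = int(rng.choice(counts, p=weights))
        min_codons = max(lo_c, 10 * (n_introns + 1))
        n_codons = int(rng.integers(min_codons, hi_c + 1))
        codons = _sample_codons(rng, n_codons - 2, code)
        cds = "ATG" + "".join(codons) + "TGA"
        L = len(cds)

        if n_introns:
            slack = L - 60 - (n_introns - 1) * 30
            offsets = np.sort(rng.choice(slack + 1, size=n_introns, replace=False))
            positions = [int(o) + 30 + 30 * k for k, o in enumerate(offsets)]
        else:
            positions = []
        ilens = rng.integers(20, 36, size=n_introns)
        consensus = rng.random(n_introns) < params.consensus_fraction
        iseqs = [
            _intron_seq(rng, int(l), bool(c)) for l, c in zip(ilens, consensus)
        ]

        # assemble the coding-strand gene region and local exon coordinates
        region_parts: list[str] = []
        exon_local: list[tuple[int, int]] = []
        intron_local_iv: list[tuple[int, int]] = []
        prev = 0
        off = 0
        for pos, iseq in zip(positions, iseqs):
            region_parts.append(cds[prev:pos])
            exon_local.append((off, off + (pos - prev)))
            off += pos - prev
            region_parts.append(iseq)
            intron_local_iv.append((off, off + len(iseq)))
            off += len(iseq)
            prev = pos
        region_parts.append(cds[prev:])
        exon_local.append((off, off + (L - prev)))
        off += L - prev
        region = "".join(region_parts)

        strand = "+" if rng.random() < 0.5 else "-"
        spacer = _random_seq(rng, 100)
        start = contig_pos + len(spacer)
        contig_parts.append(spacer)
        contig_parts.append(region if strand == "+" else revcomp(region))
        contig_pos = start + len(region)

        def to_genomic(local_iv: tuple[int, int]) -> tuple[int, int]:
            s, e = local_iv
            if strand == "+":
                return start + s, start + e
            return start + len(region) - e, start + len(region) - s

        exons = [to_genomic(iv) for iv in exon_local]
        contig = f"ctg{contig_idx}"
        gene = GeneModel(
            id=gene_id, contig=contig, strand=strand,
            exons=exons, cds=list(exons),
            expression_rpkm=float(
                10 ** rng.uniform(*params.expression_log10_range)
            ),
        )
        genes.append(gene)
        cds_strings[gene_id] = cds
        gene_rows.append(
            {
                "gene_id": gene_id,
                "expression": gene.expression_rpkm,
                "n_introns": n_introns,
                "cds_length": L,
                "contig": contig,
                "strand": strand,
            }
        )

        for k, (pos, iseq, liv) in enumerate(zip(positions, iseqs, intron_local_iv)):
            giv = to_genomic(liv)
            alt_local = (liv[0] + 3, liv[1])
            alt_giv = to_genomic(alt_local)
            iid = f"{gene_id}.i{k + 1}"
            intron_local[iid] = (pos, iseq)
            intron_rows.append(
                {
                    "intron_id": iid,
                    "gene_id": gene_id,
                    "index": k + 1,
                    "contig": contig,
                    "strand": strand,
                    "start": giv[0],
                    "end": giv[1],
                    "alt_start": alt_giv[0],
                    "alt_end": alt_giv[1],
                    "length": len(iseq),
                    "is_3n": len(iseq) % 3 == 0,
                    "is_last": k == n_introns - 1,
                    "signal_match": iseq[:3] == "GTA" and iseq[-3:] == "TAG",
                    "cds_offset": pos,
                }
            )

        if (gi + 1) % params.genes_per_contig == 0 or gi == params.n_genes - 1:
            contig_parts.append(_random_seq(rng, 100))
            sequences[f"ctg{contig_idx}"] = "".join(contig_parts)
            contig_parts = []
            contig_pos = 0
            contig_idx += 1

    annotation = GenomeAnnotation(sequences=sequences, genes=genes)
    genes_df = pd.DataFrame(gene_rows).set_index("gene_id")

    introns_df = (
        pd.DataFrame(
            intron_rows,
            columns=["intron_id", "gene_id", "index", "contig", "strand", "start",
                     "end", "alt_start", "alt_end", "length", "is_3n", "is_last",
                     "signal_match", "cds_offset"],
        ).set_index("intron_id")
    )
    if len(introns_df):
        expr = genes_df.loc[introns_df["gene_id"], "expression"].to_numpy()
        n_in = genes_df.loc[introns_df["gene_id"], "n_introns"].to_numpy()
        err = intrinsic_error_rate(expr, n_in, params)
        s_ir = params.ir_assv_ratio / (1 + params.ir_assv_ratio)
        introns_df["expression"] = expr
        introns_df["n_introns"] = n_in
        introns_df["error_rate"] = err
        introns_df["e_ir"] = err * s_ir
        introns_df["e_assv"] = err * (1 - s_ir)
        introns_df["p_ir"] = introns_df["e_ir"] + params.functional_as_rate * s_ir
        introns_df["p_assv"] = (
            introns_df["e_assv"] + params.functional_as_rate * (1 - s_ir)
        )
        ir_vis, assv_vis = [], []
        for iid, row in introns_df.iterrows():
            cds = cds_strings[row["gene_id"]]
            pos, iseq = intron_local[iid]
            ir_vis.append(_insertion_creates_ptc(cds, iseq, pos, code))
            assv_vis.append(_insertion_creates_ptc(cds, iseq[:3], pos, code))
        introns_df["ir_visible"] = ir_vis
        introns_df["assv_visible"] = assv_vis

    pci_rows = []
    for gene in genes:
        cds = cds_strings[gene.id]
        exon_offsets = {}
        acc = 0
        for iv in gene.cds:
            exon_offsets[iv] = acc
            acc += iv[1] - iv[0]
        for pci in enumerate_pcis(gene, annotation):
            exon = next(
                iv for iv in gene.cds
                if iv[0] <= pci.interval[0] and pci.interval[1] <= iv[1]
            )
            if gene.strand == "+":
                local = exon_offsets[exon] + (pci.interval[0] - exon[0])
            else:
                local = exon_offsets[exon] + (exon[1] - pci.interval[1])
            pci_rows.append(
                {
                    "pci_id": pci.id,
                    "gene_id": gene.id,
                    "contig": gene.contig,
                    "strand": gene.strand,
                    "start": pci.interval[0],
                    "end": pci.interval[1],
                    "length": pci.length,
                    "is_3n": pci.is_3n,
                    "cds_offset": local,
                    "visible": _deletion_creates_ptc(cds, local, pci.length, code),
                }
            )
    pcis_df = (
        pd.DataFrame(
            pci_rows,
            columns=["pci_id", "gene_id", "contig", "strand", "start", "end",
                     "length", "is_3n", "cds_offset", "visible"],
        ).set_index("pci_id")
    )
    if len(pcis_df):
        expr = genes_df.loc[pcis_df["gene_id"], "expression"].to_numpy()
        cdsl = genes_df.loc[pcis_df["gene_id"], "cds_length"].to_numpy()
        rate = pci_intrinsic_rate(expr, cdsl, params)
        pcis_df["expression"] = expr
        pcis_df["cds_length"] = cdsl
        pcis_df["e_spl"] = rate
        pcis_df["p_spl"] = rate + params.functional_pci_rate

    truth = SimTruth(params=params, genes=genes_df, introns=introns_df, pcis=pcis_df)
    return annotation, truth


# ---------------------------------------------------------------------------
# junction reads
# ---------------------------------------------------------------------------


def _condition_rng(seed: int, condition: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(condition.encode())])


def simulate_junction_reads(
    truth: SimTruth,
    condition: str,
    seed: int | None = None,
    read_level: bool = False,
) -> JunctionCounts | pd.DataFrame:
    """Draw junction-spanning reads for one condition.

    Per element, the spanning-read total is Poisson(depth * RPKM) and reads
    are allocated multinomially across forms at the post-NMD expected
    frequencies. Returns aggregated :class:`JunctionCounts`, or a read-level
    table (read_id, gene_id, element_type, element_id, form) with
    ``read_level=True``.
    """
    params = truth.params
    if condition not in params.nmd_efficiency:
        raise KeyError(f"condition {condition!r} has no NMD efficiency")
    rng = _condition_rng(params.seed if seed is None else seed, condition)

    qi = truth.observed_intron_frequencies(condition)
    n_total = rng.poisson(qi["depth"].to_numpy())
    q_ir = qi["q_ir"].to_numpy()
    q_assv = qi["q_assv"].to_numpy()
    n3 = rng.binomial(n_total, q_ir)
    rest = n_total - n3
    with np.errstate(divide="ignore", invalid="ignore"):
        p2 = np.where(q_ir < 1, q_assv / (1 - q_ir), 0.0)
    n2 = rng.binomial(rest, np.clip(p2, 0, 1))
    n1 = rest - n2
    introns = pd.DataFrame(
        {"n1": n1, "n2": n2, "n3": n3}, index=truth.introns.index
    )

    qp = truth.observed_pci_frequencies(condition)
    m_total = rng.poisson(qp["depth"].to_numpy())
    m2 = rng.binomial(m_total, qp["q_spl"].to_numpy())
    pcis = pd.DataFrame(
        {"m1": m_total - m2, "m2": m2}, index=truth.pcis.index
    )
    counts = JunctionCounts(introns=introns, pcis=pcis)
    if not read_level:
        return counts
    return _expand_reads(counts, truth, condition)


_FORM_BY_COL = {"n1": "canonical", "n2": "ASSV", "n3": "IR",
                "m1": "unspliced", "m2": "spliced"}


def _expand_reads(
    counts: JunctionCounts, truth: SimTruth, condition: str
) -> pd.DataFrame:
    rows = []
    k = 0
    for table, meta, etype in (
        (counts.introns, truth.introns, "intron"),
        (counts.pcis, truth.pcis, "pci"),
    ):
        for eid, row in table.iterrows():
            gene_id = meta.at[eid, "gene_id"]
            for col, form in _FORM_BY_COL.items():
                for _ in range(int(row.get(col, 0) or 0)):
                    rows.append((f"{condition}.r{k}", gene_id, etype, eid, form))
                    k += 1
    return pd.DataFrame(
        rows, columns=["read_id", "gene_id", "element_type", "element_id", "form"]
    )


def render_alignments(
    read_table: pd.DataFrame,
    truth: SimTruth,
    anchor: int = 5,
) -> list[SplicedReadAlignment]:
    """Render read-level observations as block alignments (integration tests).

    Canonical reads gap exactly over the intron; IR/unspliced reads are
    contiguous; ASSV reads gap over the planted alternate interval; spliced
    PCI reads gap over the PCI.
    """
    out = []
    for _, r in read_table.iterrows():
        meta = truth.introns if r["element_type"] == "intron" else truth.pcis
        m = meta.loc[r["element_id"]]
        s, e = int(m["start"]), int(m["end"])
        if r["form"] in ("IR", "unspliced"):
            blocks = [(s - anchor, e + anchor)]
        elif r["form"] == "canonical":
            blocks = [(s - anchor, s), (e, e + anchor)]
        elif r["form"] == "spliced":
            blocks = [(s - anchor, s), (e, e + anchor)]
        elif r["form"] == "ASSV":
            a_s, a_e = int(m["alt_start"]), int(m["alt_end"])
            blocks = [(min(s, a_s) - anchor, a_s), (a_e, max(e, a_e) + anchor)]
        else:
            continue
        out.append(
            SplicedReadAlignment(
                read_id=r["read_id"], contig=m["contig"], blocks=blocks
            )
        )
    return out


# ---------------------------------------------------------------------------
# SNPs
# ---------------------------------------------------------------------------


@dataclass
class SnpConstraintParams:
    """Expression-dependent constraint on splice-site polymorphism.

    ``g`` maps RPKM to the relative SNP retention at splice sites
    (non-increasing, in [0, 1]); third codon positions are unconstrained at
    ``pi3_base``. Built-ins: "constant" (g = 1) and ("inverse", c) for
    g(E) = min(1, c/E).
    """

    pi3_base: float = 0.026
    g: str | tuple[str, float] | Callable[[float], float] = "constant"
    other_exon_factor: float = 0.3  # codon positions 1/2
    intron_body_factor: float = 0.8

    def g_of(self, expression: np.ndarray) -> np.ndarray:
        if callable(self.g):
            return np.clip([self.g(float(e)) for e in expression], 0, 1)
        if self.g == "constant":
            return np.ones_like(expression, dtype=float)
        if isinstance(self.g, tuple) and self.g[0] == "inverse":
            return np.minimum(1.0, self.g[1] / expression)
        raise ValueError(f"unknown constraint spec {self.g!r}")


def simulate_snps(
    annotation: GenomeAnnotation,
    truth: SimTruth,
    constraint: SnpConstraintParams,
    seed: int | None = None,
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Place SNPs around exon-intron boundaries under the constraint model.

    Per unique genomic site, a SNP occurs Bernoulli at a category-dependent
    density; splice-site assignment takes precedence where windows of
    neighbouring introns share a site. Returns a biallelic SNV table
    (contig, pos, ref, alt), deterministic per seed. A precomputed survey
    table (:func:`splicenoise.polymorphism.survey_sites`) may be passed when
    drawing many replicates.
    """
    rng = np.random.default_rng(
        truth.params.seed + 1_000_003 if seed is None else seed
    )
    genes = {g.id: g for g in annotation.genes}
    if sites is None:
        sites = polymorphism.survey_sites(all_introns(annotation), genes)
    prio = {"splice_site": 0, "exon": 1, "intron": 2}
    uniq = (
        sites.assign(_prio=sites["category"].map(prio))
        .sort_values(["contig", "position", "_prio"], kind="stable")
        .drop_duplicates(["contig", "position"], keep="first")
    )
    expr = truth.genes.loc[uniq["gene_id"], "expression"].to_numpy()
    g_val = constraint.g_of(expr)
    rate = np.full(len(uniq), constraint.pi3_base)
    cat = uniq["category"].to_numpy()
    cp = uniq["codon_position"].to_numpy()
    rate[cat == "splice_site"] = constraint.pi3_base * g_val[cat == "splice_site"]
    rate[cat == "intron"] *= constraint.intron_body_factor
    other_exon = (cat == "exon") & (cp != 3)
    rate[other_exon] *= constraint.other_exon_factor
    hit = rng.random(len(uniq)) < rate
    out = uniq.loc[hit, ["contig", "position"]].rename(columns={"position": "pos"})
    refs = [annotation.sequences[c][p] for c, p in zip(out["contig"], out["pos"])]
    alts = [
        rng.choice([b for b in "ACGT" if b != ref]) for ref in refs
    ]
    out = out.assign(ref=refs, alt=alts)
    return out.sort_values(["contig", "pos"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_reads_tsv(read_table: pd.DataFrame, path: str) -> None:
    read_table.to_csv(path, sep="\t", index=False)


def write_truth_json(truth: SimTruth, path: str) -> None:
    payload = {
        "params": {
            k: (v if not isinstance(v, tuple) else list(v))
            for k, v in asdict(truth.params).items()
        },
        "genes": truth.genes.reset_index().to_dict(orient="list"),
        "introns": truth.introns.reset_index().to_dict(orient="list"),
        "pcis": truth.pcis.reset_index().to_dict(orient="list"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def write_vcf(snps: pd.DataFrame, annotation: GenomeAnnotation, path: str) -> None:
    """Write the SNV table as VCF 4.2."""
    import pysam

    header = pysam.VariantHeader()
    for name, seq in annotation.sequences.items():
        header.contigs.add(name, length=len(seq))
    with pysam.VariantFile(path, "w", header=header) as vf:
        for _, r in snps.iterrows():
            rec = vf.new_record(
                contig=r["contig"], start=int(r["pos"]), stop=int(r["pos"]) + 1,
                alleles=(r["ref"], r["alt"]),
            )
            vf.write(rec)
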