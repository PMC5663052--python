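"""SNP-density profiles and the pi_spl/pi_3 splice-site constraint ratio.

Purifying selection on splice signals is measured from polymorphism: the SNP
density at splice sites (the first and last 2 nt of introns), pi_spl, is
compared to the density at third codon positions of the flanking exons,
pi_3, which are nearly neutral. The windows follow the boundary-profile
convention: the last 20 exonic nt + first 30 intronic nt around the donor,
and the last 30 intronic nt + first 20 exonic nt around the acceptor. For
very short introns the donor and acceptor windows overlap; intronic
positions are deduplicated per intron.

Density denominators count surveyed sites (intron-position pairs), not
genome positions: a genomic site shared by two introns' windows is counted
once per intron. All bulk statistics run off a tidy "survey table" built
once by :func:`survey_sites`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .annotation import GeneModel, Intron
from .rates import assign_equal_size_bins, wilson_interval

EXON_FLANK = 20
INTRON_FLANK = 30

SPLICE_SITE = "splice_site"
INTRON_BODY = "intron"
EXON = "exon"


@dataclass(frozen=True)
class Site:
    """One surveyed position of an intron's boundary windows."""

    position: int  # genomic, 0-based
    category: str  # splice_site | intron | exon
    codon_position: int | None  # 1/2/3 for exonic sites in the CDS
    window: str  # donor | acceptor
    rel: int  # window-relative offset (negative upstream of the boundary)


def _transcript_order(interval: tuple[int, int], strand: str) -> list[int]:
    s, e = interval
    return list(range(s, e)) if strand == "+" else list(range(e - 1, s - 1, -1))


def _cds_offset(gene: GeneModel, position: int) -> int | None:
    """Coding-strand CDS offset of a genomic position, or None outside CDS."""
    acc = 0
    for s, e in gene.cds:
        if s <= position < e:
            if gene.strand == "+":
                return acc + (position - s)
            return acc + (e - 1 - position)
        acc += e - s
    return None


def extract_boundary_windows(
    intron: Intron,
    gene: GeneModel,
    exon_flank: int = EXON_FLANK,
    intron_flank: int = INTRON_FLANK,
) -> list[Site]:
    """Surveyed sites of one intron's donor and acceptor windows.

    Exonic flanks shorter than ``exon_flank`` are truncated; introns shorter
    than twice ``intron_flank`` have their duplicated intronic positions
    reported once (under the donor window). Introns shorter than 4 nt are an
    error (splice sites would overlap).
    """
    if intron.length < 4:
        raise ValueError(f"intron {intron.id} shorter than 4 nt")
    ipos = _transcript_order(intron.interval, intron.strand)
    splice_sites = set(ipos[:2] + ipos[-2:])
    upstream = _transcript_order(gene.exons[intron.index - 1], gene.strand)
    downstream = _transcript_order(gene.exons[intron.index], gene.strand)

    sites: list[Site] = []

    def exon_site(pos: int, window: str, rel: int) -> Site:
        off = _cds_offset(gene, pos)
        return Site(pos, EXON, None if off is None else off % 3 + 1, window, rel)

    up = upstream[-exon_flank:]
    for rel, pos in enumerate(up, start=-len(up)):
        sites.append(exon_site(pos, "donor", rel))
    covered: set[int] = set()
    for rel, pos in enumerate(ipos[:intron_flank], start=1):
        cat = SPLICE_SITE if pos in splice_sites else INTRON_BODY
        sites.append(Site(pos, cat, None, "donor", rel))
        covered.add(pos)
    acceptor_intronic = ipos[-intron_flank:]
    for rel, pos in enumerate(acceptor_intronic, start=-len(acceptor_intronic)):
        if pos in covered:
            continue
        cat = SPLICE_SITE if pos in splice_sites else INTRON_BODY
        sites.append(Site(pos, cat, None, "acceptor", rel))
    down = downstream[:exon_flank]
    for rel, pos in enumerate(down, start=1):
        sites.append(exon_site(pos, "acceptor", rel))
    return sites


def survey_sites(
    introns: list[Intron],
    genes: dict[str, GeneModel],
    exon_flank: int = EXON_FLANK,
    intron_flank: int = INTRON_FLANK,
) -> pd.DataFrame:
    """Tidy survey table of all (intron, site) pairs.

    Columns: intron_id, gene_id, contig, position, category, codon_position,
    window, rel. One row per surveyed intron-position pair.
    """
    rows = []
    for intron in introns:
        gene = genes[intron.gene_id]
        for s in extract_boundary_windows(intron, gene, exon_flank, intron_flank):
            rows.append(
                (intron.id, intron.gene_id, intron.contig, s.position,
                 s.category, s.codon_position, s.window, s.rel)
            )
    return pd.DataFrame(
        rows,
        columns=["intron_id", "gene_id", "contig", "position", "category",
                 "codon_position", "window", "rel"],
    )


def _with_hits(sites: pd.DataFrame, snps: pd.DataFrame) -> pd.DataFrame:
    lookup = set(zip(snps["contig"], snps["pos"]))
    out = sites.copy()
    out["hit"] = [
        (c, p) in lookup for c, p in zip(sites["contig"], sites["position"])
    ]
    return out


def snp_density_profile(
    introns: list[Intron],
    genes: dict[str, GeneModel],
    snps: pd.DataFrame,
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per relative-position SNP density around exon-intron boundaries.

    Density at a relative position is the fraction of introns carrying a SNP
    there, among introns contributing that position. Exonic positions are
    split by codon position.
    """
    if sites is None:
        sites = survey_sites(introns, genes)
    tab = _with_hits(sites, snps)
    grouped = tab.groupby(
        ["window", "rel", "category", "codon_position"], dropna=False, sort=True
    )["hit"]
    out = grouped.agg(n_introns="count", n_snps="sum").reset_index()
    out["density"] = out["n_snps"] / out["n_introns"]
    return out


@dataclass
class PiRatio:
    """pi_spl / pi_3 with the raw counts behind both densities."""

    spl_snps: int
    spl_sites: int
    third_snps: int
    third_sites: int

    @property
    def pi_spl(self) -> float:
        return self.spl_snps / self.spl_sites

    @property
    def pi3(self) -> float:
        return self.third_snps / self.third_sites

    @property
    def ratio(self) -> float:
        return self.pi_spl / self.pi3

    def ratio_ci(self, alpha: float = 0.05) -> tuple[float, float]:
        """Katz log-ratio CI; a 0.5 continuity correction guards zero counts."""
        x1, n1 = self.spl_snps, self.spl_sites
        x2, n2 = self.third_snps, self.third_sites
        if x1 == 0 or x2 == 0:
            x1, x2 = x1 + 0.5, x2 + 0.5
        log_ratio = np.log((x1 / n1) / (x2 / n2))
        se = np.sqrt(1 / x1 - 1 / n1 + 1 / x2 - 1 / n2)
        z = norm.ppf(1 - alpha / 2)
        return float(np.exp(log_ratio - z * se)), float(np.exp(log_ratio + z * se))


def _pi_counts(tab: pd.DataFrame) -> PiRatio:
    spl = tab["category"] == SPLICE_SITE
    third = (tab["category"] == EXON) & (tab["codon_position"] == 3)
    return PiRatio(
        spl_snps=int(tab.loc[spl, "hit"].sum()),
        spl_sites=int(spl.sum()),
        third_snps=int(tab.loc[third, "hit"].sum()),
        third_sites=int(third.sum()),
    )


def pi_ratio(
    introns: list[Intron],
    genes: dict[str, GeneModel],
    snps: pd.DataFrame,
    sites: pd.DataFrame | None = None,
) -> PiRatio:
    """Pooled pi_spl/pi_3 over a set of introns.

    pi_spl counts SNPs at the 4 splice-site nucleotides of each intron;
    pi_3 counts SNPs at third codon positions within the flanking exonic
    windows. Sites are deduplicated within an intron but counted once per
    intron when shared between introns. pi_3 = 0 is an error (ratio
    undefined).
    """
    if sites is None:
        sites = survey_sites(introns, genes)
    pr = _pi_counts(_with_hits(sites, snps))
    if pr.third_sites == 0 or pr.third_snps == 0:
        raise ValueError("pi_3 is zero or unsurveyed; ratio undefined")
    return pr


def ratio_by_bin(
    introns: list[Intron],
    genes: dict[str, GeneModel],
    snps: pd.DataFrame,
    keys: pd.Series,
    n_bins: int = 10,
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """pi_spl/pi_3 per equal-size bin of ``keys`` (expression or IR rate).

    ``keys`` is indexed by intron id. Bins whose pi_3 count is zero are
    flagged (NaN ratio). Per-bin pi_3 is reported as the neutral control.
    """
    if sites is None:
        sites = survey_sites(introns, genes)
    bins = assign_equal_size_bins(keys, n_bins)
    tab = _with_hits(sites, snps)
    tab["bin"] = bins.reindex(tab["intron_id"]).to_numpy()
    rows = []
    for b in range(n_bins):
        pr = _pi_counts(tab[tab["bin"] == b])
        flagged = pr.third_sites == 0 or pr.third_snps == 0
        ids = bins.index[bins == b]
        rows.append(
            {
                "bin": b,
                "n_introns": len(ids),
                "spl_snps": pr.spl_snps,
                "spl_sites": pr.spl_sites,
                "third_snps": pr.third_snps,
                "third_sites": pr.third_sites,
                "pi_spl": pr.pi_spl if pr.spl_sites else np.nan,
                "pi3": pr.pi3 if pr.third_sites else np.nan,
                "ratio": np.nan if flagged else pr.ratio,
                "flagged": flagged,
                "mean_key": float(keys.loc[ids].mean()),
            }
        )
    return pd.DataFrame(rows)


def consensus_fraction_by_bin(
    introns: list[Intron],
    keys: pd.Series,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Per-bin fractions of GT donors and AG acceptors, with Wilson 95% CIs."""
    by_id = {i.id: i for i in introns}
    bins = assign_equal_size_bins(keys, n_bins)
    rows = []
    for b in range(n_bins):
        ids = bins.index[bins == b]
        n = len(ids)
        gt = sum(by_id[i].donor2 == "GT" for i in ids)
        ag = sum(by_id[i].acceptor2 == "AG" for i in ids)
        gt_lo, gt_hi = wilson_interval(gt, n)
        ag_lo, ag_hi = wilson_interval(ag, n)
        rows.append(
            {
                "bin": b, "n_introns": n,
                "gt_fraction": gt / n, "gt_ci_low": gt_lo, "gt_ci_high": gt_hi,
                "ag_fraction": ag / n, "ag_ci_low": ag_lo, "ag_ci_high": ag_hi,
                "mean_key": float(keys.loc[ids].mean()),
            }
        )
    return pd.DataFrame(rows)


def read_snps(vcf_path: str) -> pd.DataFrame:
    """Read biallelic SNVs from a VCF; indels and multiallelics are dropped.

    Returns (contig, pos, ref, alt) with 0-based positions and the number of
    dropped records in ``attrs['n_dropped']``.
    """
    import pysam

    rows = []
    dropped = 0
    with pysam.VariantFile(vcf_path) as vf:
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                dropped += 1
                continue
            rows.append((rec.contig, rec.start, rec.ref, alts[0]))
    out = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    out.attrs["n_dropped"] = dropped
    return out
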