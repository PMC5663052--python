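"""Boundary windows, SNP-density profiles and the pi_spl/pi_3 ratio."""

import numpy as np
import pandas as pd
import pytest

import splicenoise as sn
from splicenoise import polymorphism as poly
from splicenoise.annotation import all_introns, derive_introns

from conftest import build_gene


def _snps(pairs):
    return pd.DataFrame(
        [(c, p, "A", "T") for c, p in pairs],
        columns=["contig", "pos", "ref", "alt"],
    )


@pytest.fixture()
def toy():
    intron = "GT" + "A" * 26 + "AG"  # 30 nt
    genome, gene = build_gene(
        [("exon", "ATG" + "CCT" * 9), ("intron", intron),
         ("exon", "CCT" * 10 + "TGA")],
        pad=10,
    )
    return genome, gene, derive_introns(gene, genome)[0]


class TestBoundaryWindows:
    def test_thirty_nt_intron_positions_appear_once(self, toy):
        _, gene, intron = toy
        sites = poly.extract_boundary_windows(intron, gene)
        intronic = [s for s in sites if s.category != poly.EXON]
        assert len(intronic) == 30  # fully covered, no duplicates
        assert len({s.position for s in intronic}) == 30
        splice = [s for s in sites if s.category == poly.SPLICE_SITE]
        assert len(splice) == 4

    def test_exonic_codon_positions_follow_frame(self, toy):
        _, gene, intron = toy
        sites = poly.extract_boundary_windows(intron, gene)
        donor_exon = {s.rel: s for s in sites if s.window == "donor"
                      and s.category == poly.EXON}
        # exon1 is 30 nt: the nt immediately 5' of the donor is CDS offset 29,
        # i.e. codon position 29 % 3 + 1 = 3
        assert donor_exon[-1].codon_position == 3
        assert donor_exon[-2].codon_position == 2
        assert donor_exon[-3].codon_position == 1

    def test_minus_strand_windows_mirror(self):
        intron = "GT" + "A" * 26 + "AG"
        genome, gene = build_gene(
            [("exon", "ATG" + "CCT" * 9), ("intron", intron),
             ("exon", "CCT" * 10 + "TGA")],
            strand="-", pad=10,
        )
        fwd_genome, fwd_gene = build_gene(
            [("exon", "ATG" + "CCT" * 9), ("intron", intron),
             ("exon", "CCT" * 10 + "TGA")],
            strand="+", pad=10,
        )
        rev = poly.extract_boundary_windows(
            derive_introns(gene, genome)[0], gene
        )
        fwd = poly.extract_boundary_windows(
            derive_introns(fwd_gene, fwd_genome)[0], fwd_gene
        )
        by_key = lambda sites: {(s.window, s.rel): s for s in sites}
        rk, fk = by_key(rev), by_key(fwd)
        assert rk.keys() == fk.keys()
        for key in fk:
            assert rk[key].category == fk[key].category
            assert rk[key].codon_position == fk[key].codon_position
        # donor window is transcriptionally upstream: on the minus strand its
        # genomic coordinates are the mirror image of the plus-strand ones
        total = len(genome.sequences["c1"]) - 1
        for key in fk:
            assert rk[key].position == total - fk[key].position

    def test_tiny_intron_is_an_error(self):
        genome, gene = build_gene(
            [("exon", "A" * 30), ("intron", "GTG"), ("exon", "A" * 30)]
        )
        with pytest.raises(ValueError, match="shorter than 4"):
            poly.extract_boundary_windows(derive_introns(gene, genome)[0], gene)


class TestDensityProfile:
    def test_no_snps_means_zero_density(self, toy):
        genome, gene, intron = toy
        prof = poly.snp_density_profile([intron], {gene.id: gene}, _snps([]))
        assert (prof["density"] == 0).all()

    def test_snp_at_every_donor_gt(self, toy):
        genome, gene, intron = toy
        s = intron.interval[0]
        prof = poly.snp_density_profile(
            [intron], {gene.id: gene}, _snps([("c1", s), ("c1", s + 1)])
        )
        donor12 = prof[(prof["window"] == "donor") & (prof["rel"].isin([1, 2]))]
        assert (donor12["density"] == 1.0).all()
        rest = prof[~((prof["window"] == "donor") & (prof["rel"].isin([1, 2])))]
        assert (rest["density"] == 0.0).all()

    def test_uniform_snps_give_flat_profile(self, mid_sim):
        _, genome, _ = mid_sim
        rng = np.random.default_rng(17)
        pairs = [
            (name, int(p))
            for name, seq in genome.sequences.items()
            for p in np.flatnonzero(rng.random(len(seq)) < 0.01)
        ]
        introns = all_introns(genome)
        genes = {g.id: g for g in genome.genes}
        prof = poly.snp_density_profile(introns, genes, _snps(pairs))
        pooled = prof["n_snps"].sum() / prof["n_introns"].sum()
        assert pooled == pytest.approx(0.01, abs=0.002)
        assert prof["density"].max() < 0.04


class TestPiRatio:
    def test_equal_densities_give_unit_ratio(self, toy):
        genome, gene, intron = toy
        sites = poly.extract_boundary_windows(intron, gene)
        pairs = [("c1", s.position) for s in sites]  # SNP everywhere
        pr = poly.pi_ratio([intron], {gene.id: gene}, _snps(pairs))
        assert pr.ratio == 1.0

    def test_no_splice_site_snps_zero_ratio(self, toy):
        genome, gene, intron = toy
        third = [
            s.position for s in poly.extract_boundary_windows(intron, gene)
            if s.category == poly.EXON and s.codon_position == 3
        ]
        pr = poly.pi_ratio(
            [intron], {gene.id: gene}, _snps([("c1", p) for p in third[:3]])
        )
        assert pr.ratio == 0.0

    def test_hand_counted_planted_ratio(self, toy):
        genome, gene, intron = toy
        sites = poly.extract_boundary_windows(intron, gene)
        splice = [s.position for s in sites if s.category == poly.SPLICE_SITE]
        third = [s.position for s in sites
                 if s.category == poly.EXON and s.codon_position == 3]
        # plant 1 of 4 splice-site SNPs and 3 third-position SNPs
        pairs = [("c1", splice[0])] + [("c1", p) for p in third[:3]]
        pr = poly.pi_ratio([intron], {gene.id: gene}, _snps(pairs))
        assert (pr.spl_snps, pr.spl_sites) == (1, 4)
        assert pr.third_snps == 3 and pr.third_sites == len(third)
        assert pr.ratio == pytest.approx((1 / 4) / (3 / len(third)))

    def test_agrees_with_bruteforce_site_tally(self, small_sim):
        _, genome, _ = small_sim
        genes = {g.id: g for g in genome.genes}
        introns = all_introns(genome)[:100]
        rng = np.random.default_rng(23)
        pairs = [
            (name, int(p))
            for name, seq in genome.sequences.items()
            for p in np.flatnonzero(rng.random(len(seq)) < 0.02)
        ]
        snps = _snps(pairs)
        pr = poly.pi_ratio(introns, genes, snps)
        # independent per-site recount
        lookup = set(pairs)
        spl = [0, 0]
        third = [0, 0]
        for intron in introns:
            for site in poly.extract_boundary_windows(intron, genes[intron.gene_id]):
                hit = (intron.contig, site.position) in lookup
                if site.category == "splice_site":
                    spl[0] += 1
                    spl[1] += hit
                elif site.category == "exon" and site.codon_position == 3:
                    third[0] += 1
                    third[1] += hit
        assert (pr.spl_sites, pr.spl_snps) == tuple(spl)
        assert (pr.third_sites, pr.third_snps) == tuple(third)


def test_consensus_fractions_all_one_for_gt_ag_introns(mid_sim):
    _, genome, truth = mid_sim
    introns = all_introns(genome)
    keys = truth.introns["expression"]
    tab = poly.consensus_fraction_by_bin(introns, keys, 10)
    assert (tab["gt_fraction"] == 1.0).all()
    assert (tab["ag_fraction"] == 1.0).all()
    assert len(tab) == 10 and tab["n_introns"].min() > 0


def test_ratio_by_bin_structure(mid_sim):
    _, genome, truth = mid_sim
    genes = {g.id: g for g in genome.genes}
    introns = all_introns(genome)
    snps = sn.simulate_snps(genome, truth, sn.SnpConstraintParams(), seed=41)
    tab = poly.ratio_by_bin(introns, genes, snps, truth.introns["expression"], 10)
    assert len(tab) == 10
    assert tab["n_introns"].sum() == len(introns)
    assert (tab.loc[~tab["flagged"], "ratio"] > 0).all()
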