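"""Synthetic-data generator: determinism, rate model, NMD action, SNPs."""

import json

import numpy as np
import pandas as pd
import pytest

import splicenoise as sn
from splicenoise import nmd, polymorphism as poly
from splicenoise.annotation import all_introns, derive_introns, write_gff3
from splicenoise.events import classify_read_for_intron, detect_cryptic_splicing
from splicenoise.simulate import pci_intrinsic_rate, render_alignments


def test_generation_is_deterministic(tmp_path):
    runs = []
    for _ in range(2):
        genome, truth = sn.generate_genome(sn.TruthParams(n_genes=20, seed=1))
        gff = tmp_path / "x.gff3"
        write_gff3(genome, str(gff))
        counts = sn.simulate_junction_reads(truth, "WT")
        runs.append((genome.sequences, gff.read_text(), counts.introns.copy()))
    assert runs[0][0] == runs[1][0]
    assert runs[0][1] == runs[1][1]
    pd.testing.assert_frame_equal(runs[0][2], runs[1][2])


def test_all_mass_on_zero_introns():
    genome, truth = sn.generate_genome(
        sn.TruthParams(n_genes=15, seed=2, intron_count_weights={0: 1.0})
    )
    assert len(truth.introns) == 0
    assert all(derive_introns(g, genome) == [] for g in genome.genes)


def test_intron_construction_invariants(small_sim):
    _, genome, truth = small_sim
    for intron in all_introns(genome):
        assert 20 <= intron.length <= 35
        assert intron.donor2 == "GT" and intron.acceptor2 == "AG"
        assert intron.seq[3:5] == "GT"  # planted alternate donor
        assert truth.introns.at[intron.id, "length"] == intron.length


def test_intrinsic_error_rate_formula():
    p0 = sn.TruthParams(alpha=0.0, beta=0.0, epsilon0=0.2)
    assert sn.intrinsic_error_rate(5.0, 3, p0) == 0.2
    p1 = sn.TruthParams(alpha=1.0, beta=0.0, epsilon0=0.1)
    assert sn.intrinsic_error_rate(10.0, 1, p1) == pytest.approx(0.01)
    with pytest.raises(ValueError):
        sn.intrinsic_error_rate(0.0, 1, p1)


def test_error_rate_monotone_in_expression_and_introns():
    rng = np.random.default_rng(3)
    for _ in range(200):
        p = sn.TruthParams(
            alpha=float(rng.uniform(0, 2)), beta=float(rng.uniform(0, 1)),
            epsilon0=float(rng.uniform(0.01, 0.5)),
        )
        e = float(rng.uniform(0.1, 100))
        n = int(rng.integers(1, 8))
        assert sn.intrinsic_error_rate(2 * e, n, p) <= sn.intrinsic_error_rate(e, n, p)
        assert sn.intrinsic_error_rate(e, n + 1, p) <= sn.intrinsic_error_rate(e, n, p)


@pytest.fixture(scope="module")
def nmd_off_sim():
    params = sn.TruthParams(
        n_genes=60, seed=11, nmd_efficiency={"OFF": 0.0, "FULL": 1.0}
    )
    return params, *sn.generate_genome(params)


def test_no_degradation_recovers_intrinsic_frequencies(nmd_off_sim):
    params, genome, truth = nmd_off_sim
    exp_ir = (truth.introns["p_ir"] * truth.observed_intron_frequencies("OFF")["depth"]).sum()
    got = 0
    total = 0
    for rep in range(10):
        counts = sn.simulate_junction_reads(truth, "OFF", seed=100 + rep)
        got += counts.introns["n3"].sum()
        total += counts.introns.to_numpy().sum()
    se = np.sqrt(10 * exp_ir)  # Poisson scale over replicates
    assert abs(got - 10 * exp_ir) < 3 * se


def test_full_degradation_silences_visible_variants(nmd_off_sim):
    params, genome, truth = nmd_off_sim
    counts = sn.simulate_junction_reads(truth, "FULL", seed=5)
    vis = truth.introns["ir_visible"]
    assert counts.introns.loc[vis, "n3"].sum() == 0
    # invisible variants keep their intrinsic expected count
    q = truth.observed_intron_frequencies("FULL")
    exp = (q.loc[~vis, "q_ir"] * q.loc[~vis, "depth"]).sum()
    got = counts.introns.loc[~vis, "n3"].sum()
    assert abs(got - exp) < 3 * np.sqrt(exp)


def test_read_level_table_reproducible(nmd_off_sim):
    _, _, truth = nmd_off_sim
    t1 = sn.simulate_junction_reads(truth, "OFF", seed=9, read_level=True)
    t2 = sn.simulate_junction_reads(truth, "OFF", seed=9, read_level=True)
    pd.testing.assert_frame_equal(t1, t2)


def test_truth_bookkeeping_matches_manual_computation(small_sim):
    params, genome, truth = small_sim
    ids = truth.introns.index[:40]
    d = params.nmd_efficiency["WT"]
    num = den = 0.0
    for iid in ids:
        row = truth.introns.loc[iid]
        w_ir = 1 - d if row["ir_visible"] else 1.0
        w_assv = 1 - d if row["assv_visible"] else 1.0
        z = (1 - row["p_ir"] - row["p_assv"]) + row["p_ir"] * w_ir + row["p_assv"] * w_assv
        depth = params.read_depth_per_rpkm * row["expression"]
        num += depth * (row["e_ir"] * w_ir + row["e_assv"] * w_assv) / z
        den += depth * (row["p_ir"] * w_ir + row["p_assv"] * w_assv) / z
    assert truth.true_error_proportion("WT", ids) == pytest.approx(num / den, rel=1e-12)


def test_planted_visibility_labels_match_full_classifier(small_sim):
    """The generator's incremental PTC labels equal full reconstruction."""
    params, genome, truth = small_sim
    introns = {i.id: i for i in all_introns(genome)}
    for iid, row in truth.introns.iterrows():
        gene = genome.gene(row["gene_id"])
        ir = nmd.classify_nmd(
            nmd.apply_event_to_cds(gene, nmd.Event.ir(introns[iid]), genome)
        )
        assert ir.nmd_visible == row["ir_visible"], iid
        alt = (int(row["alt_start"]), int(row["alt_end"]))
        assv = nmd.classify_nmd(
            nmd.apply_event_to_cds(
                gene, nmd.Event.assv(introns[iid], alt), genome
            )
        )
        assert assv.nmd_visible == row["assv_visible"], iid
    sample = truth.pcis.sample(n=min(150, len(truth.pcis)), random_state=0)
    for pid, row in sample.iterrows():
        gene = genome.gene(row["gene_id"])
        ev = nmd.Event(
            "PCI", gene.id, (int(row["start"]), int(row["end"]))
        )
        got = nmd.classify_nmd(nmd.apply_event_to_cds(gene, ev, genome))
        assert got.nmd_visible == row["visible"], pid


def test_simulated_reads_classify_without_error():
    """Rendered alignments reproduce the generator's form for every element."""
    params = sn.TruthParams(
        n_genes=6, seed=21, expression_log10_range=(0.0, 1.0),
        read_depth_per_rpkm=0.8,
    )
    genome, truth = sn.generate_genome(params)
    table = sn.simulate_junction_reads(truth, "NMD", read_level=True)
    assert len(table) > 50
    reads = {r.read_id: r for r in render_alignments(table, truth)}
    introns = {i.id: i for i in all_introns(genome)}
    pcis = {
        pid: row for pid, row in truth.pcis.iterrows()
    }
    from splicenoise.annotation import PCI

    for _, obs in table.iterrows():
        read = reads[obs["read_id"]]
        if obs["element_type"] == "intron":
            got = classify_read_for_intron(read, introns[obs["element_id"]], genome)
            want = {"canonical": "canonical", "IR": "IR", "ASSV": "ASSV"}[obs["form"]]
        else:
            row = pcis[obs["element_id"]]
            pci = PCI(
                gene_id=row["gene_id"], contig=row["contig"], strand=row["strand"],
                interval=(int(row["start"]), int(row["end"])), seq="GT..AG",
            )
            got = detect_cryptic_splicing(read, pci)
            want = obs["form"]
        assert got == want


def test_pci_rate_decreases_with_cds_length():
    p = sn.TruthParams()
    assert pci_intrinsic_rate(10.0, 2400, p) < pci_intrinsic_rate(10.0, 300, p)


def test_snps_constant_constraint_ratio_near_one(mid_sim):
    _, genome, truth = mid_sim
    genes = {g.id: g for g in genome.genes}
    introns = all_introns(genome)
    snps = sn.simulate_snps(genome, truth, sn.SnpConstraintParams(), seed=31)
    pr = poly.pi_ratio(introns, genes, snps)
    lo, hi = pr.ratio_ci(alpha=0.01)
    assert lo <= 1.0 <= hi


def test_snps_full_constraint_empties_splice_sites(mid_sim):
    _, genome, truth = mid_sim
    genes = {g.id: g for g in genome.genes}
    introns = all_introns(genome)
    snps = sn.simulate_snps(
        genome, truth, sn.SnpConstraintParams(g=("inverse", 0.0)), seed=32
    )
    pr = poly.pi_ratio(introns, genes, snps)
    assert pr.spl_snps == 0 and pr.ratio == 0.0


def test_vcf_round_trip(tmp_path, small_sim):
    _, genome, truth = small_sim
    from splicenoise.simulate import write_vcf

    snps = sn.simulate_snps(genome, truth, sn.SnpConstraintParams(), seed=33)
    path = tmp_path / "snps.vcf"
    write_vcf(snps, genome, str(path))
    back = poly.read_snps(str(path))
    pd.testing.assert_frame_equal(back, snps.astype({"pos": back["pos"].dtype}))


def test_truth_json_writer(tmp_path, small_sim):
    _, _, truth = small_sim
    from splicenoise.simulate import write_truth_json

    path = tmp_path / "truth.json"
    write_truth_json(truth, str(path))
    payload = json.loads(path.read_text())
    assert payload["params"]["n_genes"] == 80
    assert len(payload["introns"]["intron_id"]) == len(truth.introns)
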