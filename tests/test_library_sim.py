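"""Fixture generator: determinism, planted-locus recovery, cohort designs."""
import numpy as np
import pytest

from migseq import constants as C
from migseq.insilico_pcr import predict_amplicons, find_annealing_sites
from migseq.library_sim import (CohortSpec, SimConfig, locus_windows,
                                make_barcodes, parse_read_id, simulate_cohort,
                                simulate_genome, simulate_reads,
                                truth_to_matrix)
from migseq.matrix import parse_genotype
from migseq.primer_design import published_set1


def test_planted_loci_are_recovered_exactly_in_strict_mode(set1):
    cfg = SimConfig(seed=1, n_loci=5, genome_len=10_000)
    genome, loci = simulate_genome(cfg)
    amps = predict_amplicons(find_annealing_sites(genome, set1))
    assert len(amps) == 5
    got = sorted((a.fwd_site.start, a.rev_site.end) for a in amps)
    want = sorted((int(r.fwd_start), int(r.rev_end)) for r in loci.itertuples())
    assert got == want


def test_same_seed_reproduces_identical_genome():
    a, _ = simulate_genome(SimConfig(seed=3, n_loci=4, genome_len=8_000))
    b, _ = simulate_genome(SimConfig(seed=3, n_loci=4, genome_len=8_000))
    assert a == b


def test_zero_loci_gives_background_only(set1):
    genome, loci = simulate_genome(SimConfig(seed=2, n_loci=0, genome_len=3_000))
    assert len(loci) == 0
    assert predict_amplicons(find_annealing_sites(genome, set1)) == []


def test_infeasible_packing_raises():
    with pytest.raises(ValueError):
        simulate_genome(SimConfig(seed=1, n_loci=50, genome_len=5_000))


def test_seed_is_mandatory_and_rates_validated():
    with pytest.raises(ValueError):
        SimConfig(seed=None)
    with pytest.raises(ValueError):
        SimConfig(seed=1, pcr_error_rate=1.5)


def test_megagametophyte_allele_counts_are_conserved_and_balanced(small_sim):
    truth = small_sim.truth
    haploids = [s for s in truth.samples.index if truth.samples.at[s, "ploidy"] == 1]
    het_sites = []
    for sid, srow in truth.sites.iterrows():
        mg = truth.genotypes.at["mother_rep1", sid]
        if len(set(str(mg).split("/"))) == 2:
            het_sites.append(sid)
    assert het_sites
    total_alt = total = 0
    for sid in het_sites:
        srow = truth.sites.loc[sid]
        alleles = [truth.genotypes.at[h, sid] for h in haploids]
        assert len(alleles) == 16  # conservation: one allele per haploid
        total_alt += sum(a == srow.alt for a in alleles)
        total += len(alleles)
    # 1:1 segregation within binomial error (4 sigma)
    p = total_alt / total
    assert abs(p - 0.5) < 4 * np.sqrt(0.25 / total)


def test_clonal_design_with_zero_somatic_changes_is_identical():
    cfg = SimConfig(seed=5, n_loci=40, genome_len=50_000, read2_snp_rate=0.0)
    _, loci = simulate_genome(cfg)
    spec = CohortSpec(design="clonal_ramets", n_genets=2, ramets_per_genet=3,
                      somatic_diff_count=0, min_inter_diff=5)
    truth = simulate_cohort(loci, spec, cfg)
    for genet in ("genet1", "genet2"):
        members = [s for s in truth.samples.index
                   if truth.samples.at[s, "genet"] == genet]
        rows = [tuple(truth.genotypes.loc[m]) for m in members]
        assert len(set(rows)) == 1


def test_replicate_pair_duplicates_the_first_sample():
    cfg = SimConfig(seed=6, n_loci=10, genome_len=16_000)
    _, loci = simulate_genome(cfg)
    truth = simulate_cohort(loci, CohortSpec(design="replicate_pair"), cfg)
    assert tuple(truth.genotypes.loc["sample_01"]) == \
        tuple(truth.genotypes.loc["sample_01_rep"])


def test_read_geometry_and_index_reads(small_sim):
    bundle = small_sim.reads["haploid_01"]
    assert all(len(r.seq) == C.READ1_LEN for r in bundle.read1)
    assert all(len(r.seq) == C.READ2_RAW_LEN for r in bundle.read2)
    assert all(len(r.seq) == C.INDEX_LEN for r in bundle.index)
    barcode = small_sim.truth.samples.at["haploid_01", "barcode"]
    assert all(r.seq == barcode for r in bundle.index)


def test_error_free_homozygous_locus_reads_are_identical():
    cfg = SimConfig(seed=9, n_loci=3, genome_len=6_000, seq_error_rate=0.0,
                    pcr_error_rate=0.0, dropout_rate=0.0, read2_snp_rate=0.0)
    genome, loci = simulate_genome(cfg)
    truth = simulate_cohort(loci, CohortSpec(design="megagametophyte_panel",
                                             n_het_loci=0), cfg)
    reads = simulate_reads(genome, truth)
    left, right = locus_windows(genome, loci)[loci.index[0]]
    seqs = {r.seq for r in reads["haploid_01"].read1
            if parse_read_id(r.id)["locus_id"] == loci.index[0]}
    assert seqs <= {left, right}


def test_total_read_count_tracks_depth_and_dropout(small_sim):
    truth, cfg = small_sim.truth, small_sim.cfg
    sample = "haploid_02"
    n_amplified = sum((sample, lid) not in truth.dropouts for lid in truth.loci.index)
    expect = n_amplified * cfg.depth_mean
    got = len(small_sim.reads[sample].read1)
    assert abs(got - expect) < 5 * np.sqrt(expect)


def test_every_read_maps_back_to_a_truth_record(small_sim):
    truth = small_sim.truth
    for sample, bundle in small_sim.reads.items():
        for r in bundle.read1[::37]:
            prov = parse_read_id(r.id)
            assert prov["sample_id"] == sample
            assert prov["locus_id"] in truth.loci.index
            assert (sample, prov["locus_id"]) not in truth.dropouts
            if prov["pseudo_allele"]:
                ev = truth.pcr_events
                assert ((ev.sample_id == sample)
                        & (ev.locus_id == prov["locus_id"])).any()


def test_read_simulation_is_deterministic(small_sim):
    again = simulate_reads(small_sim.genome, small_sim.truth)
    a = small_sim.reads["mother_rep1"].read1
    b = again["mother_rep1"].read1
    assert [(r.id, r.seq, r.qual) for r in a] == [(r.id, r.seq, r.qual) for r in b]


def test_truth_matrix_applies_dropouts_as_missing(small_sim):
    gm = truth_to_matrix(small_sim.truth)
    truth = small_sim.truth
    assert set(gm.calls.index) == set(truth.samples.index)
    for (s, lid) in list(truth.dropouts)[:10]:
        for sid in gm.sites.index[gm.sites["locus_id"] == f"{lid}.r1"]:
            assert parse_genotype(gm.calls.at[s, sid]) is None


def test_barcodes_are_distinct_and_well_separated():
    bcs = make_barcodes(24)
    assert len(set(bcs)) == 24
    from migseq._seq import hamming
    assert min(hamming(a, b) for i, a in enumerate(bcs)
               for b in bcs[i + 1:]) >= 2


def test_duplicated_locus_reads_show_both_copies():
    cfg = SimConfig(seed=15, n_loci=4, genome_len=8_000, duplication_rate=1.0,
                    seq_error_rate=0.0, pcr_error_rate=0.0, dropout_rate=0.0,
                    read2_snp_rate=0.0)
    genome, loci = simulate_genome(cfg)
    truth = simulate_cohort(loci, CohortSpec(design="megagametophyte_panel",
                                             n_het_loci=0), cfg)
    reads = simulate_reads(genome, truth)
    lid = loci.index[0]
    row = loci.loc[lid]
    left, _ = locus_windows(genome, loci)[lid]
    bases = {r.seq[int(row.r1_snp_offset)] for r in reads["haploid_01"].read1
             if parse_read_id(r.id)["locus_id"] == lid
             and r.seq[:int(row.r1_snp_offset)] == left[:int(row.r1_snp_offset)]}
    assert {row.r1_ref, row.r1_alt} <= bases
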