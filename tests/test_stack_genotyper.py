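"""Stack building, depth-ratio genotype calls, catalog and marker selection."""
import itertools

import numpy as np
import pandas as pd
import pytest

from migseq._seq import hamming
from migseq.io import write_vcf
from migseq.matrix import GenotypeMatrix, parse_genotype
from migseq.stack_genotyper import (GenotyperConfig, build_catalog,
                                    build_stacks, call_genotype,
                                    genotype_matrix, genotype_samples,
                                    population_filter)

from conftest import rand_dna

CFG = GenotyperConfig()


def _mutate(seq, pos, base):
    return seq[:pos] + base + seq[pos + 1:]


def test_identical_reads_form_one_stack_and_minimum_depth_applies():
    rng = np.random.default_rng(0)
    seq = rand_dna(rng, 80)
    assert len(build_stacks([seq] * 100, "s", CFG)) == 1
    assert build_stacks([seq] * 100, "s", CFG)[0].total_depth == 100
    assert build_stacks([seq] * 19, "s", CFG) == []


def test_two_allele_merge_gives_one_locus_with_site_depths():
    rng = np.random.default_rng(1)
    a = rand_dna(rng, 80)
    b = _mutate(a, 40, "T" if a[40] != "T" else "G")
    loci = build_stacks([a] * 60 + [b] * 50, "s", CFG)
    assert len(loci) == 1
    locus = loci[0]
    assert locus.consensus == a  # depth order
    assert locus.site_depths(40) == {a[40]: 60, b[40]: 50}
    assert locus.n_primary == 2


def test_reads_must_be_80nt():
    with pytest.raises(ValueError):
        build_stacks(["ACGT"], "s", CFG)


def test_overmerged_pileups_are_discarded():
    rng = np.random.default_rng(2)
    a = rand_dna(rng, 80)
    variants = [a] + [_mutate(a, 10 + i, "A" if a[10 + i] != "A" else "C")
                      for i in range(4)]
    reads = list(itertools.chain.from_iterable([v] * 30 for v in variants))
    assert build_stacks(reads, "s", CFG) == []


@pytest.mark.parametrize("depths,expected", [
    ({"A": 100, "T": 4}, ("A", "A")),   # 4/100 < 1/20 -> minor rejected
    ({"A": 100, "T": 10}, ("A", "T")),  # 10/100 >= 1/20 -> heterozygous
    ({"A": 57}, ("A", "A")),
    ({"A": 100, "T": 5}, ("A", "T")),   # boundary: exactly 1/20 calls het
])
def test_depth_ratio_genotype_rule(depths, expected):
    call = call_genotype(depths, CFG, ploidy=2)
    assert call.alleles == expected


def test_haploid_mode_reports_major_allele_with_flag():
    call = call_genotype({"A": 60, "T": 50}, CFG, ploidy=1)
    assert call.alleles == ("A",) and call.het_flag
    clean = call_genotype({"A": 60, "T": 2}, CFG, ploidy=1)
    assert clean.alleles == ("A",) and not clean.het_flag
    assert call_genotype({}, CFG) is None


def test_catalog_groups_samples_and_separates_distant_loci():
    rng = np.random.default_rng(3)
    a = rand_dna(rng, 80)
    far = a
    for pos in range(0, 50, 5):  # 10 substitutions
        far = _mutate(far, pos, "A" if far[pos] != "A" else "C")
    sample_loci = []
    for i in range(10):
        sample_loci += build_stacks([a] * 40 + [far] * 40, f"s{i}", CFG)
    catalog = build_catalog(sample_loci, CFG)
    assert len(catalog) == 2
    assert all(len(c.members) == 10 for c in catalog)


def test_catalog_merges_within_n_mismatches_against_naive_oracle():
    rng = np.random.default_rng(4)
    base = rand_dna(rng, 80)
    seqs = {"s1": base, "s2": _mutate(_mutate(_mutate(base, 5, "A" if base[5] != "A" else "C"),
                                              15, "A" if base[15] != "A" else "C"),
                                      25, "A" if base[25] != "A" else "C")}
    assert hamming(seqs["s1"], seqs["s2"]) == 3
    sample_loci = [build_stacks([s] * 30, name, CFG)[0]
                   for name, s in seqs.items()]
    catalog = build_catalog(sample_loci, CFG)
    assert len(catalog) == 1  # 3 <= n = 4
    # naive all-pairs check agrees
    assert hamming(seqs["s1"], seqs["s2"]) <= CFG.n


def test_population_filter_thresholds_and_single_snp():
    samples = [f"a{i}" for i in range(8)] + [f"b{i}" for i in range(8)]
    pops = {s: s[0] for s in samples}
    sites = ["L1:5", "L2:7", "L3:2", "L3:9", "L3:40"]
    calls = pd.DataFrame(index=samples, columns=sites, dtype=object)
    # L1 genotyped in 4/8 of population a only
    for s in samples[:4]:
        calls.at[s, "L1:5"] = "A/T"
    # L2 genotyped in 3/8 of each population
    for s in samples[:3] + samples[8:11]:
        calls.at[s, "L2:7"] = "A/T"
    # L3 genotyped everywhere with 3 SNPs
    for s in samples:
        for sid in sites[2:]:
            calls.at[s, sid] = "C/G"
    gm = GenotypeMatrix(calls=calls)
    kept = population_filter(gm, pops, GenotyperConfig(r=0.5, p=1),
                             drop_monomorphic=False)
    assert "L1:5" in kept.site_ids       # 4/8 = 0.5 in one population
    assert "L2:7" not in kept.site_ids   # 0.375 < 0.5 everywhere
    assert kept.sites_of_locus("L3") == ["L3:2"]  # first SNP only
    strict = population_filter(gm, pops, GenotyperConfig(r=0.5, p=2),
                               drop_monomorphic=False)
    assert "L1:5" not in strict.site_ids
    with pytest.raises(KeyError):
        population_filter(gm, {"a0": "a"}, CFG)


def test_singleton_error_reads_never_change_the_genotype():
    rng = np.random.default_rng(5)
    a = rand_dna(rng, 80)
    err = _mutate(a, 63, "A" if a[63] != "A" else "C")
    loci = build_stacks([a] * 100 + [err], "s", CFG)
    assert len(loci) == 1
    call = call_genotype(loci[0].site_depths(63), CFG, ploidy=2)
    assert call.alleles == (a[63], a[63])


def test_raising_m_or_r_never_increases_retained_loci(small_sim, small_gm):
    pops = {s: small_sim.truth.samples.at[s, "group"]
            for s in small_gm.samples}
    base = population_filter(small_gm, pops, GenotyperConfig(r=0.5, p=1))
    strict = population_filter(small_gm, pops, GenotyperConfig(r=0.75, p=1))
    assert set(strict.loci()) <= set(base.loci())


def test_matrix_tsv_roundtrip_and_vcf_export(tmp_path, small_gm):
    path = tmp_path / "m.tsv"
    small_gm.to_tsv(path)
    back = GenotypeMatrix.from_tsv(path)
    assert back.calls.shape == small_gm.calls.shape
    for s in small_gm.samples[:4]:
        for sid in small_gm.site_ids[:5]:
            assert parse_genotype(back.calls.at[s, sid]) == \
                parse_genotype(small_gm.calls.at[s, sid])
    vcf = tmp_path / "m.vcf"
    write_vcf(small_gm, vcf)
    lines = [l for l in vcf.read_text().splitlines() if not l.startswith("#")]
    assert len(lines) == len(small_gm.site_ids)
    assert all(len(l.split("\t")) == 9 + len(small_gm.samples) for l in lines)


def test_error_free_pipeline_recovers_truth_exactly():
    from migseq.library_sim import (CohortSpec, SimConfig, locus_windows,
                                    match_catalog_to_truth, simulate_cohort,
                                    simulate_genome, simulate_reads)
    cfg = SimConfig(seed=31, n_loci=12, genome_len=20_000, seq_error_rate=0.0,
                    pcr_error_rate=0.0, dropout_rate=0.0)
    genome, loci = simulate_genome(cfg)
    truth = simulate_cohort(loci, CohortSpec(design="megagametophyte_panel",
                                             n_het_loci=6), cfg)
    reads = simulate_reads(genome, truth)
    by_sample = {s: [r.seq for r in b.read1]
                 + [r.seq[14:] for r in b.read2] for s, b in reads.items()}
    ploidy = {s: int(p) for s, p in truth.samples["ploidy"].items()}
    gm = genotype_samples(by_sample, CFG, ploidy_map=ploidy,
                          apply_population_filter=False)
    mapping = match_catalog_to_truth(gm.consensus, genome, loci)
    windows = locus_windows(genome, loci)
    assert len(gm.consensus) == 2 * len(loci)
    for sid in gm.site_ids:
        cl = gm.sites.loc[sid, "locus_id"]
        pos = int(gm.sites.loc[sid, "pos"])
        planted, end = mapping[cl].rsplit(".", 1)
        row = loci.loc[planted]
        off = int(row.r1_snp_offset) if end == "r1" else int(row.r2_snp_offset)
        window = windows[planted][0 if end == "r1" else 1]
        for s in gm.samples:
            call = parse_genotype(gm.calls.at[s, sid])
            assert call is not None  # no dropout, depth ~100 >> m
            if pos == off:
                expected = tuple(sorted(str(truth.genotype(s, planted, end)).split("/")))
            else:
                expected = (window[pos],) * int(truth.samples.at[s, "ploidy"])
            assert call == expected
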