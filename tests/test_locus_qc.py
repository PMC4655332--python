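"""Artifact filters: singletons, replicates, homology, duplication, paired ends."""
import numpy as np
import pandas as pd
import pytest

from migseq.locus_qc import (DUP_HETERO_HETERO, DUP_HOMO_HETERO, DUP_HOMO_HOMO,
                             DUP_LINKAGE, DUP_NORMAL, classify_duplicated_loci,
                             detect_paired_end_loci, hwe_test,
                             remove_singleton_variant_loci,
                             replicate_concordance_filter, run_qc,
                             shifted_homology_filter, shifted_identity)
from migseq.matrix import GenotypeMatrix

from conftest import rand_dna


def make_gm(columns, samples, het=None, depths=None, consensus=None, ploidy=None):
    calls = pd.DataFrame(index=samples, columns=list(columns), dtype=object)
    for sid, per_sample in columns.items():
        for s, g in per_sample.items():
            calls.at[s, sid] = g
    gm = GenotypeMatrix(calls=calls, consensus=consensus or {},
                        ploidy=pd.Series(ploidy or 2, index=samples))
    if het:
        for sid, per_sample in het.items():
            for s, f in per_sample.items():
                gm.het_flags.at[s, sid] = f
    if depths:
        gm.depths = pd.DataFrame(index=samples, columns=list(columns), dtype=object)
        for sid, per_sample in depths.items():
            for s, d in per_sample.items():
                gm.depths.at[s, sid] = d
    return gm


# ---------------------------------------------------------------------------
# singleton filter
# ---------------------------------------------------------------------------

def test_singleton_minor_allele_locus_is_removed():
    samples = [f"s{i}" for i in range(18)]
    cols = {
        "L1:4": {s: ("A/T" if s == "s0" else "A/A") for s in samples},  # singleton
        "L2:9": {s: ("A/T" if s in ("s0", "s1") else "A/A") for s in samples},
        "L3:2": {s: "C/C" for s in samples},  # monomorphic: untouched
    }
    gm = make_gm(cols, samples)
    out, report = remove_singleton_variant_loci(gm)
    assert report.loc["L1", "status"] == "removed_singleton"
    assert report.loc["L2", "status"] == "kept"
    assert report.loc["L3", "status"] == "kept"
    assert set(out.loci()) == {"L2", "L3"}


def test_singleton_filter_needs_two_samples():
    gm = make_gm({"L1:0": {"s0": "A/T"}}, ["s0"])
    with pytest.raises(ValueError):
        remove_singleton_variant_loci(gm)


# ---------------------------------------------------------------------------
# replicate filter
# ---------------------------------------------------------------------------

def test_replicate_discordance_removes_locus_with_depth_chisquare():
    samples = ["rep1", "rep2", "x1", "x2"]
    cols = {"L1:3": {"rep1": "A/T", "rep2": "A/T", "x1": "A/A", "x2": "A/T"},
            "L2:5": {"rep1": "A/A", "rep2": "A/T", "x1": "A/A", "x2": "A/T"}}
    depths = {"L2:5": {"rep2": {"A": 90, "T": 10}}}
    gm = make_gm(cols, samples, depths=depths)
    out, report = replicate_concordance_filter(gm, [("rep1", "rep2")])
    assert report.loc["L1", "status"] == "kept"
    assert report.loc["L2", "status"] == "removed_replicate_discordant"
    assert "chi2=64" in report.loc["L2", "evidence"]
    assert "biased=True" in report.loc["L2", "evidence"]
    assert set(out.loci()) == {"L1"}
    with pytest.raises(KeyError):
        replicate_concordance_filter(gm, [("rep1", "missing")])


# ---------------------------------------------------------------------------
# shifted-homology filter
# ---------------------------------------------------------------------------

def naive_shifted_identity(a, b, max_shift=16):
    best = 0.0
    for s in range(-(max_shift - 1), max_shift):
        matches = sum(1 for i in range(80)
                      if 0 <= i + s < 80 and a[i + s] == b[i])
        best = max(best, matches / 80)
    return best


def test_shifted_identity_agrees_with_naive_oracle():
    rng = np.random.default_rng(0)
    g = rand_dna(rng, 200)
    pairs = [(g[:80], g[10:90]), (g[:80], g[100:180]), (g[5:85], g[20:100])]
    for a, b in pairs:
        ident, _ = shifted_identity(a, b)
        assert ident == pytest.approx(naive_shifted_identity(a, b))


def test_homology_filter_removes_shifted_copies_and_keeps_unrelated():
    rng = np.random.default_rng(1)
    g = rand_dna(rng, 200)
    consensus = {
        "L1": g[:80],
        "L2": g[:80],            # identical, shift 0
        "L3": g[10:90],          # shifted by 10: identity >= 70/80
        "L4": g[15:95],          # shifted by 15: identity 65/80 = 0.8125
        "L5": rand_dna(rng, 80),  # unrelated (expected identity ~0.25)
    }
    samples = ["a", "b"]
    cols = {f"{l}:0": {"a": "A/A", "b": "A/T"} for l in consensus}
    gm = make_gm(cols, samples, consensus=consensus)
    out, report, hits = shifted_homology_filter(gm)
    assert set(out.loci()) == {"L5"}
    assert all(report.loc[l, "status"] == "removed_homology_group"
               for l in ("L1", "L2", "L3", "L4"))
    idents = {frozenset((h.locus_a, h.locus_b)): h.identity for h in hits}
    assert idents[frozenset(("L1", "L2"))] == 1.0
    assert idents[frozenset(("L1", "L4"))] == pytest.approx(65 / 80)


def test_homology_filter_keep_one_mode():
    rng = np.random.default_rng(2)
    seq = rand_dna(rng, 80)
    gm = make_gm({f"L{i}:0": {"a": "A/A", "b": "A/T"} for i in (1, 2)},
                 ["a", "b"], consensus={"L1": seq, "L2": seq})
    out, _, _ = shifted_homology_filter(gm, keep_one=True)
    assert out.loci() == ["L1"]


# ---------------------------------------------------------------------------
# duplicated-locus classification
# ---------------------------------------------------------------------------

def _haploid_gm(flag_pattern, alleles=None):
    haploids = [f"h{i:02d}" for i in range(16)]
    alleles = alleles or {s: "A" for s in haploids}
    cols = {"L1:0": {s: alleles[s] for s in haploids}}
    het = {"L1:0": {s: f for s, f in zip(haploids, flag_pattern)}}
    return make_gm(cols, haploids, het=het, ploidy=1), haploids


@pytest.mark.parametrize("n_flagged,expected", [
    (16, DUP_HOMO_HOMO),   # 'heterozygote' in every haploid
    (9, DUP_HOMO_HETERO),  # 9:7 compatible with 1:1
    (2, DUP_LINKAGE),      # 1-3-sample minority class
    (0, DUP_NORMAL),
])
def test_duplication_signatures(n_flagged, expected):
    gm, haploids = _haploid_gm([True] * n_flagged + [False] * (16 - n_flagged))
    types = classify_duplicated_loci(gm, haploids)
    assert types["L1"] == expected


def test_hetero_hetero_requires_two_homozygote_classes():
    flags = [True] * 8 + [False] * 8
    alleles = {f"h{i:02d}": ("A" if i < 12 else "T") for i in range(16)}
    gm, haploids = _haploid_gm(flags, alleles)
    assert classify_duplicated_loci(gm, haploids)["L1"] == DUP_HETERO_HETERO


def test_classification_refused_with_too_few_haploids():
    gm, haploids = _haploid_gm([False] * 16)
    with pytest.raises(ValueError):
        classify_duplicated_loci(gm, haploids[:5])


# ---------------------------------------------------------------------------
# paired-end loci
# ---------------------------------------------------------------------------

def test_paired_end_loci_are_detected_and_one_survives():
    haploids = [f"h{i:02d}" for i in range(16)]
    rng = np.random.default_rng(3)
    gametes = rng.integers(0, 2, 16)
    other = rng.integers(0, 2, 16)
    cols = {
        "L1:4": {s: ("A" if g else "T") for s, g in zip(haploids, gametes)},
        "L2:9": {s: ("C" if g else "G") for s, g in zip(haploids, gametes)},
        "L3:1": {s: ("A" if g else "C") for s, g in zip(haploids, other)},
    }
    gm = make_gm(cols, haploids, ploidy=1)
    out, report, pairs = detect_paired_end_loci(gm)
    assert pairs == [("L1", "L2")]
    assert set(out.loci()) == {"L1", "L3"}
    assert report.loc["L2", "status"] == "removed_paired_end"
    # independently segregating loci (50% concordance) are not paired
    assert ("L1", "L3") not in pairs and ("L2", "L3") not in pairs


# ---------------------------------------------------------------------------
# pipeline conservation / idempotence
# ---------------------------------------------------------------------------

def test_run_qc_accounts_for_every_locus_and_is_idempotent():
    samples = ["rep1", "rep2"] + [f"h{i:02d}" for i in range(16)]
    rng = np.random.default_rng(4)
    gametes = rng.integers(0, 2, 16)
    cols, consensus = {}, {}
    for i in range(6):
        sid = f"L{i}:3"
        cols[sid] = {"rep1": "A/T", "rep2": "A/T"}
        for s, g in zip(samples[2:], gametes):
            cols[sid][s] = "A" if (g + i) % 2 else "T"
        consensus[f"L{i}"] = rand_dna(rng, 80)
    cols["L5:3"]["rep2"] = "A/A"  # replicate-discordant locus
    cols["L4:3"] = {s: ("A/T" if s == "rep1" else "A/A") for s in samples}
    gm = make_gm(cols, samples, consensus=consensus,
                 ploidy={s: (1 if s.startswith("h") else 2) for s in samples})
    out, report = run_qc(gm, replicate_pairs=[("rep1", "rep2")],
                         haploid_ids=samples[2:])
    assert sorted(report.index) == sorted(gm.loci())
    assert (report["status"] == "kept").sum() == len(out.loci())
    out2, report2 = run_qc(out, replicate_pairs=[("rep1", "rep2")],
                           haploid_ids=samples[2:])
    assert out2.loci() == out.loci()
    assert (report2["status"] == "kept").all()


def test_hwe_flag_detects_excess_heterozygosity():
    samples = [f"s{i}" for i in range(40)]
    cols = {"L1:0": {s: "A/T" for s in samples},  # all het: HWE violated
            "L2:0": {s: ("A/A" if i < 20 else ("A/T" if i < 30 else "T/T"))
                     for i, s in enumerate(samples)}}
    gm = make_gm(cols, samples)
    p = hwe_test(gm)
    assert p["L1:0"] < 0.001
    assert p["L2:0"] > 0.001
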