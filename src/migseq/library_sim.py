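"""Synthetic data generator: genomes with plantable ISSR loci, cohorts, reads.

This module builds the in-silico study material: a random genome carrying a
known number of amplifiable inter-SSR loci, cohort designs mirroring the
validation analyses (a haploid megagametophyte panel segregating 1:1 from a
heterozygous mother, clonal ramet groups, two differentiated populations,
replicate pairs), and indexed paired-end reads with the artifact classes the
QC layer is built to catch: per-base sequencing errors, per-sample PCR
pseudo-alleles with biased depth fractions, and per-sample-per-locus
amplification dropout.

Every random draw descends from ``SimConfig.seed`` through fixed integer
stream keys, so identical configurations reproduce byte-identical output.

Read geometry follows the sequencing layout: read 1 is 80 nt of genomic
sequence immediately interior to the forward-side primer (the primer itself
is skipped by DarkCycle), read 2 is 94 nt = the 14-nt primer annealing region
plus 80 nt of genomic sequence, and the index read is the 6-nt sample
barcode.  Each fragment is amplified in forward-reverse or reverse-forward
orientation with equal probability, so a given locus end appears in both the
read-1 and read-2 pools.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import constants as C
from ._seq import DNA, hamming, revcomp
from .insilico_pcr import find_annealing_sites
from .io import FastqRead, write_fastq
from .matrix import GenotypeMatrix, format_genotype
from .primer_design import PrimerSet, published_set1

_READ_LEN = C.READ1_LEN


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Simulation knobs; all rates are probabilities in [0, 1].

    ``insert_len_range`` is the final library-size window (genomic span plus
    34 bases of tails), matching the 300-800 bp size selection.  ``depth_mean``
    is the mean fragment count per locus per sample.  ``pcr_error_rate`` is the
    per-locus-per-sample probability that a PCR pseudo-allele arises, carried
    by a Beta-distributed fraction of that sample-locus's fragments, so biased
    depth ratios (the PCR-error signature) occur.  ``dropout_rate`` is the
    per-sample-per-locus probability of amplification failure, producing the
    locus-detection heterogeneity seen in real panels.
    """

    seed: int
    n_loci: int = 200
    genome_len: int = 200_000
    insert_len_range: tuple = (C.SIZE_SELECT_MIN, C.SIZE_SELECT_MAX)
    depth_mean: float = 100.0
    seq_error_rate: float = 0.001
    pcr_error_rate: float = 0.01
    pcr_error_depth_beta: tuple = (2.0, 2.0)
    maf_range: tuple = (0.1, 0.5)
    duplication_rate: float = 0.0
    dropout_rate: float = 0.15
    read2_snp_rate: float = 0.1
    shifted_site_rate: float = 0.0
    min_locus_gap: int = 250
    base_quality: int = 37
    low_quality_read_frac: float = 0.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory; no unseeded randomness")
        for name in ("seq_error_rate", "pcr_error_rate", "dropout_rate",
                     "duplication_rate", "read2_snp_rate", "shifted_site_rate",
                     "low_quality_read_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def rng(self, *key) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), *map(int, key)])


@dataclass
class CohortSpec:
    """Cohort design: which samples exist and how genotypes are drawn.

    design is one of ``population_pair`` (n_per_group diploids in each of two
    populations with Balding-Nichols-style frequency differentiation
    ``fst_like``), ``megagametophyte_panel`` (``n_haploids`` haploid seeds plus
    ``n_mother_replicates`` replicate samples of the diploid mother,
    heterozygous at ``n_het_loci`` loci segregating 1:1), ``clonal_ramets``
    (``n_genets`` genets x ``ramets_per_genet`` ramets, each ramet carrying
    ``somatic_diff_count`` somatic single-locus changes, genets separated by
    at least ``min_inter_diff`` genotype differences), or ``replicate_pair``
    (independent diploids plus an exact replicate of the first).
    """

    design: str
    n_per_group: int = 4
    fst_like: float = 0.2
    n_haploids: int = 16
    n_mother_replicates: int = 2
    n_het_loci: Optional[int] = None
    n_genets: int = 3
    ramets_per_genet: int = 6
    somatic_diff_count: int = 2
    min_inter_diff: int = 27

    _DESIGNS = ("population_pair", "megagametophyte_panel", "clonal_ramets",
                "replicate_pair")

    def __post_init__(self):
        if self.design not in self._DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; one of {self._DESIGNS}")


@dataclass
class TruthTable:
    """Ground truth sufficient to score every downstream filter decision.

    samples     sample_id, ploidy, group, genet, barcode.
    loci        planted locus coordinates, primers, SNP definitions.
    sites       per segregating-site metadata (locus, end r1/r2, offset,
                ref/alt allele in read orientation).
    genotypes   samples x truth-site ids; phased strings ("ref/alt" order is
                the haplotype order used by the read simulator).
    dropouts    (sample, locus) pairs that failed to amplify.
    pcr_events  planted pseudo-allele events with window, offset, substituted
                base and fragment depth fraction.
    """

    samples: pd.DataFrame
    loci: pd.DataFrame
    sites: pd.DataFrame
    genotypes: pd.DataFrame
    dropouts: set
    pcr_events: pd.DataFrame
    config: SimConfig
    spec: CohortSpec

    def site_id(self, locus_id: str, end: str) -> str:
        return f"{locus_id}.{end}"

    def genotype(self, sample: str, locus_id: str, end: str = "r1"):
        sid = self.site_id(locus_id, end)
        if sid not in self.genotypes.columns:
            return None
        return self.genotypes.at[sample, sid]


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def _random_bases(rng, n) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


def _to_str(arr: np.ndarray) -> str:
    return "".join(DNA[b] for b in arr)


def simulate_genome(config: SimConfig, primers: Optional[PrimerSet] = None,
                    contig: str = "chr1"):
    """Random genome with ``n_loci`` planted convergent primer-site pairs.

    Returns (genome dict, loci DataFrame).  Loci are packed left to right with
    seeded random gaps of at least ``min_locus_gap`` bases — large enough that
    no cross-locus convergent pair falls inside the size-selection window —
    and the background is scrubbed of accidental annealing sites, so a strict
    scan recovers exactly the planted amplicons.  Each locus carries one
    segregating-site definition in its read-1 window and, for a
    ``read2_snp_rate`` fraction of loci, a second one in its read-2 window.
    With ``shifted_site_rate`` > 0 a fraction of loci get a planted companion
    whose read window is a near-identical shifted copy (pseudo-locus from
    shifted priming) for exercising the homology filter.
    """
    if primers is None:
        primers = published_set1()
    queries = [(pair[0].candidate.base_name, pair[0].annealing_seq)
               for pair in primers.members]
    rng = config.rng(0)

    lo, hi = config.insert_len_range
    lib_lens = rng.integers(lo, hi + 1, size=config.n_loci)
    spans = lib_lens - 2 * C.TAIL_BASES_PER_END
    total = int(spans.sum()) + (config.n_loci + 1) * config.min_locus_gap
    if total > config.genome_len:
        raise ValueError(
            f"genome_len {config.genome_len} too small for {config.n_loci} loci "
            f"(needs >= {total})")
    extra = config.genome_len - total
    gaps = rng.multinomial(extra, [1.0 / (config.n_loci + 1)] * (config.n_loci + 1))
    gaps = gaps + config.min_locus_gap

    genome = _random_bases(rng, config.genome_len)
    enc = {b: i for i, b in enumerate(DNA)}

    is_shifted = rng.random(config.n_loci) < config.shifted_site_rate
    rows = []
    pos = 0
    for i in range(config.n_loci):
        pos += int(gaps[i])
        fwd_name, fwd_seq = queries[rng.integers(len(queries))]
        rev_name, rev_seq = queries[rng.integers(len(queries))]
        span = int(spans[i])
        fwd_start, fwd_end = pos, pos + C.ANNEALING_LEN
        rev_end = pos + span
        rev_start = rev_end - C.ANNEALING_LEN
        genome[fwd_start:fwd_end] = [enc[b] for b in fwd_seq]
        genome[rev_start:rev_end] = [enc[b] for b in revcomp(rev_seq)]
        shift = int(rng.integers(1, 16)) if is_shifted[i] else 0
        rows.append(dict(
            locus_id=f"P{i:04d}", contig=contig,
            fwd_start=fwd_start, fwd_end=fwd_end,
            rev_start=rev_start, rev_end=rev_end,
            insert_start=fwd_end, insert_end=rev_start,
            library_len=int(lib_lens[i]),
            fwd_primer=fwd_name, rev_primer=rev_name,
            fwd_annealing=fwd_seq, rev_annealing=rev_seq,
            shift_of=None, shift=shift,
        ))
        if shift:
            # companion pseudo-locus: its read-1 window is the previous locus's
            # window advanced by `shift` bases (shifted-priming artifact)
            src = rows[-1]
            window = genome[src["insert_start"] + shift:
                            src["insert_start"] + shift + _READ_LEN + 16].copy()
            pos = rev_end
            pos += int(config.min_locus_gap)
            span2 = int(rng.integers(lo, hi + 1)) - 2 * C.TAIL_BASES_PER_END
            f2s, f2e = pos, pos + C.ANNEALING_LEN
            r2e = pos + span2
            r2s = r2e - C.ANNEALING_LEN
            if r2e + config.min_locus_gap > config.genome_len:
                raise ValueError("genome_len too small for shifted companions")
            genome[f2s:f2e] = [enc[b] for b in fwd_seq]
            genome[r2s:r2e] = [enc[b] for b in revcomp(rev_seq)]
            genome[f2e:f2e + len(window)] = window
            rows.append(dict(
                locus_id=f"P{i:04d}s", contig=contig,
                fwd_start=f2s, fwd_end=f2e, rev_start=r2s, rev_end=r2e,
                insert_start=f2e, insert_end=r2s,
                library_len=span2 + 2 * C.TAIL_BASES_PER_END,
                fwd_primer=fwd_name, rev_primer=rev_name,
                fwd_annealing=fwd_seq, rev_annealing=rev_seq,
                shift_of=src["locus_id"], shift=shift,
            ))
            pos = r2e
        else:
            pos = rev_end

    columns = ["locus_id", "contig", "fwd_start", "fwd_end", "rev_start",
               "rev_end", "insert_start", "insert_end", "library_len",
               "fwd_primer", "rev_primer", "fwd_annealing", "rev_annealing",
               "shift_of", "shift"]
    loci = pd.DataFrame(rows, columns=columns).set_index("locus_id", drop=False)
    genome_str = _to_str(genome)

    # scrub accidental annealing sites so planted loci are the only amplicons
    planted = {(int(r.fwd_start), "+") for r in loci.itertuples()}
    planted |= {(int(r.rev_start), "-") for r in loci.itertuples()}
    footprints = []
    for r in loci.itertuples():
        footprints.append((int(r.fwd_start), int(r.fwd_end)))
        footprints.append((int(r.rev_start), int(r.rev_end)))
    for _ in range(20):
        extra_sites = [s for s in find_annealing_sites({contig: genome_str}, primers)
                       if (s.start, s.strand) not in planted]
        if not extra_sites:
            break
        chars = list(genome_str)
        for s in extra_sites:
            for p in range(s.start, s.end):
                if not any(a <= p < b for a, b in footprints):
                    chars[p] = DNA[(DNA.index(chars[p]) + 1) % 4]
                    break
        genome_str = "".join(chars)
    else:  # pragma: no cover - 20 passes always suffice in practice
        raise RuntimeError("failed to scrub accidental annealing sites")

    # assign segregating-site definitions from the final sequence
    rng_snp = config.rng(1)
    r1_off = rng_snp.integers(0, _READ_LEN, size=len(loci))
    has_r2 = rng_snp.random(len(loci)) < config.read2_snp_rate
    r2_off = rng_snp.integers(0, _READ_LEN, size=len(loci))
    r1_ref, r1_alt, r2_ref, r2_alt = [], [], [], []
    for j, r in enumerate(loci.itertuples()):
        ref = genome_str[r.insert_start + int(r1_off[j])]
        alt = DNA[(DNA.index(ref) + 1 + int(rng_snp.integers(3))) % 4]
        r1_ref.append(ref)
        r1_alt.append(alt)
        if has_r2[j]:
            # read-2 window is bottom strand: allele recorded in read space
            base = revcomp(genome_str[r.insert_end - 1 - int(r2_off[j])])
            alt2 = DNA[(DNA.index(base) + 1 + int(rng_snp.integers(3))) % 4]
            r2_ref.append(base)
            r2_alt.append(alt2)
        else:
            r2_ref.append(None)
            r2_alt.append(None)
    loci["r1_snp_offset"] = r1_off
    loci["r1_ref"] = r1_ref
    loci["r1_alt"] = r1_alt
    loci["r2_snp_offset"] = np.where(has_r2, r2_off, -1)
    loci["r2_ref"] = r2_ref
    loci["r2_alt"] = r2_alt
    # two-copy loci: a second, unlinked genomic copy fixed for the alternate
    # base co-assembles with the first (duplicated-locus artifact); modelled at
    # read level, so the planted amplicon count stays n_loci
    loci["dup_locus"] = rng_snp.random(len(loci)) < config.duplication_rate
    return {contig: genome_str}, loci


def locus_windows(genome: dict, loci: pd.DataFrame) -> dict:
    """Reference read windows per locus: {locus_id: (read1_window, read2_window)}.

    read1 is the top-strand 80-mer after the forward footprint; read2 is the
    bottom-strand 80-mer after the reverse footprint (as sequenced).
    """
    out = {}
    for r in loci.itertuples():
        seq = genome[r.contig]
        left = seq[r.insert_start: r.insert_start + _READ_LEN]
        right = revcomp(seq[r.insert_end - _READ_LEN: r.insert_end])
        out[r.locus_id] = (left, right)
    return out


def write_planted_bed(loci: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for r in loci.itertuples():
            fh.write(f"{r.contig}\t{r.insert_start}\t{r.insert_end}\t{r.locus_id}\t"
                     f"{r.library_len}\t+\n")


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def make_barcodes(n: int, length: int = C.INDEX_LEN, min_dist: int = 2) -> list:
    """Deterministic list of n mutually distinct barcodes (pairwise Hamming
    distance >= min_dist); barcode design itself is an external concern, this
    is fixture plumbing."""
    out = []
    for combo in itertools.product(DNA, repeat=length):
        bc = "".join(combo)
        if all(hamming(bc, other) >= min_dist for other in out):
            out.append(bc)
            if len(out) == n:
                return out
    raise ValueError(f"cannot build {n} barcodes of length {length}")


def _sample_table(spec: CohortSpec) -> pd.DataFrame:
    rows = []
    if spec.design == "megagametophyte_panel":
        for i in range(spec.n_mother_replicates):
            rows.append(("mother_rep%d" % (i + 1), 2, "mother", None))
        for i in range(spec.n_haploids):
            rows.append(("haploid_%02d" % (i + 1), 1, "offspring", None))
    elif spec.design == "population_pair":
        for p in (1, 2):
            for i in range(spec.n_per_group):
                rows.append(("pop%d_s%02d" % (p, i + 1), 2, "pop%d" % p, None))
    elif spec.design == "clonal_ramets":
        for g in range(spec.n_genets):
            for i in range(spec.ramets_per_genet):
                rows.append(("genet%d_ramet%d" % (g + 1, i + 1), 2,
                             "ramets", "genet%d" % (g + 1)))
    elif spec.design == "replicate_pair":
        for i in range(spec.n_per_group):
            rows.append(("sample_%02d" % (i + 1), 2, "cohort", None))
        rows.append(("sample_01_rep", 2, "cohort", None))
    df = pd.DataFrame(rows, columns=["sample_id", "ploidy", "group", "genet"])
    df["barcode"] = make_barcodes(len(df))
    return df.set_index("sample_id", drop=False)


def _truth_sites(loci: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for r in loci.itertuples():
        rows.append((f"{r.locus_id}.r1", r.locus_id, "r1",
                     int(r.r1_snp_offset), r.r1_ref, r.r1_alt))
        if r.r2_snp_offset >= 0:
            rows.append((f"{r.locus_id}.r2", r.locus_id, "r2",
                         int(r.r2_snp_offset), r.r2_ref, r.r2_alt))
    return pd.DataFrame(rows, columns=["site_id", "locus_id", "end", "offset",
                                       "ref", "alt"]).set_index("site_id", drop=False)


def simulate_cohort(loci: pd.DataFrame, spec: CohortSpec,
                    config: SimConfig) -> TruthTable:
    """Draw true genotypes, dropouts and PCR-error events for a cohort."""
    samples = _sample_table(spec)
    sites = _truth_sites(loci)
    rng = config.rng(2)
    geno = pd.DataFrame(index=samples.index, columns=sites.index, dtype=object)

    if spec.design == "megagametophyte_panel":
        n_het = spec.n_het_loci
        if n_het is None:
            n_het = int(round(0.37 * len(loci)))
        het_loci = set(rng.choice(loci.index.to_numpy(), size=min(n_het, len(loci)),
                                  replace=False))
        mothers = [s for s in samples.index if samples.at[s, "group"] == "mother"]
        haploids = [s for s in samples.index if samples.at[s, "ploidy"] == 1]
        gamete_by_locus = {}
        for sid, srow in sites.iterrows():
            het = srow.locus_id in het_loci
            if het and srow.locus_id not in gamete_by_locus:
                gamete_by_locus[srow.locus_id] = rng.integers(0, 2, size=len(haploids))
            gametes = gamete_by_locus.get(srow.locus_id)
            for m in mothers:
                geno.at[m, sid] = f"{srow.ref}/{srow.alt}" if het else f"{srow.ref}/{srow.ref}"
            if het:
                # r2 sites are completely linked to r1 (same gamete draw)
                for h, g in zip(haploids, gametes):
                    geno.at[h, sid] = srow.alt if g else srow.ref
            else:
                for h in haploids:
                    geno.at[h, sid] = srow.ref

    elif spec.design == "population_pair":
        groups = {g: [s for s in samples.index if samples.at[s, "group"] == g]
                  for g in ("pop1", "pop2")}
        F = spec.fst_like
        for sid, srow in sites.iterrows():
            if srow.end != "r1":
                for s in samples.index:
                    geno.at[s, sid] = f"{srow.ref}/{srow.ref}"
                continue
            p = rng.uniform(*config.maf_range)
            for g, members in groups.items():
                if F > 0:
                    pk = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
                else:
                    pk = p
                for s in members:
                    alleles = [srow.alt if rng.random() < pk else srow.ref
                               for _ in range(2)]
                    geno.at[s, sid] = "/".join(alleles)

    elif spec.design == "clonal_ramets":
        r1_sites = sites.index[sites["end"] == "r1"]
        for attempt in range(200):
            genet_geno = {}
            for g in range(spec.n_genets):
                gg = {}
                for sid in r1_sites:
                    srow = sites.loc[sid]
                    p = rng.uniform(*config.maf_range)
                    alleles = sorted(srow.alt if rng.random() < p else srow.ref
                                     for _ in range(2))
                    gg[sid] = "/".join(alleles)
                genet_geno["genet%d" % (g + 1)] = gg
            names = sorted(genet_geno)
            ok = all(
                sum(genet_geno[a][sid] != genet_geno[b][sid] for sid in r1_sites)
                >= spec.min_inter_diff
                for a, b in itertools.combinations(names, 2))
            if ok:
                break
        else:
            raise RuntimeError("could not plant genets with the requested separation")
        for s in samples.index:
            genet = samples.at[s, "genet"]
            for sid in sites.index:
                srow = sites.loc[sid]
                if srow.end == "r1":
                    geno.at[s, sid] = genet_geno[genet][sid]
                else:
                    geno.at[s, sid] = f"{srow.ref}/{srow.ref}"
            flip = rng.choice(np.asarray(r1_sites), size=spec.somatic_diff_count,
                              replace=False)
            for sid in flip:
                srow = sites.loc[sid]
                options = [f"{srow.ref}/{srow.ref}",
                           "/".join(sorted((srow.ref, srow.alt))),
                           f"{srow.alt}/{srow.alt}"]
                current = geno.at[s, sid]
                others = [o for o in options if o != current]
                geno.at[s, sid] = others[int(rng.integers(len(others)))]

    elif spec.design == "replicate_pair":
        base = [s for s in samples.index if not s.endswith("_rep")]
        for sid, srow in sites.iterrows():
            if srow.end != "r1":
                for s in samples.index:
                    geno.at[s, sid] = f"{srow.ref}/{srow.ref}"
                continue
            p = rng.uniform(*config.maf_range)
            for s in base:
                alleles = [srow.alt if rng.random() < p else srow.ref for _ in range(2)]
                geno.at[s, sid] = "/".join(alleles)
        for sid in sites.index:
            geno.at["sample_01_rep", sid] = geno.at["sample_01", sid]

    # amplification dropout and PCR pseudo-allele events
    rng_d = config.rng(3)
    dropouts = set()
    events = []
    windows_per_locus = {lid: ("r1", "r2") for lid in loci.index}
    for s in samples.index:
        for lid in loci.index:
            if rng_d.random() < config.dropout_rate:
                dropouts.add((s, lid))
                continue
            if rng_d.random() < config.pcr_error_rate:
                end = windows_per_locus[lid][int(rng_d.integers(2))]
                offset = int(rng_d.integers(_READ_LEN))
                frac = float(rng_d.beta(*config.pcr_error_depth_beta))
                events.append(dict(sample_id=s, locus_id=lid, end=end,
                                   offset=offset, to_base=None, frac=frac))
    pcr_events = pd.DataFrame(events, columns=["sample_id", "locus_id", "end",
                                               "offset", "to_base", "frac"])
    return TruthTable(samples=samples, loci=loci, sites=sites, genotypes=geno,
                      dropouts=dropouts, pcr_events=pcr_events,
                      config=config, spec=spec)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class SampleReads:
    sample_id: str
    read1: list
    read2: list
    index: list


def _substitute(seq: str, pos: int, base: str) -> str:
    return seq[:pos] + base + seq[pos + 1:]


def _apply_seq_errors(seq: str, n: int, rng) -> str:
    chars = list(seq)
    for pos in rng.integers(0, len(chars), size=n):
        chars[pos] = DNA[(DNA.index(chars[pos]) + 1 + int(rng.integers(3))) % 4]
    return "".join(chars)


def simulate_reads(genome: dict, truth: TruthTable,
                   outdir=None) -> dict:
    """Per-sample indexed paired-end reads for a simulated cohort.

    Returns {sample_id: SampleReads}; when ``outdir`` is given, additionally
    writes ``<sample>_R1.fastq`` / ``_R2.fastq`` / ``_I1.fastq``.  Read ids
    encode full provenance (sample, locus, fragment, haplotype, pseudo-allele
    flag, orientation) so every read maps back to a truth record.
    """
    config = truth.config
    loci = truth.loci
    windows = locus_windows(genome, loci)
    events = {}
    for e in truth.pcr_events.itertuples():
        events[(e.sample_id, e.locus_id)] = e

    out = {}
    qual1 = chr(config.base_quality + 33) * _READ_LEN
    qual2 = chr(config.base_quality + 33) * C.READ2_RAW_LEN
    low1 = qual1[:20] + "#" * (_READ_LEN - 20)
    low2 = qual2[:20] + "#" * (C.READ2_RAW_LEN - 20)
    quali = chr(config.base_quality + 33) * C.INDEX_LEN

    for si, sample in enumerate(truth.samples.index):
        barcode = truth.samples.at[sample, "barcode"]
        r1_reads, r2_reads, idx_reads = [], [], []
        for li, lid in enumerate(loci.index):
            if (sample, lid) in truth.dropouts:
                continue
            rng = config.rng(4, si, li)
            depth = int(rng.poisson(config.depth_mean))
            if depth == 0:
                continue
            row = loci.loc[lid]
            left_ref, right_ref = windows[lid]

            # haplotype windows with the sample's alleles substituted in
            g1 = truth.genotype(sample, lid, "r1")
            g2 = truth.genotype(sample, lid, "r2")
            a1 = str(g1).split("/")
            a2 = str(g2).split("/") if g2 is not None else None
            n_hap = max(len(a1), 1)
            lefts, rights = [], []
            for h in range(n_hap):
                L = _substitute(left_ref, int(row.r1_snp_offset), a1[h % len(a1)])
                R = right_ref
                if a2 is not None:
                    R = _substitute(right_ref, int(row.r2_snp_offset),
                                    a2[h % len(a2)])
                lefts.append(L)
                rights.append(R)

            if bool(row.get("dup_locus", False)):
                # second copy: same windows but fixed alternate base at the
                # read-1 site; contributes its own fragments in every sample
                lefts.append(_substitute(left_ref, int(row.r1_snp_offset),
                                         row.r1_alt))
                rights.append(right_ref)
                extra = int(rng.poisson(config.depth_mean))
                haps_dup = np.full(extra, len(lefts) - 1, dtype=int)
                n_hap_eff = n_hap
            else:
                extra = 0
                haps_dup = None

            haps = rng.integers(0, n_hap, size=depth) if n_hap > 1 else \
                np.zeros(depth, dtype=int)
            if extra:
                haps = np.concatenate([haps, haps_dup])
                depth += extra
            orient = rng.integers(0, 2, size=depth)

            pseudo = np.zeros(depth, dtype=bool)
            ev = events.get((sample, lid))
            if ev is not None:
                k = int(rng.binomial(depth, ev.frac))
                if k:
                    pseudo[rng.choice(depth, size=k, replace=False)] = True
                # substituted base differs from the reference window base
                ref_window = left_ref if ev.end == "r1" else right_ref
                cur = ref_window[ev.offset]
                to_base = DNA[(DNA.index(cur) + 1 + int(rng.integers(3))) % 4]
                truth.pcr_events.loc[
                    (truth.pcr_events.sample_id == sample)
                    & (truth.pcr_events.locus_id == lid), "to_base"] = to_base

            nerr1 = rng.binomial(_READ_LEN, config.seq_error_rate, size=depth) \
                if config.seq_error_rate > 0 else np.zeros(depth, dtype=int)
            nerr2 = rng.binomial(C.READ2_RAW_LEN, config.seq_error_rate, size=depth) \
                if config.seq_error_rate > 0 else np.zeros(depth, dtype=int)
            lowq = rng.random(depth) < config.low_quality_read_frac \
                if config.low_quality_read_frac > 0 else np.zeros(depth, dtype=bool)

            for i in range(depth):
                h = int(haps[i])
                L, R = lefts[h], rights[h]
                if pseudo[i]:
                    if ev.end == "r1":
                        L = _substitute(L, ev.offset, to_base)
                    else:
                        R = _substitute(R, ev.offset, to_base)
                if orient[i] == 0:  # forward-reverse: read1 = left end
                    seq1 = L
                    seq2 = row.rev_annealing + R
                    tag = "FR"
                else:  # reverse-forward: read1 = right end
                    seq1 = R
                    seq2 = row.fwd_annealing + L
                    tag = "RF"
                if nerr1[i]:
                    seq1 = _apply_seq_errors(seq1, int(nerr1[i]), rng)
                if nerr2[i]:
                    seq2 = _apply_seq_errors(seq2, int(nerr2[i]), rng)
                rid = f"{sample}|{lid}|{i}|h{h}|{'P' if pseudo[i] else '-'}|{tag}"
                r1_reads.append(FastqRead(rid + "/1", seq1,
                                          low1 if lowq[i] else qual1))
                r2_reads.append(FastqRead(rid + "/2", seq2,
                                          low2 if lowq[i] else qual2))
                idx_reads.append(FastqRead(rid + "/I", barcode, quali))
        out[sample] = SampleReads(sample, r1_reads, r2_reads, idx_reads)

    if outdir is not None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample, reads in out.items():
            write_fastq(reads.read1, outdir / f"{sample}_R1.fastq")
            write_fastq(reads.read2, outdir / f"{sample}_R2.fastq")
            write_fastq(reads.index, outdir / f"{sample}_I1.fastq")
    return out


def parse_read_id(rid: str) -> dict:
    """Invert the simulator's read-id encoding (provenance round trip)."""
    core = rid.rsplit("/", 1)[0]
    sample, locus, frag, hap, pseudo, orient = core.split("|")
    return dict(sample_id=sample, locus_id=locus, fragment=int(frag),
                haplotype=int(hap[1:]), pseudo_allele=pseudo == "P",
                orientation=orient)


# ---------------------------------------------------------------------------
# matrix-level view of the truth (for analyses that skip read simulation)
# ---------------------------------------------------------------------------

def truth_to_matrix(truth: TruthTable, apply_dropout: bool = True) -> GenotypeMatrix:
    """Observed genotype matrix implied by the truth table.

    Site ids follow the genotyper convention ``<locus>.<end>:<offset>`` —
    each read window is its own locus, exactly as the de-novo pipeline sees
    the data.  Dropped (sample, locus) pairs become missing cells.
    """
    cols, meta = [], []
    for sid, srow in truth.sites.iterrows():
        col = f"{srow.locus_id}.{srow.end}:{srow.offset}"
        cols.append((sid, col))
        meta.append((col, f"{srow.locus_id}.{srow.end}", int(srow.offset)))
    calls = pd.DataFrame(index=truth.genotypes.index,
                         columns=[c for _, c in cols], dtype=object)
    for sid, col in cols:
        locus = truth.sites.at[sid, "locus_id"]
        for s in calls.index:
            if apply_dropout and (s, locus) in truth.dropouts:
                continue
            g = truth.genotypes.at[s, sid]
            if g is None:
                continue
            alleles = str(g).split("/")
            calls.at[s, col] = format_genotype(alleles) if len(alleles) > 1 else alleles[0]
    sites = pd.DataFrame({"locus_id": [m[1] for m in meta],
                          "pos": [m[2] for m in meta]},
                         index=[m[0] for m in meta])
    ploidy = truth.samples["ploidy"].copy()
    ploidy.index = list(truth.samples.index)
    return GenotypeMatrix(calls=calls, sites=sites, ploidy=ploidy)


def match_catalog_to_truth(catalog_consensus: dict, genome: dict,
                           loci: pd.DataFrame, max_mismatch: int = 4) -> dict:
    """Map de-novo catalog loci back to planted (locus, end) windows.

    ``catalog_consensus`` is {catalog_locus_id: 80-nt consensus}.  Returns
    {catalog_locus_id: "<planted locus>.<end>"} for consensus within
    ``max_mismatch`` of a reference window (allele differences included).
    """
    windows = locus_windows(genome, loci)
    refs = {}
    for lid, (left, right) in windows.items():
        refs[f"{lid}.r1"] = left
        refs[f"{lid}.r2"] = right
    out = {}
    for cid, cons in catalog_consensus.items():
        best, best_d = None, max_mismatch + 1
        for name, ref in refs.items():
            d = hamming(cons, ref)
            if d < best_d:
                best, best_d = name, d
        if best is not None:
            out[cid] = best
    return out
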