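"""Simplified de-novo stack-based SNP discovery and genotyping.

A functional desk-scale stand-in for the ustacks/cstacks/sstacks/populations
chain: identical 80-nt reads are bundled into stacks per sample, stacks are
merged into putative sample loci (greedy, highest-depth seed first, merge
distance M), sample loci are clustered across samples into a catalog (mismatch
budget n), and genotypes are called from per-site allele depths with the
depth-ratio rule: a minor allele whose depth is less than ``het_ratio``
(default 1/20) of the major allele's is rejected, otherwise the site is
heterozygous.  Haploid samples are always called as the major allele, but a
"haploid-heterozygote" flag records when the diploid rule would have called
heterozygous — the raw signal for duplicated-locus classification.

Deliberate simplifications versus the original software: the deleveraging and
removal algorithms are replaced by the greedy seed-first merge plus a cap
discarding sample loci assembled from more than ``max_stacks_per_locus``
primary stacks, and the likelihood-based SNP model is replaced by the
depth-ratio rule.  Ties are broken lexicographically throughout, so results
are deterministic.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import encode_matrix
from .matrix import GenotypeMatrix, format_genotype, site_id

READ_LEN = 80


@dataclass
class GenotyperConfig:
    m: int = 20              # minimum stack depth
    M: int = 2               # max distance between merged stacks
    n: int = 4               # catalog mismatch budget between samples
    het_ratio: float = 1 / 20  # min minor/major depth ratio to call het
    r: float = 0.5           # min fraction of samples per population
    p: int = 1               # min number of populations per locus
    single_snp: bool = True  # keep only the first SNP of each locus
    ploidy: int = 2          # default ploidy when no per-sample map given
    max_stacks_per_locus: int = 3

    def __post_init__(self):
        if not 0 < self.het_ratio < 1:
            raise ValueError("het_ratio must be in (0, 1)")
        if self.m < 1:
            raise ValueError("m must be >= 1")


@dataclass
class Stack:
    sample_id: str
    consensus: str
    depth: int


@dataclass
class SampleLocus:
    """Merged stacks of one sample: consensus plus member (seq, depth) pairs."""

    sample_id: str
    consensus: str
    members: list  # [(seq, depth)], primary stacks and attached secondaries
    n_primary: int
    total_depth: int

    def site_depths(self, pos: int) -> dict:
        out: dict = {}
        for seq, depth in self.members:
            out[seq[pos]] = out.get(seq[pos], 0) + depth
        return out

    def variant_positions(self, reference: str) -> set:
        out = set()
        for seq, _ in self.members:
            if seq != reference:
                out.update(i for i, (a, b) in enumerate(zip(seq, reference)) if a != b)
        return out


@dataclass
class CatalogLocus:
    locus_id: str
    consensus: str
    members: Dict[str, list] = field(default_factory=dict)  # sample -> [SampleLocus]
    snp_sites: list = field(default_factory=list)  # [(pos, alleles)]

    def sample_site_depths(self, sample: str, pos: int) -> dict:
        out: dict = {}
        for sl in self.members.get(sample, []):
            for base, depth in sl.site_depths(pos).items():
                out[base] = out.get(base, 0) + depth
        return out


@dataclass
class GenotypeCall:
    alleles: tuple
    het_flag: bool  # haploid sample where the diploid rule said heterozygous
    depths: dict

    @property
    def genotype(self) -> str:
        return format_genotype(self.alleles) if len(self.alleles) > 1 else self.alleles[0]


# ---------------------------------------------------------------------------
# stacks within one sample
# ---------------------------------------------------------------------------

def build_stacks(reads: Iterable, sample_id: str,
                 config: GenotyperConfig = None) -> List[SampleLocus]:
    """Bundle identical reads and merge near-identical stacks into sample loci.

    Groups with depth >= m seed loci in depth order (lexicographic
    tie-break); remaining groups within M mismatches of a seed consensus are
    merged — smaller groups (depth < m) only ever join as secondary members.
    Sample loci assembled from more than ``max_stacks_per_locus`` primary
    stacks are discarded (highly repetitive pile-ups).
    """
    config = config or GenotyperConfig()
    seqs = []
    for r in reads:
        s = r if isinstance(r, str) else r.seq
        if len(s) != READ_LEN:
            raise ValueError(f"reads must be {READ_LEN} nt, got {len(s)}")
        seqs.append(s)
    if not seqs:
        return []
    counts = Counter(seqs)
    uniq = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    useqs = [s for s, _ in uniq]
    depths = np.array([c for _, c in uniq], dtype=np.int64)
    enc = encode_matrix(useqs)
    primary = depths >= config.m
    unused = np.ones(len(uniq), dtype=bool)

    loci = []
    for i in range(len(uniq)):
        if not (primary[i] and unused[i]):
            continue
        dist = (enc != enc[i]).sum(axis=1)
        take = unused & (dist <= config.M)
        unused[take] = False
        idx = np.nonzero(take)[0]
        n_primary = int(primary[idx].sum())
        if n_primary > config.max_stacks_per_locus:
            continue  # discard over-merged pile-up
        members = [(useqs[j], int(depths[j])) for j in idx]
        loci.append(SampleLocus(
            sample_id=sample_id, consensus=useqs[i], members=members,
            n_primary=n_primary, total_depth=int(depths[idx].sum())))
    return loci


# ---------------------------------------------------------------------------
# genotype calling
# ---------------------------------------------------------------------------

def call_genotype(site_depths: dict, config: GenotyperConfig = None,
                  ploidy: int = 2) -> Optional[GenotypeCall]:
    """Depth-ratio genotype call at one site.

    Diploid: heterozygous iff minor/major depth >= het_ratio, else homozygous
    for the major allele.  Haploid: the major allele, with a flag recording
    when the diploid rule would have called heterozygous.  Zero depth returns
    None (missing).
    """
    config = config or GenotyperConfig()
    ranked = sorted(site_depths.items(), key=lambda kv: (-kv[1], kv[0]))
    ranked = [(b, d) for b, d in ranked if d > 0]
    if not ranked:
        return None
    major, dmaj = ranked[0]
    het = len(ranked) > 1 and ranked[1][1] / dmaj >= config.het_ratio
    if ploidy == 1:
        return GenotypeCall((major,), het, dict(ranked))
    if het:
        minor = ranked[1][0]
        return GenotypeCall(tuple(sorted((major, minor))), False, dict(ranked))
    return GenotypeCall((major, major), False, dict(ranked))


# ---------------------------------------------------------------------------
# catalog across samples
# ---------------------------------------------------------------------------

def build_catalog(sample_loci: Sequence[SampleLocus],
                  config: GenotyperConfig = None) -> List[CatalogLocus]:
    """Greedy clustering of sample-locus consensus sequences at <= n mismatches.

    Consensus sequences are processed in total-depth order (lexicographic
    tie-break); each joins the first existing catalog locus whose consensus is
    within n mismatches, else founds a new one whose consensus it defines.
    """
    config = config or GenotyperConfig()
    sample_loci = list(sample_loci)
    if not sample_loci:
        return []
    groups: dict = {}
    for sl in sample_loci:
        groups.setdefault(sl.consensus, []).append(sl)
    ordered = sorted(groups.items(),
                     key=lambda kv: (-sum(sl.total_depth for sl in kv[1]), kv[0]))
    reps: list = []  # encoded catalog consensus
    catalog: List[CatalogLocus] = []
    rep_mat = None
    for cons, members in ordered:
        enc = encode_matrix([cons])[0]
        target = None
        if catalog:
            dist = (rep_mat != enc).sum(axis=1)
            hits = np.nonzero(dist <= config.n)[0]
            if hits.size:
                target = catalog[int(hits[0])]
        if target is None:
            target = CatalogLocus(locus_id="", consensus=cons)
            catalog.append(target)
            reps.append(enc)
            rep_mat = np.vstack(reps)
        for sl in members:
            target.members.setdefault(sl.sample_id, []).append(sl)
    for i, cat in enumerate(catalog):
        cat.locus_id = f"CL{i:05d}"
    return catalog


def _candidate_positions(cat: CatalogLocus) -> list:
    pos = set()
    for sls in cat.members.values():
        for sl in sls:
            pos.update(sl.variant_positions(cat.consensus))
    return sorted(pos)


def genotype_matrix(catalog: Sequence[CatalogLocus], samples: Sequence[str],
                    config: GenotyperConfig = None,
                    ploidy_map: dict = None) -> GenotypeMatrix:
    """Call genotypes at every polymorphic catalog site.

    A position is a SNP site when the called genotypes across samples carry
    more than one allele.  Cells for samples without a matching sample locus
    are missing.
    """
    config = config or GenotyperConfig()
    ploidy_map = ploidy_map or {}
    samples = list(samples)

    columns, meta, consensus = [], [], {}
    calls_cols, flags_cols, depth_cols = {}, {}, {}
    for cat in catalog:
        consensus[cat.locus_id] = cat.consensus
        for pos in _candidate_positions(cat):
            cells, flags, deps = {}, {}, {}
            alleles = set()
            for s in samples:
                if s not in cat.members:
                    continue
                ploidy = int(ploidy_map.get(s, config.ploidy))
                call = call_genotype(cat.sample_site_depths(s, pos), config, ploidy)
                if call is None:
                    continue
                cells[s] = call.genotype
                flags[s] = call.het_flag
                deps[s] = call.depths
                alleles.update(call.alleles)
            if len(alleles) < 2:
                continue
            sid = site_id(cat.locus_id, pos)
            columns.append(sid)
            meta.append((sid, cat.locus_id, pos))
            calls_cols[sid] = cells
            flags_cols[sid] = flags
            depth_cols[sid] = deps

    calls = pd.DataFrame(index=samples, columns=columns, dtype=object)
    het_flags = pd.DataFrame(False, index=samples, columns=columns)
    depths = pd.DataFrame(index=samples, columns=columns, dtype=object)
    for sid in columns:
        for s, g in calls_cols[sid].items():
            calls.at[s, sid] = g
        for s, f in flags_cols[sid].items():
            het_flags.at[s, sid] = bool(f)
        for s, d in depth_cols[sid].items():
            depths.at[s, sid] = d
    sites = pd.DataFrame({"locus_id": [m[1] for m in meta],
                          "pos": [m[2] for m in meta]},
                         index=[m[0] for m in meta])
    ploidy = pd.Series([int(ploidy_map.get(s, config.ploidy)) for s in samples],
                       index=samples)
    return GenotypeMatrix(calls=calls, het_flags=het_flags, depths=depths,
                          sites=sites, ploidy=ploidy, consensus=consensus)


# ---------------------------------------------------------------------------
# marker selection (populations step)
# ---------------------------------------------------------------------------

def population_filter(gm: GenotypeMatrix, populations: dict,
                      config: GenotyperConfig = None,
                      drop_monomorphic: bool = True) -> GenotypeMatrix:
    """Keep loci genotyped in >= r of samples in >= p populations; optionally
    keep only the first (leftmost) SNP per locus and drop monomorphic sites."""
    config = config or GenotyperConfig()
    unknown = [s for s in gm.samples if s not in populations]
    if unknown:
        raise KeyError(f"samples missing from population map: {unknown}")
    pops: dict = {}
    for s in gm.samples:
        pops.setdefault(populations[s], []).append(s)

    genotyped = gm.genotyped_mask()
    keep_sites = []
    for locus in gm.loci():
        sids = gm.sites_of_locus(locus)
        present = genotyped[sids].any(axis=1)
        n_ok = sum(present.loc[members].mean() >= config.r
                   for members in pops.values())
        if n_ok < config.p:
            continue
        chosen = sorted(sids, key=lambda s: int(gm.sites.loc[s, "pos"]))
        if config.single_snp:
            chosen = chosen[:1]
        keep_sites.extend(chosen)
    out = gm.subset_sites(keep_sites)
    if drop_monomorphic:
        poly = [sid for sid in out.site_ids if len(out.alleles_at(sid)) >= 2]
        out = out.subset_sites(poly)
    return out


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def genotype_samples(reads_by_sample: dict, config: GenotyperConfig = None,
                     ploidy_map: dict = None, populations: dict = None,
                     apply_population_filter: bool = True) -> GenotypeMatrix:
    """Stacks -> catalog -> genotype matrix (-> marker selection) pipeline.

    ``reads_by_sample`` maps sample id to an iterable of 80-nt read sequences
    (strings or objects with a ``seq`` attribute).
    """
    config = config or GenotyperConfig()
    all_loci = []
    for sample, reads in reads_by_sample.items():
        all_loci.extend(build_stacks(reads, sample, config))
    catalog = build_catalog(all_loci, config)
    gm = genotype_matrix(catalog, list(reads_by_sample), config, ploidy_map)
    if apply_population_filter and populations is not None:
        gm = population_filter(gm, populations, config)
    return gm
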