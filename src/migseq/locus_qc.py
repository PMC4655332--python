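"""Locus-level artifact control.

Five artifact classes are handled: sequencing errors (already absorbed by the
genotyper's depth thresholds), PCR pseudo-variants (single-sample minor
alleles; replicate discordance with a depth chi-square signature), pseudo-loci
from shifted priming (>60% shifted sequence homology), duplicated loci
(classified from haploid-heterozygote flags), and paired-end loci (the two
ends of one fragment, found as perfectly linked marker pairs).

Identity in the homology filter is counted over the full 80-base read length
(not the overlap), matching the arithmetic (80-16-16)/80 = 0.6 that defines
the published threshold; shifts are strictly smaller than 16 bases.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._seq import encode_matrix, revcomp
from .matrix import GenotypeMatrix, parse_genotype

READ_LEN = 80

STATUS_KEPT = "kept"
STATUS_SINGLETON = "removed_singleton"
STATUS_REPLICATE = "removed_replicate_discordant"
STATUS_HOMOLOGY = "removed_homology_group"
STATUS_PAIRED_END = "removed_paired_end"


@dataclass
class HomologyHit:
    locus_a: str
    locus_b: str
    shift: int
    identity: float


def _new_report(gm: GenotypeMatrix) -> pd.DataFrame:
    loci = gm.loci()
    return pd.DataFrame({"status": [STATUS_KEPT] * len(loci),
                         "evidence": [""] * len(loci),
                         "dup_type": [""] * len(loci)},
                        index=pd.Index(loci, name="locus_id"))


def _allele_carriers(gm: GenotypeMatrix, sid: str) -> dict:
    carriers: dict = {}
    for s in gm.samples:
        parsed = parse_genotype(gm.calls.at[s, sid])
        if parsed:
            for a in set(parsed):
                carriers.setdefault(a, set()).add(s)
    return carriers


# ---------------------------------------------------------------------------
# PCR-error filters
# ---------------------------------------------------------------------------

def remove_singleton_variant_loci(gm: GenotypeMatrix,
                                  report: Optional[pd.DataFrame] = None):
    """Drop loci whose minor allele is carried by exactly one sample.

    Random PCR errors cannot be shared among samples, so a variant seen in a
    single sample is treated as a pseudo-variant.  Monomorphic sites are left
    untouched.  Requires at least two samples.
    """
    if len(gm.samples) < 2:
        raise ValueError("singleton filter requires >= 2 samples")
    report = _new_report(gm) if report is None else report
    removed = set()
    for sid in gm.site_ids:
        carriers = _allele_carriers(gm, sid)
        if len(carriers) < 2:
            continue
        n_min = min(len(v) for v in carriers.values())
        if n_min == 1:
            locus = gm.sites.loc[sid, "locus_id"]
            removed.add(locus)
            report.loc[locus, ["status", "evidence"]] = [
                STATUS_SINGLETON, f"site {sid}: minor allele in one sample"]
    return gm.drop_loci(removed), report


def replicate_concordance_filter(gm: GenotypeMatrix, replicate_pairs: Sequence[tuple],
                                 report: Optional[pd.DataFrame] = None,
                                 alpha: float = 0.05):
    """Drop loci with discordant genotypes between declared replicate pairs.

    For each discordant locus, the two allele depths in the heterozygous
    member are tested against 1:1 by chi-square; P < alpha marks the biased
    depth ratio typical of a PCR error.
    """
    for a, b in replicate_pairs:
        for s in (a, b):
            if s not in gm.samples:
                raise KeyError(f"replicate sample {s!r} not in matrix")
    report = _new_report(gm) if report is None else report
    removed = set()
    for sid in gm.site_ids:
        locus = gm.sites.loc[sid, "locus_id"]
        if locus in removed:
            continue
        for a, b in replicate_pairs:
            ga, gb = parse_genotype(gm.calls.at[a, sid]), parse_genotype(gm.calls.at[b, sid])
            if ga is None or gb is None or ga == gb:
                continue
            chi2, pval = np.nan, np.nan
            if gm.depths is not None:
                # depth bias in whichever replicate shows the extra allele
                for s, g in ((a, ga), (b, gb)):
                    deps = gm.depths.at[s, sid]
                    if isinstance(deps, dict) and len(deps) >= 2:
                        d1, d2 = sorted(deps.values(), reverse=True)[:2]
                        chi2 = (d1 - d2) ** 2 / (d1 + d2)
                        pval = float(stats.chi2.sf(chi2, df=1))
                        break
            biased = bool(pval < alpha) if pval == pval else False
            removed.add(locus)
            report.loc[locus, ["status", "evidence"]] = [
                STATUS_REPLICATE,
                f"site {sid}: {a}={gm.calls.at[a, sid]} vs {b}={gm.calls.at[b, sid]};"
                f" depth chi2={chi2:.3g} P={pval:.3g} biased={biased}"]
            break
    return gm.drop_loci(removed), report


# ---------------------------------------------------------------------------
# shifted-priming pseudo-locus filter
# ---------------------------------------------------------------------------

def shifted_identity(a: str, b: str, max_shift: int = 16,
                     both_strands: bool = False) -> Tuple[float, int]:
    """Best ungapped identity of two 80-mers over offsets |s| < max_shift.

    Identity is matching positions divided by the read length (80), so a
    shift of s caps identity at (80 - s)/80 even for identical sequences.
    Returns (identity, shift); shift is the offset of b relative to a.
    """
    ident, shift = _identity_matrices([a, b], max_shift, both_strands)
    return float(ident[0, 1]), int(shift[0, 1])


def _identity_matrices(seqs: Sequence[str], max_shift: int,
                       both_strands: bool):
    n = len(seqs)
    L = len(seqs[0])
    enc = encode_matrix(seqs)
    onehot = np.zeros((n, L, 4), dtype=np.float32)
    for k in range(4):
        onehot[:, :, k] = enc == k
    variants = [(onehot, False)]
    if both_strands:
        rc = np.zeros_like(onehot)
        for k in range(4):
            rc[:, :, k] = (enc[:, ::-1] == 3 - k)
        variants.append((rc, True))
    best = np.zeros((n, n), dtype=np.float64)
    best_shift = np.zeros((n, n), dtype=np.int32)
    for other, _ in variants:
        for s in range(0, max_shift):
            A = onehot[:, s:, :].reshape(n, -1)
            B = other[:, : L - s, :].reshape(n, -1)
            # m[i, j] = matches of seq_i offset +s against seq_j (integral)
            m = np.rint(A @ B.T).astype(np.float64)
            for mat, sh in ((m, s), (m.T, -s)):
                upd = mat > best
                best = np.where(upd, mat, best)
                best_shift = np.where(upd, sh, best_shift)
    np.fill_diagonal(best_shift, 0)
    return best / L, best_shift


def shifted_homology_filter(gm: GenotypeMatrix,
                            identity_threshold: float = 0.6,
                            max_shift: int = 16,
                            both_strands: bool = False,
                            keep_one: bool = False,
                            report: Optional[pd.DataFrame] = None):
    """Remove whole groups of loci with >60% shifted sequence homology.

    Pairs whose best shifted identity exceeds the threshold form edges; every
    locus in a connected component of size >= 2 is removed (the published
    procedure eliminates entire groups, inevitably including some true loci).
    ``keep_one`` retains the lexicographically first locus of each group.
    """
    report = _new_report(gm) if report is None else report
    loci = [l for l in gm.loci() if l in gm.consensus]
    missing = [l for l in gm.loci() if l not in gm.consensus]
    if missing:
        raise ValueError(f"no consensus sequence for loci: {missing[:5]}...")
    if len(loci) < 2:
        return gm, report, []
    seqs = [gm.consensus[l] for l in loci]
    ident, shifts = _identity_matrices(seqs, max_shift, both_strands)
    graph = nx.Graph()
    graph.add_nodes_from(loci)
    hits = []
    for i, j in zip(*np.nonzero(np.triu(ident > identity_threshold, k=1))):
        hits.append(HomologyHit(loci[i], loci[j], int(shifts[i, j]),
                                float(ident[i, j])))
        graph.add_edge(loci[i], loci[j])
    removed = set()
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        comp = sorted(comp)
        doomed = comp[1:] if keep_one else comp
        for locus in doomed:
            removed.add(locus)
            partners = [c for c in comp if c != locus]
            report.loc[locus, ["status", "evidence"]] = [
                STATUS_HOMOLOGY, f"homology group with {','.join(partners)}"]
    return gm.drop_loci(removed), report, hits


# ---------------------------------------------------------------------------
# duplicated-locus classification
# ---------------------------------------------------------------------------

DUP_NORMAL = "normal"
DUP_HOMO_HOMO = "dup_homo_homo"
DUP_HOMO_HETERO = "dup_homo_hetero"
DUP_LINKAGE = "dup_linkage"
DUP_HETERO_HETERO = "dup_hetero_hetero"


def classify_duplicated_loci(gm: GenotypeMatrix, haploid_ids: Sequence[str],
                             alpha: float = 0.05, min_haploids: int = 8,
                             report: Optional[pd.DataFrame] = None) -> pd.Series:
    """Classify loci by the haploid-heterozygote signature of duplication.

    A haploid sample can only be truly homozygous, so an apparent heterozygote
    (the haploid-het flag) marks two co-assembled genomic copies.  Signatures:
    every haploid flagged -> two homozygous copies with different alleles
    (homo+homo); flagged:unflagged compatible with 1:1 (two-sided binomial,
    not rejected at alpha) with a single allele among unflagged -> homo+hetero;
    both homozygote classes present among unflagged -> hetero+hetero (1:2:1);
    a 1-3-sample minority class -> tight linkage of two nearby loci.
    """
    haploid_ids = [s for s in haploid_ids if s in gm.samples]
    if len(haploid_ids) < min_haploids:
        raise ValueError(
            f"duplicated-locus classification needs >= {min_haploids} haploid "
            f"samples, got {len(haploid_ids)}")
    out = {}
    for locus in gm.loci():
        sids = gm.sites_of_locus(locus)
        flagged, unflagged, unflagged_alleles = set(), set(), set()
        for s in haploid_ids:
            called = False
            is_flagged = False
            sample_alleles = set()
            for sid in sids:
                g = parse_genotype(gm.calls.at[s, sid])
                if g is None:
                    continue
                called = True
                sample_alleles.update(g)
                if bool(gm.het_flags.at[s, sid]):
                    is_flagged = True
            if not called:
                continue
            if is_flagged:
                flagged.add(s)
            else:
                unflagged.add(s)
                unflagged_alleles.update(sample_alleles)
        nf, nu = len(flagged), len(unflagged)
        total = nf + nu
        if total < min_haploids:
            out[locus] = "insufficient_haploids"
            continue
        if nf == 0:
            out[locus] = DUP_NORMAL
        elif nu == 0:
            out[locus] = DUP_HOMO_HOMO
        elif min(nf, nu) <= 3:
            out[locus] = DUP_LINKAGE
        elif stats.binomtest(nf, total, 0.5).pvalue >= alpha:
            out[locus] = (DUP_HETERO_HETERO if len(unflagged_alleles) >= 2
                          else DUP_HOMO_HETERO)
        else:
            out[locus] = DUP_LINKAGE
    result = pd.Series(out, name="dup_type")
    if report is not None:
        for locus, dup in result.items():
            if locus in report.index and dup not in (DUP_NORMAL,):
                report.loc[locus, "dup_type"] = dup
    return result


# ---------------------------------------------------------------------------
# paired-end locus detection
# ---------------------------------------------------------------------------

def detect_paired_end_loci(gm: GenotypeMatrix, min_informative: int = 8,
                           report: Optional[pd.DataFrame] = None):
    """Find marker pairs that are the two ends of one fragment.

    Both reads of a fragment carry the same two haplotypes, so the two derived
    markers are perfectly linked: across co-genotyped samples the genotype at
    one determines the genotype at the other (zero recombinants, bijective
    mapping, both sites polymorphic, >= min_informative informative samples).
    The lower-id locus of each linked group is retained.
    """
    report = _new_report(gm) if report is None else report
    first_site = {locus: gm.sites_of_locus(locus)[0] for locus in gm.loci()}
    loci = sorted(first_site)
    graph = nx.Graph()
    graph.add_nodes_from(loci)
    pairs = []
    for la, lb in itertools.combinations(loci, 2):
        sa, sb = first_site[la], first_site[lb]
        fwd, rev = {}, {}
        n = 0
        ok = True
        for s in gm.samples:
            ga = parse_genotype(gm.calls.at[s, sa])
            gb = parse_genotype(gm.calls.at[s, sb])
            if ga is None or gb is None:
                continue
            n += 1
            if fwd.setdefault(ga, gb) != gb or rev.setdefault(gb, ga) != ga:
                ok = False
                break
        if ok and n >= min_informative and len(fwd) >= 2 and len(rev) >= 2:
            pairs.append((la, lb))
            graph.add_edge(la, lb)
    removed = set()
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        comp = sorted(comp)
        for locus in comp[1:]:
            removed.add(locus)
            report.loc[locus, ["status", "evidence"]] = [
                STATUS_PAIRED_END, f"paired with {comp[0]}"]
    return gm.drop_loci(removed), report, pairs


# ---------------------------------------------------------------------------
# Hardy-Weinberg screen (flag only)
# ---------------------------------------------------------------------------

def hwe_test(gm: GenotypeMatrix, samples: Optional[Sequence[str]] = None) -> pd.Series:
    """Chi-square Hardy-Weinberg test per biallelic site over diploid samples."""
    samples = [s for s in (samples or gm.samples) if gm.ploidy[s] == 2]
    out = {}
    for sid in gm.site_ids:
        alleles = gm.alleles_at(sid)
        if len(alleles) != 2:
            out[sid] = np.nan
            continue
        a, b = alleles
        counts = {f"{a}/{a}": 0, f"{a}/{b}": 0, f"{b}/{b}": 0}
        for s in samples:
            parsed = parse_genotype(gm.calls.at[s, sid])
            if parsed and len(parsed) == 2:
                counts["/".join(parsed)] += 1
        n = sum(counts.values())
        if n == 0:
            out[sid] = np.nan
            continue
        p = (2 * counts[f"{a}/{a}"] + counts[f"{a}/{b}"]) / (2 * n)
        exp = np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)]) * n
        obs = np.array(list(counts.values()), dtype=float)
        valid = exp > 0
        chi2 = ((obs[valid] - exp[valid]) ** 2 / exp[valid]).sum()
        out[sid] = float(stats.chi2.sf(chi2, df=1))
    return pd.Series(out, name="hwe_p")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_qc(gm: GenotypeMatrix, replicate_pairs: Sequence[tuple] = (),
           haploid_ids: Sequence[str] = (),
           identity_threshold: float = 0.6, max_shift: int = 16,
           min_informative: int = 8, classify_duplicates: bool = True):
    """Published filter order: singleton/replicate -> homology -> paired-end.

    Returns (filtered matrix, QC report).  The report lists every input locus
    exactly once with its final status; duplicated-locus types are recorded as
    flags, not removals.  Re-running on the filtered output is idempotent.
    """
    report = _new_report(gm)
    out, report = remove_singleton_variant_loci(gm, report)
    if replicate_pairs:
        out, report = replicate_concordance_filter(out, replicate_pairs, report)
    if out.consensus:
        out, report, _ = shifted_homology_filter(
            out, identity_threshold, max_shift, report=report)
    if classify_duplicates and len(haploid_ids) >= 8:
        classify_duplicated_loci(out, haploid_ids, report=report)
    out, report, _ = detect_paired_end_loci(out, min_informative, report)
    return out, report
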