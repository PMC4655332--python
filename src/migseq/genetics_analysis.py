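"""Downstream genetic analyses: segregation, clone identification, differentiation.

Three reusable procedures mirroring the validation analyses of the method:

* Mendelian segregation — variants heterozygous in a mother tree must
  segregate 1:1 in her haploid megagametophytes; tested by an uncorrected
  chi-square (a - b)^2 / (a + b) with one degree of freedom (a Yates-corrected
  variant is available by flag).
* Clone (individual) identification — pairwise counts of differing SNPs over
  co-genotyped loci; ramets of one genet differ by a handful of somatic or
  residual-error SNPs while distinct genets differ by tens, giving a bimodal
  difference histogram; the automatic threshold is the midpoint of the
  largest gap in the sorted pairwise differences, and genets are the
  single-linkage components at or below it.
* Population differentiation — per-population allele frequencies, a
  Hudson-type FST estimator (sample-size-corrected numerator over mean
  between-population diversity, averaged as a ratio of sums), and an
  allele-sharing distance matrix for external ordination.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .matrix import GenotypeMatrix, parse_genotype


# ---------------------------------------------------------------------------
# Mendelian segregation
# ---------------------------------------------------------------------------

def segregation_test(gm: GenotypeMatrix, mother_ids, haploid_ids: Sequence[str],
                     min_informative: int = 10,
                     yates: bool = False) -> pd.DataFrame:
    """Chi-square 1:1 segregation test over a haploid panel.

    A locus qualifies when the mother (every listed replicate, concordantly)
    is heterozygous, no genotyped haploid carries the haploid-heterozygote
    flag (those are duplicated-locus candidates, not segregation material),
    and at least ``min_informative`` haploids are genotyped.  Returns one row
    per qualifying locus with the two allele counts, the chi-square statistic
    and its two-sided p-value (df = 1).
    """
    if isinstance(mother_ids, str):
        mother_ids = [mother_ids]
    haploid_ids = [s for s in haploid_ids if s in gm.samples]
    rows = []
    for locus in gm.loci():
        for sid in gm.sites_of_locus(locus):
            mg = [parse_genotype(gm.calls.at[m, sid]) for m in mother_ids]
            if any(g is None for g in mg) or len(set(mg)) != 1:
                continue
            alleles = mg[0]
            if len(set(alleles)) != 2:
                continue  # mother not heterozygous here
            counts = {a: 0 for a in alleles}
            flagged = False
            for h in haploid_ids:
                g = parse_genotype(gm.calls.at[h, sid])
                if g is None:
                    continue
                if bool(gm.het_flags.at[h, sid]):
                    flagged = True
                    break
                if g[0] in counts:
                    counts[g[0]] += 1
            if flagged:
                continue
            a, b = (counts[x] for x in sorted(counts))
            n = a + b
            if n < min_informative:
                continue
            if yates:
                chi2 = (abs(a - b) - 1) ** 2 / n if n else np.nan
            else:
                chi2 = (a - b) ** 2 / n if n else np.nan
            rows.append(dict(locus_id=locus, site_id=sid,
                             allele_a=sorted(counts)[0], allele_b=sorted(counts)[1],
                             count_a=a, count_b=b, informative_n=n,
                             chi_square=chi2,
                             p_value=float(stats.chi2.sf(chi2, df=1))))
            break  # one site per locus
    out = pd.DataFrame(rows, columns=["locus_id", "site_id", "allele_a", "allele_b",
                                      "count_a", "count_b", "informative_n",
                                      "chi_square", "p_value"])
    if out.empty:
        warnings.warn("no loci qualified for the segregation test")
    return out


# ---------------------------------------------------------------------------
# clone identification
# ---------------------------------------------------------------------------

@dataclass
class CloneAssignment:
    """Pairwise SNP-difference matrix with optional clonal grouping."""

    differences: pd.DataFrame      # samples x samples, NaN when no shared loci
    shared_counts: pd.DataFrame    # co-genotyped locus counts
    threshold: Optional[float] = None
    groups: list = field(default_factory=list)  # list of sample-id lists

    def histogram(self) -> pd.Series:
        vals = []
        samples = list(self.differences.index)
        for i, a in enumerate(samples):
            for b in samples[i + 1:]:
                v = self.differences.at[a, b]
                if v == v:
                    vals.append(int(v))
        return pd.Series(vals, dtype=int).value_counts().sort_index()


def pairwise_difference_matrix(gm: GenotypeMatrix) -> CloneAssignment:
    """Count differing SNPs for every sample pair over co-genotyped loci.

    Any allelic mismatch at a site counts as one difference; loci missing in
    either sample are excluded from that pair's comparison, and a pair with no
    co-genotyped locus gets a missing cell.
    """
    samples = gm.samples
    if len(samples) < 2:
        raise ValueError("need >= 2 samples")
    parsed = {s: [parse_genotype(g) for g in gm.calls.loc[s]] for s in samples}
    diff = pd.DataFrame(np.nan, index=samples, columns=samples)
    shared = pd.DataFrame(0, index=samples, columns=samples)
    for i, a in enumerate(samples):
        diff.at[a, a] = 0.0
        shared.at[a, a] = sum(g is not None for g in parsed[a])
        for b in samples[i + 1:]:
            n, d = 0, 0
            for ga, gb in zip(parsed[a], parsed[b]):
                if ga is None or gb is None:
                    continue
                n += 1
                if ga != gb:
                    d += 1
            shared.at[a, b] = shared.at[b, a] = n
            if n:
                diff.at[a, b] = diff.at[b, a] = float(d)
    return CloneAssignment(differences=diff, shared_counts=shared)


def assign_clones(assignment: CloneAssignment,
                  threshold: Optional[float] = None) -> CloneAssignment:
    """Group samples into genets by single linkage at a difference threshold.

    The automatic threshold assumes a bimodal difference distribution (near
    zero within clones, large between) and takes the midpoint of the largest
    gap between consecutive sorted pairwise values; a unimodal distribution
    triggers a warning but still yields a grouping.
    """
    samples = list(assignment.differences.index)
    vals = sorted({float(assignment.differences.at[a, b])
                   for i, a in enumerate(samples) for b in samples[i + 1:]
                   if assignment.differences.at[a, b] == assignment.differences.at[a, b]})
    if threshold is None:
        if len(vals) < 2:
            warnings.warn("degenerate pairwise-difference distribution; "
                          "using the single observed value as threshold")
            threshold = vals[0] if vals else 0.0
        else:
            gaps = [(vals[i + 1] - vals[i], i) for i in range(len(vals) - 1)]
            width, i = max(gaps)
            if width <= 1:
                warnings.warn("no clear gap in the pairwise-difference "
                              "distribution; clone threshold is unreliable")
            threshold = (vals[i] + vals[i + 1]) / 2
    graph = nx.Graph()
    graph.add_nodes_from(samples)
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            v = assignment.differences.at[a, b]
            if v == v and v <= threshold:
                graph.add_edge(a, b)
    groups = sorted((sorted(c) for c in nx.connected_components(graph)),
                    key=lambda c: c[0])
    return CloneAssignment(differences=assignment.differences,
                           shared_counts=assignment.shared_counts,
                           threshold=float(threshold), groups=groups)


# ---------------------------------------------------------------------------
# population differentiation
# ---------------------------------------------------------------------------

@dataclass
class PopDiffSummary:
    frequencies: pd.DataFrame     # sites x populations (alt-allele frequency)
    sample_sizes: pd.DataFrame    # sites x populations (allele counts)
    fst_per_site: pd.Series
    mean_fst: float
    distances: pd.DataFrame       # samples x samples allele-sharing distance


def _hudson_fst(p1, p2, n1, n2):
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def population_differentiation(gm: GenotypeMatrix,
                               populations: Dict[str, str]) -> PopDiffSummary:
    """Allele frequencies, Hudson-type FST and allele-sharing distances.

    ``populations`` maps sample id -> population label (two or more
    populations, each with >= 2 samples).  FST is computed per biallelic site
    from the first two populations' frequencies and averaged as a ratio of
    sums; sites with all-missing data in a population are skipped.
    """
    pops: dict = {}
    for s in gm.samples:
        if s in populations:
            pops.setdefault(populations[s], []).append(s)
    names = sorted(pops)
    if len(names) < 2 or any(len(v) < 2 for v in pops.values()):
        raise ValueError("need >= 2 populations with >= 2 samples each")

    freqs = pd.DataFrame(np.nan, index=gm.site_ids, columns=names)
    sizes = pd.DataFrame(0, index=gm.site_ids, columns=names)
    fst = pd.Series(np.nan, index=gm.site_ids, dtype=float)
    num_sum = den_sum = 0.0
    for sid in gm.site_ids:
        alleles = gm.alleles_at(sid)
        if len(alleles) < 2:
            continue
        alt = alleles[1]
        per_pop = {}
        for pop in names:
            count = tot = 0
            for s in pops[pop]:
                parsed = parse_genotype(gm.calls.at[s, sid])
                if parsed is None:
                    continue
                tot += len(parsed)
                count += sum(a == alt for a in parsed)
            if tot:
                freqs.at[sid, pop] = count / tot
                sizes.at[sid, pop] = tot
            per_pop[pop] = (count, tot)
        (c1, t1), (c2, t2) = per_pop[names[0]], per_pop[names[1]]
        if t1 > 1 and t2 > 1:
            num, den = _hudson_fst(c1 / t1, c2 / t2, t1, t2)
            if den > 0:
                fst[sid] = num / den
                num_sum += num
                den_sum += den
    mean_fst = num_sum / den_sum if den_sum > 0 else np.nan

    samples = gm.samples
    dist = pd.DataFrame(0.0, index=samples, columns=samples)
    parsed_all = {s: [parse_genotype(g) for g in gm.calls.loc[s]] for s in samples}
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            share, n = 0.0, 0
            for ga, gb in zip(parsed_all[a], parsed_all[b]):
                if ga is None or gb is None:
                    continue
                n += 1
                ca, cb = list(ga), list(gb)
                matched = 0
                for x in ca:
                    if x in cb:
                        cb.remove(x)
                        matched += 1
                share += matched / max(len(ga), len(gb))
            d = 1.0 - share / n if n else np.nan
            dist.at[a, b] = dist.at[b, a] = d
    return PopDiffSummary(frequencies=freqs, sample_sizes=sizes,
                          fst_per_site=fst, mean_fst=float(mean_fst),
                          distances=dist)
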