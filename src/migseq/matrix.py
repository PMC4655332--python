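"""Genotype matrix container shared by the genotyper, QC and analysis layers.

Cells are genotype strings: ``"A/T"`` for diploid calls (alleles sorted),
``"A"`` for haploid calls, and missing data is NaN — a locus not detected in
a sample is missing, never homozygous reference.  Site ids are
``"<locus_id>:<pos>"`` with a 0-based offset into the 80-nt locus consensus.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

MISSING = "."


def parse_genotype(g):
    """Genotype string -> sorted allele tuple, or None for missing."""
    if g is None or (isinstance(g, float) and np.isnan(g)) or g in ("", MISSING):
        return None
    return tuple(sorted(str(g).split("/")))


def format_genotype(alleles) -> str:
    return "/".join(sorted(alleles))


def genotypes_equal(a, b) -> bool:
    return parse_genotype(a) == parse_genotype(b)


def site_id(locus_id: str, pos: int) -> str:
    return f"{locus_id}:{pos}"


def split_site_id(sid: str):
    locus, _, pos = sid.rpartition(":")
    return locus, int(pos)


@dataclass
class GenotypeMatrix:
    """Samples x SNP-sites genotype calls with per-cell depths and flags.

    calls      samples x site_ids DataFrame of genotype strings / NaN.
    het_flags  same shape, True where the diploid rule would have called a
               haploid sample heterozygous (duplicated-locus signal).
    depths     same shape, dict {base: depth} per genotyped cell (optional).
    sites      per-site metadata indexed by site_id: locus_id, pos, alleles.
    ploidy     per-sample ploidy (1 or 2).
    consensus  locus_id -> 80-nt catalog consensus (optional; required by the
               homology filter).
    """

    calls: pd.DataFrame
    het_flags: Optional[pd.DataFrame] = None
    depths: Optional[pd.DataFrame] = None
    sites: Optional[pd.DataFrame] = None
    ploidy: Optional[pd.Series] = None
    consensus: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.het_flags is None:
            self.het_flags = pd.DataFrame(False, index=self.calls.index,
                                          columns=self.calls.columns)
        if self.sites is None:
            meta = [split_site_id(s) for s in self.calls.columns]
            self.sites = pd.DataFrame(
                {"locus_id": [m[0] for m in meta], "pos": [m[1] for m in meta]},
                index=list(self.calls.columns))
        if self.ploidy is None:
            self.ploidy = pd.Series(2, index=self.calls.index)

    # -- basic accessors ----------------------------------------------------
    @property
    def samples(self) -> list:
        return list(self.calls.index)

    @property
    def site_ids(self) -> list:
        return list(self.calls.columns)

    def loci(self) -> list:
        seen, out = set(), []
        for lid in self.sites["locus_id"]:
            if lid not in seen:
                seen.add(lid)
                out.append(lid)
        return out

    def sites_of_locus(self, locus_id: str) -> list:
        return list(self.sites.index[self.sites["locus_id"] == locus_id])

    def genotyped_mask(self) -> pd.DataFrame:
        return self.calls.notna() & (self.calls != MISSING)

    def alleles_at(self, sid: str) -> list:
        """Distinct alleles among called genotypes at a site, sorted."""
        alleles = set()
        for g in self.calls[sid].dropna():
            parsed = parse_genotype(g)
            if parsed:
                alleles.update(parsed)
        return sorted(alleles)

    # -- subsetting ---------------------------------------------------------
    def subset_sites(self, keep: Iterable[str]) -> "GenotypeMatrix":
        keep = [s for s in self.site_ids if s in set(keep)]
        return GenotypeMatrix(
            calls=self.calls[keep].copy(),
            het_flags=self.het_flags[keep].copy(),
            depths=self.depths[keep].copy() if self.depths is not None else None,
            sites=self.sites.loc[keep].copy(),
            ploidy=self.ploidy.copy(),
            consensus={k: v for k, v in self.consensus.items()
                       if k in set(self.sites.loc[keep, "locus_id"])},
        )

    def drop_loci(self, locus_ids: Iterable[str]) -> "GenotypeMatrix":
        drop = set(locus_ids)
        keep = [s for s in self.site_ids if self.sites.loc[s, "locus_id"] not in drop]
        return self.subset_sites(keep)

    # -- text round trip ----------------------------------------------------
    def to_tsv(self, path) -> None:
        """Genotype table TSV (samples x sites, '.' for missing)."""
        out = self.calls.fillna(MISSING)
        out.index.name = "sample"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, ploidy: Optional[pd.Series] = None) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        df = df.replace(MISSING, np.nan)
        return cls(calls=df, ploidy=ploidy)
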