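"""In-silico multiplexed ISSR-PCR: annealing-site scan and amplicon prediction.

Finds primer annealing footprints on both strands of a genome, pairs
convergent (+/-) sites into amplicons, applies the 300-800 bp library size
selection (the genomic span plus 17 non-genomic tail bases per end), and
extracts the two 80-nt end windows that the sequencer reports as reads 1/2.

Coordinates are 0-based half-open throughout (and in BED output); FASTA
headers additionally carry 1-based inclusive spans for human reading.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import constants as C
from ._seq import encode, require_dna, revcomp
from .primer_design import PrimerSet, TailedPrimer


@dataclass(frozen=True)
class AnnealingSite:
    """Genomic footprint of a primer's 14-nt annealing part."""

    contig: str
    start: int
    end: int
    strand: str  # "+" | "-"
    primer_name: str
    mismatches: int = 0

    def __post_init__(self):
        if self.end - self.start != C.ANNEALING_LEN:
            raise ValueError("annealing footprint must span 14 bases")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class PredictedAmplicon:
    """A convergent site pair with its insert coordinates and library size."""

    contig: str
    fwd_site: AnnealingSite
    rev_site: AnnealingSite
    insert_start: int
    insert_end: int
    genomic_len: int
    library_len: int
    sequenceable_fraction: float = 0.5


@dataclass
class LocusTemplate:
    """The two 80-nt end windows of an amplicon, as sequenced.

    ``read1_seq`` is the top strand immediately interior to the forward
    footprint; ``read2_seq`` is the bottom strand immediately interior to the
    reverse footprint (reverse complement of the corresponding top-strand
    window).  ``overlap_risk`` flags inserts shorter than 160 bases, where the
    two windows overlap.
    """

    amplicon: PredictedAmplicon
    read1_seq: str
    read2_seq: str
    locus_id: str
    overlap_risk: bool = False


# ---------------------------------------------------------------------------
# primer / genome input normalisation
# ---------------------------------------------------------------------------

def _annealing_queries(primers) -> list:
    """Distinct (name, annealing_seq) pairs from a PrimerSet, TailedPrimers,
    PrimerCandidates, or raw (name, seq) tuples."""
    items = []
    if isinstance(primers, PrimerSet):
        for fwd, _rev in primers.members:
            items.append((fwd.candidate.base_name, fwd.annealing_seq))
    else:
        for p in primers:
            if isinstance(p, TailedPrimer):
                items.append((p.candidate.base_name, p.annealing_seq))
            elif isinstance(p, tuple) and len(p) == 2 and isinstance(p[0], str):
                items.append((p[0], require_dna(p[1], "annealing sequence")))
            elif hasattr(p, "annealing_seq"):
                items.append((p.base_name, p.annealing_seq))
            else:
                raise TypeError(f"cannot interpret primer {p!r}")
    seen, out = set(), []
    for name, seq in items:
        if seq not in seen:
            seen.add(seq)
            out.append((name, seq))
    return out


def as_genome_dict(genome) -> dict:
    """Normalise FASTA path / dict / SeqRecord iterable to {contig: str}."""
    if isinstance(genome, dict):
        return {k: str(v).upper() for k, v in genome.items()}
    if isinstance(genome, (str, Path)):
        from .io import read_fasta
        return read_fasta(genome)
    out = {}
    for rec in genome:  # Bio.SeqRecord iterable
        out[rec.id] = str(rec.seq).upper()
    return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def find_annealing_sites(genome, primers, max_mismatch_5prime: int = 0,
                         exact_3prime_len: int = 6) -> list:
    """Scan both strands for primer annealing footprints.

    A position qualifies when the primer's 3'-terminal ``exact_3prime_len``
    bases match exactly and the remaining 5' bases match with at most
    ``max_mismatch_5prime`` mismatches.  The defaults (6 exact 3' bases — the
    anchor plus the last repeat unit — and zero 5' mismatches) give strict
    perfect-site prediction; raising ``max_mismatch_5prime`` models the
    low-stringency annealing of the 48 degC protocol.  Non-ACGT characters
    never match and are counted in the scan (warning emitted via ``warnings``).
    """
    if not 0 < exact_3prime_len <= C.ANNEALING_LEN:
        raise ValueError("exact_3prime_len must be in 1..14")
    queries = _annealing_queries(primers)
    contigs = as_genome_dict(genome)
    sites = []
    n_bad = 0
    for contig, seq in contigs.items():
        if len(seq) < C.ANNEALING_LEN:
            continue
        enc = encode(seq)
        n_bad += int((enc == 255).sum())
        windows = np.lib.stride_tricks.sliding_window_view(enc, C.ANNEALING_LEN)
        for name, query in queries:
            # plus strand: exact region is the 3' (right) end of the footprint
            q = encode(query)
            neq = windows != q
            ok3 = ~neq[:, C.ANNEALING_LEN - exact_3prime_len:].any(axis=1)
            mm5 = neq[:, : C.ANNEALING_LEN - exact_3prime_len].sum(axis=1)
            for pos in np.nonzero(ok3 & (mm5 <= max_mismatch_5prime))[0]:
                sites.append(AnnealingSite(contig, int(pos), int(pos) + C.ANNEALING_LEN,
                                           "+", name, int(mm5[pos])))
            # minus strand: footprint matches revcomp(query); the primer 3' end
            # maps to the footprint start in top-strand coordinates
            qrc = encode(revcomp(query))
            neq = windows != qrc
            ok3 = ~neq[:, :exact_3prime_len].any(axis=1)
            mm5 = neq[:, exact_3prime_len:].sum(axis=1)
            for pos in np.nonzero(ok3 & (mm5 <= max_mismatch_5prime))[0]:
                sites.append(AnnealingSite(contig, int(pos), int(pos) + C.ANNEALING_LEN,
                                           "-", name, int(mm5[pos])))
    if n_bad:
        import warnings
        warnings.warn(f"{n_bad} non-ACGT genome characters skipped during site scan")
    sites.sort(key=lambda s: (s.contig, s.start, s.strand, s.primer_name))
    return sites


def predict_amplicons(sites: Sequence[AnnealingSite],
                      min_len: int = C.SIZE_SELECT_MIN,
                      max_len: int = C.SIZE_SELECT_MAX,
                      tail_bases_per_end: int = C.TAIL_BASES_PER_END) -> list:
    """Pair convergent sites into size-selected amplicons.

    Every (+, -) pair on the same contig with the reverse footprint downstream
    of the forward one becomes an amplicon when its library length (genomic
    span + 2 x 17 tail bases) falls within [min_len, max_len].  Any primer may
    pair with any primer; nested and overlapping amplicons are all reported.
    Half of the PCR product carries same-tail (forward-forward or reverse-
    reverse) adapters and cannot be sequenced, hence sequenceable_fraction 0.5.
    """
    if not 0 < min_len < max_len:
        raise ValueError("require 0 < min_len < max_len")
    extra = 2 * tail_bases_per_end
    by_contig: dict = {}
    for s in sites:
        by_contig.setdefault(s.contig, ([], []))[0 if s.strand == "+" else 1].append(s)
    out = []
    for contig, (plus, minus) in sorted(by_contig.items()):
        for f in plus:
            for r in minus:
                if r.start < f.end:
                    continue
                genomic_len = r.end - f.start
                library_len = genomic_len + extra
                if min_len <= library_len <= max_len:
                    out.append(PredictedAmplicon(
                        contig=contig, fwd_site=f, rev_site=r,
                        insert_start=f.end, insert_end=r.start,
                        genomic_len=genomic_len, library_len=library_len))
    out.sort(key=lambda a: (a.contig, a.fwd_site.start, a.rev_site.start))
    return out


def extract_locus_reads(amplicon: PredictedAmplicon, genome,
                        read_len: int = C.READ1_LEN,
                        locus_id: str = None) -> LocusTemplate:
    """The 80-nt end windows of one amplicon (read 1 top strand, read 2 bottom)."""
    contigs = as_genome_dict(genome)
    seq = contigs[amplicon.contig]
    insert_len = amplicon.insert_end - amplicon.insert_start
    read1 = seq[amplicon.insert_start: amplicon.insert_start + read_len]
    read2 = revcomp(seq[amplicon.insert_end - read_len: amplicon.insert_end])
    if locus_id is None:
        locus_id = (f"{amplicon.contig}:{amplicon.fwd_site.start}-{amplicon.rev_site.end}"
                    f":{amplicon.fwd_site.primer_name}+{amplicon.rev_site.primer_name}")
    return LocusTemplate(amplicon=amplicon, read1_seq=read1, read2_seq=read2,
                         locus_id=locus_id, overlap_risk=insert_len < 2 * read_len)


def scan_genome(genome, primers, min_len: int = C.SIZE_SELECT_MIN,
                max_len: int = C.SIZE_SELECT_MAX, max_mismatch_5prime: int = 0,
                exact_3prime_len: int = 6) -> list:
    """Site scan -> amplicon pairing -> end-window extraction, end to end."""
    contigs = as_genome_dict(genome)
    sites = find_annealing_sites(contigs, primers, max_mismatch_5prime, exact_3prime_len)
    amps = predict_amplicons(sites, min_len, max_len)
    return [extract_locus_reads(a, contigs, locus_id=f"locus_{i:05d}")
            for i, a in enumerate(amps)]


def export_loci(templates: Sequence[LocusTemplate], bed_path, fasta_path) -> None:
    """Write insert coordinates as BED6 and the end windows as FASTA."""
    templates = list(templates)
    if not templates:
        raise ValueError("no locus templates to export")
    with open(bed_path, "w") as bed:
        for t in templates:
            a = t.amplicon
            name = f"{t.locus_id}|{a.fwd_site.primer_name}+{a.rev_site.primer_name}"
            bed.write(f"{a.contig}\t{a.insert_start}\t{a.insert_end}\t{name}\t"
                      f"{a.library_len}\t+\n")
    with open(fasta_path, "w") as fa:
        for t in templates:
            a = t.amplicon
            span = f"{a.contig}:{a.insert_start + 1}-{a.insert_end}"
            fa.write(f">{t.locus_id}/read1 {span}\n{t.read1_seq}\n")
            fa.write(f">{t.locus_id}/read2 {span}\n{t.read2_seq}\n")
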