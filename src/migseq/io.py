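"""File I/O: FASTA/FASTQ/BED/TSV/VCF plumbing.

FASTA parsing goes through Biopython; FASTQ records are kept as a minimal
dataclass because the simulator and preprocessor shuttle millions of short
reads and only need id/seq/qual.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

PHRED_OFFSET = 33


@dataclass
class FastqRead:
    id: str
    seq: str
    qual: str  # phred+33 string

    def quals(self) -> list:
        return [ord(c) - PHRED_OFFSET for c in self.qual]


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict:
    """FASTA -> {id: uppercase sequence}."""
    with _open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict, path) -> None:
    with _open(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fastq(path) -> Iterator[FastqRead]:
    with _open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()  # '+'
            qual = fh.readline().rstrip("\n")
            yield FastqRead(header.rstrip("\n")[1:], seq, qual)


def write_fastq(reads: Iterable[FastqRead], path) -> None:
    with _open(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def read_barcode_map(path) -> dict:
    """Two-column TSV (sample, barcode) -> {barcode: sample}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "barcode"],
                     dtype=str, comment="#")
    dup = df["barcode"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate barcodes in map: {sorted(df['barcode'][dup])}")
    return dict(zip(df["barcode"], df["sample"]))


def write_barcode_map(barcodes: dict, path) -> None:
    """{sample: barcode} -> two-column TSV."""
    with open(path, "w") as fh:
        for sample, bc in barcodes.items():
            fh.write(f"{sample}\t{bc}\n")


def write_vcf(gm, path, reference_name: str = "catalog") -> None:
    """Minimal VCF 4.2 export: CHROM = locus id, POS = 1-based SNP offset."""
    from .matrix import parse_genotype

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference_name}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = gm.samples
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for sid in gm.site_ids:
            locus = gm.sites.loc[sid, "locus_id"]
            pos = int(gm.sites.loc[sid, "pos"])
            alleles = gm.alleles_at(sid)
            cons = gm.consensus.get(locus)
            ref = cons[pos] if cons and pos < len(cons) else (alleles[0] if alleles else "N")
            alts = [a for a in alleles if a != ref] or ["."]
            index = {ref: 0, **{a: i + 1 for i, a in enumerate(alts) if a != "."}}
            row = [locus, str(pos + 1), sid, ref, ",".join(alts), ".", "PASS", ".", "GT"]
            for s in samples:
                parsed = parse_genotype(gm.calls.at[s, sid])
                if parsed is None:
                    row.append("./." if gm.ploidy[s] == 2 else ".")
                else:
                    row.append("/".join(str(index.get(a, ".")) for a in parsed))
            fh.write("\t".join(row) + "\n")
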