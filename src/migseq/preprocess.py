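"""Read pretreatment: demultiplex, trim, quality-filter, adapter screen.

Reproduces the documented semantics of the published pipeline's pretreatment
chain: exact-match index demultiplexing, removal of the first 14 bases of
read 2 (the 12-base SSR core plus 2-base anchor carried over from the 1st-PCR
primer), a keep-if-at-least-p%-of-bases->=q quality filter (q=30, p=40), and
removal of reads containing the opposite sequencing-primer sequence (the
signature of a read-through on an extremely short insert).  Reads 1 and 2 are
deliberately kept unpaired downstream: forward-reverse and reverse-forward
amplification of the same fragment would otherwise split one locus into two.

Quality strings are Phred+33.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

from . import constants as C
from .io import FastqRead, PHRED_OFFSET


@dataclass
class PreprocessConfig:
    q_threshold: int = 30
    p_percent: float = 40.0
    trim_read2_bases: int = C.READ2_TRIM
    adapter_read1: str = C.ADAPTER_QUERY_READ1
    adapter_read2: str = C.ADAPTER_QUERY_READ2
    adapter_max_mismatch: int = 0
    phred_offset: int = PHRED_OFFSET

    def __post_init__(self):
        if not 0 < self.p_percent <= 100:
            raise ValueError("p_percent must be in (0, 100]")


@dataclass
class ReadRecord:
    """A read with sample assignment and filter provenance."""

    sample_id: str
    mate: str  # "read1" | "read2"
    seq: str
    qual: str
    read_id: str = ""
    trimmed: bool = False
    filtered_reason: Optional[str] = None

    @property
    def kept(self) -> bool:
        return self.filtered_reason is None


class BarcodeCollisionError(ValueError):
    pass


def demultiplex(read1: Iterable[FastqRead], read2: Iterable[FastqRead],
                index_reads: Iterable[FastqRead], barcode_map: dict):
    """Assign read pairs to samples by exact index match.

    ``barcode_map`` maps barcode -> sample id.  Returns (groups, counts) where
    groups is {sample: [(read1, read2), ...]} including an ``undetermined``
    bin, and counts is a per-group tally.  Conservation holds: assigned plus
    undetermined equals the input pair count.
    """
    barcodes = list(barcode_map)
    if len(set(barcodes)) != len(barcodes):
        raise BarcodeCollisionError("duplicate barcodes in map")
    if any(len(b) != C.INDEX_LEN for b in barcodes):
        raise ValueError("barcodes must be six bases")
    groups = {sample: [] for sample in barcode_map.values()}
    groups["undetermined"] = []
    counts = {k: 0 for k in groups}
    for r1, r2, idx in zip(read1, read2, index_reads):
        sample = barcode_map.get(idx.seq, "undetermined")
        groups[sample].append((r1, r2))
        counts[sample] += 1
    return groups, counts


def trim_read2(record: ReadRecord, config: PreprocessConfig = None) -> ReadRecord:
    """Remove the primer-derived first bases of a read-2 record (seq and qual
    in lockstep)."""
    config = config or PreprocessConfig()
    n = config.trim_read2_bases
    if record.mate != "read2":
        raise ValueError("trim_read2 applies to read-2 records only")
    if len(record.seq) < n + 1:
        return replace(record, filtered_reason="too_short_to_trim")
    return replace(record, seq=record.seq[n:], qual=record.qual[n:], trimmed=True)


def quality_filter(record: ReadRecord, config: PreprocessConfig = None) -> bool:
    """Keep iff at least p_percent % of bases have quality >= q_threshold."""
    config = config or PreprocessConfig()
    quals = [ord(c) - config.phred_offset for c in record.qual]
    if not quals:
        return False
    good = sum(q >= config.q_threshold for q in quals)
    return 100.0 * good / len(quals) >= config.p_percent


def _fuzzy_contains(hay: str, needle: str, max_mismatch: int) -> bool:
    if max_mismatch == 0:
        return needle in hay
    n = len(needle)
    for i in range(len(hay) - n + 1):
        mm = 0
        for a, b in zip(hay[i : i + n], needle):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            return True
    return False


def remove_adapter_reads(record: ReadRecord, config: PreprocessConfig = None) -> bool:
    """Keep iff the mate-appropriate sequencing-primer query is absent.

    The read-2 primer region is searched in read 1 and the read-1 primer
    region in (trimmed) read 2; a hit marks a read-through into the adapter on
    a short insert.
    """
    config = config or PreprocessConfig()
    query = config.adapter_read1 if record.mate == "read1" else config.adapter_read2
    return not _fuzzy_contains(record.seq, query, config.adapter_max_mismatch)


def preprocess_reads(records: Iterable[ReadRecord],
                     config: PreprocessConfig = None):
    """Run trim -> quality filter -> adapter screen over a record stream.

    Returns (survivors, report) where report is a DataFrame counting drop
    reasons per (sample, mate); survivors + drops = input count.
    """
    config = config or PreprocessConfig()
    survivors = []
    tally: dict = {}

    def count(sample, mate, reason):
        key = (sample, mate, reason)
        tally[key] = tally.get(key, 0) + 1

    for rec in records:
        if rec.mate == "read2" and not rec.trimmed:
            rec = trim_read2(rec, config)
            if rec.filtered_reason:
                count(rec.sample_id, rec.mate, rec.filtered_reason)
                continue
        if not quality_filter(rec, config):
            count(rec.sample_id, rec.mate, "low_quality")
            continue
        if not remove_adapter_reads(rec, config):
            count(rec.sample_id, rec.mate, "adapter")
            continue
        count(rec.sample_id, rec.mate, "kept")
        survivors.append(rec)
    report = pd.DataFrame(
        [(s, m, r, n) for (s, m, r), n in sorted(tally.items())],
        columns=["sample_id", "mate", "reason", "count"])
    return survivors, report


def sample_reads_to_records(sample_reads) -> list:
    """Flatten a simulator SampleReads bundle into untrimmed ReadRecords."""
    out = []
    for r in sample_reads.read1:
        out.append(ReadRecord(sample_reads.sample_id, "read1", r.seq, r.qual,
                              read_id=r.id))
    for r in sample_reads.read2:
        out.append(ReadRecord(sample_reads.sample_id, "read2", r.seq, r.qual,
                              read_id=r.id))
    return out
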