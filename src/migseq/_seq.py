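"""Low-level DNA string helpers shared across the package."""
from __future__ import annotations

import numpy as np

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT(N) string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def is_dna(seq: str) -> bool:
    return bool(seq) and all(c in "ACGT" for c in seq)


def require_dna(seq: str, what: str = "sequence") -> str:
    """Validate an uppercase ACGT string; ambiguity codes are rejected."""
    if not is_dna(seq):
        raise ValueError(f"{what} must be a non-empty uppercase ACGT string, got {seq!r}")
    return seq


# byte-level encoding: A,C,G,T -> 0..3, anything else -> 255 (never matches)
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(DNA):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 vector (non-ACGT become 255)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_matrix(seqs) -> np.ndarray:
    """Stack equal-length sequences into an (N, L) uint8 matrix."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    return np.vstack([encode(s) for s in seqs])


def pairwise_hamming(enc: np.ndarray, chunk: int = 512) -> np.ndarray:
    """All-pairs Hamming distances of an encoded (N, L) matrix."""
    n = enc.shape[0]
    out = np.empty((n, n), dtype=np.int32)
    for i in range(0, n, chunk):
        block = enc[i : i + chunk]
        out[i : i + chunk] = (block[:, None, :] != enc[None, :, :]).sum(axis=2)
    return out
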