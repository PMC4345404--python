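"""Nucleotide encoding helpers shared by the aligners and generators.

Bases are coded A=0, C=1, G=2, T=3, N=4.  Code 4 never matches anything,
which implements the "N counts as a mismatch" rule everywhere.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

# complement of a code; N stays N
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-complements)."""
    return seq.translate(_RC_TABLE)[::-1]


def kmer_value(codes: np.ndarray) -> int:
    """Pack a code array (no N) into an integer, first base most significant."""
    v = 0
    for c in codes:
        v = (v << 2) | int(c)
    return v
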