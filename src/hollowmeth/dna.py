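"""Base-level sequence utilities shared by the simulator, aligner and callers.

Sequences are handled in two forms: plain upper-case strings at the API
surface, and uint8 code arrays (A=0, C=1, G=2, T=3, N=4) everywhere speed
matters. All coordinates are 0-based half-open internally.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4

_CODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement of each code; N maps to N
_COMP = np.array([T, G, C, A, N], dtype=np.uint8)

PHRED_OFFSET = 33


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 code array."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an upper-case string."""
    return _BASES[codes].tobytes().decode("ascii")


def complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis (works on read batches)."""
    return _COMP[codes][..., ::-1]


def gc_fraction(codes: np.ndarray) -> float:
    acgt = np.count_nonzero(codes < 4)
    if acgt == 0:
        return 0.0
    return float(np.count_nonzero((codes == C) | (codes == G)) / acgt)


def ct_transform(codes: np.ndarray) -> np.ndarray:
    """Bisulfite three-letter view of the plus strand: every C becomes T."""
    return np.where(codes == C, np.uint8(T), codes)


def ga_transform(codes: np.ndarray) -> np.ndarray:
    """Three-letter view for minus-strand chemistry: every G becomes A."""
    return np.where(codes == G, np.uint8(A), codes)


def quals_to_ascii(quals: np.ndarray) -> str:
    return (quals.astype(np.uint8) + PHRED_OFFSET).tobytes().decode("ascii")


def ascii_to_quals(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8) - PHRED_OFFSET
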