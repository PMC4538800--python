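"""Small shared helpers for RNA sequence handling.

All sequences in this package are RNA strings over {A, C, G, U}; reads may
additionally contain N. DNA input (T) is converted to U at the I/O boundary.
"""

from __future__ import annotations

import numpy as np

from .exceptions import AlphabetError

RNA_ALPHABET = frozenset("ACGU")
READ_ALPHABET = frozenset("ACGUN")

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

# Integer encoding used by the numba kernels. N -> 4 (never matches).
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGUN"):
    _ENCODE[ord(_b)] = _i


def validate_rna(seq: str, *, allow_n: bool = False) -> str:
    """Return *seq* unchanged if it is a valid RNA string, else raise."""
    if not seq:
        raise AlphabetError("empty sequence")
    allowed = READ_ALPHABET if allow_n else RNA_ALPHABET
    bad = set(seq) - allowed
    if bad:
        raise AlphabetError(
            f"invalid character(s) {sorted(bad)} in sequence (allowed: {sorted(allowed)})"
        )
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


def encode(seq: str) -> np.ndarray:
    """Encode an RNA string as int8 codes (A=0, C=1, G=2, U=3, N=4)."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        raise AlphabetError(f"cannot encode sequence {seq!r}")
    return np.ascontiguousarray(arr)


def decode(codes: np.ndarray) -> str:
    return "".join("ACGUN"[c] for c in codes)
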