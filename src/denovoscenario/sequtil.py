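"""Small nucleotide-sequence helpers shared across the pipeline.

Sequences are plain upper-case strings over {A,C,G,T,N}; the numeric
encoding used by the alignment kernels maps A,C,G,T -> 0..3 and anything
else (N, gap) -> 4.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
GAP = "-"

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes (A,C,G,T -> 0..3; other -> 4)."""
    return _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    lookup = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return bytes(lookup[codes]).decode("ascii")


def revcomp(seq: str) -> str:
    return "".join(_COMP.get(c, "N") for c in reversed(seq.upper()))


def gc_fraction(seq: str) -> float:
    """G+C fraction of a sequence; N bases are excluded from the denominator."""
    s = seq.upper()
    n = sum(1 for c in s if c in "ACGT")
    if n == 0:
        raise ValueError("sequence has no unambiguous bases")
    return sum(1 for c in s if c in "GC") / n


def degap(seq: str) -> str:
    return seq.replace(GAP, "")
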