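"""Shared nucleotide encoding helpers: string <-> uint8 codes, complements.

Codes: A=0, C=1, G=2, T=3, N=4.  Everything else must be cleaned to N first
(see :func:`aninull.formats.clean_sequence`).
"""

from __future__ import annotations

import numpy as np

BASES = b"ACGTN"
N_CODE = 4

_ENCODE_LUT = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE_LUT[_b] = _i
    _ENCODE_LUT[_b + 32] = _i  # lowercase

_DECODE_LUT = np.frombuffer(BASES, dtype=np.uint8)

# complement of codes 0..4 (N -> N)
COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_REVCOMP_TABLE = bytes.maketrans(b"ACGTNacgtn", b"TGCANTGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back into an uppercase nucleotide string."""
    return _DECODE_LUT[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-complements)."""
    return seq.translate(_REVCOMP_TABLE)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMPLEMENT[codes][::-1]
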