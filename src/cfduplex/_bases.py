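"""Nucleotide and barcode encodings shared across the package.

Bases are stored as uint8 codes: A=0, C=1, G=2, T=3; code 4 is the mask
value (an ``N`` / no-call).  Strand barcodes are 7-mers over {A,C,G,T}
stored as integers in ``[0, 4**7)`` (base-4 digit expansion).
"""
from __future__ import annotations

import numpy as np

BASES = "ACGTN"
MASK = 4
BARCODE_LEN = 7
N_BARCODES = 4**BARCODE_LEN  # 16,384 possible heptamers

_CHAR_TO_CODE = np.full(256, MASK, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CHAR_TO_CODE[ord(_c)] = _i
    _CHAR_TO_CODE[ord(_c.lower())] = _i

_CODE_TO_CHAR = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/N string as uint8 codes."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CHAR_TO_CODE[raw]


def decode_seq(codes: np.ndarray) -> str:
    """Decode uint8 base codes back to a string (mask renders as N)."""
    return _CODE_TO_CHAR[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def barcode_to_str(code: int) -> str:
    """Render an integer barcode as its heptamer sequence."""
    if not 0 <= code < N_BARCODES:
        raise ValueError(f"barcode code out of range: {code}")
    digits = []
    for _ in range(BARCODE_LEN):
        digits.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(digits))


def barcode_from_str(s: str) -> int:
    """Parse a heptamer barcode string to its integer code."""
    if len(s) != BARCODE_LEN:
        raise ValueError(f"barcode must be a {BARCODE_LEN}-mer, got {s!r}")
    code = 0
    for c in s:
        code = code * 4 + "ACGT".index(c.upper())
    return code


def random_reference(length: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random reference sequence as base codes."""
    return rng.integers(0, 4, size=length, dtype=np.uint8)
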