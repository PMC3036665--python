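"""IUPAC nucleotide codes as 4-bit masks (A=1, C=2, G=4, T=8).

A code's mask has a bit set for every base it may represent; gaps and '?'
carry the full mask (any base).  Bitmasks let Fitch parsimony and partial
likelihood vectors share one encoding.
"""

from __future__ import annotations

import numpy as np

A, C, G, T = 1, 2, 4, 8

CODE_TO_MASK: dict[str, int] = {
    "A": A, "C": C, "G": G, "T": T, "U": T,
    "R": A | G, "Y": C | T, "S": C | G, "W": A | T,
    "K": G | T, "M": A | C,
    "B": C | G | T, "D": A | G | T, "H": A | C | T, "V": A | C | G,
    "N": A | C | G | T, "-": A | C | G | T, "?": A | C | G | T,
}

#: masks of the four unambiguous bases
BASE_MASKS = (A, C, G, T)
BASES = "ACGT"

_LUT = np.full(256, 255, dtype=np.uint8)
for _ch, _m in CODE_TO_MASK.items():
    _LUT[ord(_ch)] = _m
    _LUT[ord(_ch.lower())] = _m


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string to a uint8 mask vector.

    Raises ValueError naming the first offending column (1-based) if a
    symbol is not an IUPAC nucleotide code.
    """
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    masks = _LUT[raw]
    bad = np.nonzero(masks == 255)[0]
    if bad.size:
        col = int(bad[0])
        raise ValueError(f"non-IUPAC symbol {seq[col]!r} at column {col + 1}")
    return masks


def base_index(masks: np.ndarray) -> np.ndarray:
    """Map unambiguous masks to indices 0..3 (A,C,G,T); others to -1."""
    out = np.full(masks.shape, -1, dtype=np.int8)
    for i, m in enumerate(BASE_MASKS):
        out[masks == m] = i
    return out


def is_unambiguous(masks: np.ndarray) -> np.ndarray:
    return (masks == A) | (masks == C) | (masks == G) | (masks == T)
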