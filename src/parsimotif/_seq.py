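"""Low-level DNA alphabet helpers shared across the package.

The alphabet is fixed to {A, C, G, T}, encoded as integers 0..3.  Reverse
complementation in code space is ``3 - x`` on the reversed array.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
A, C, G, T = range(4)

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _ch in enumerate(ALPHABET):
    _ENCODE[ord(_ch)] = _i
    _ENCODE[ord(_ch.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as an int8 array; raises on ambiguous symbols."""
    codes = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = seq[int(np.argmax(codes < 0))]
        raise ValueError(f"non-ACGT symbol {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def is_unambiguous(seq: str) -> bool:
    """True iff the string is non-empty and contains only A/C/G/T (any case)."""
    if not seq:
        return False
    codes = _ENCODE[np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)]
    return bool((codes >= 0).all())


def context_index(codes_2d: np.ndarray) -> np.ndarray:
    """Flatten context words to integers, nearest predecessor most significant.

    ``codes_2d`` has one row per word; column j holds the (j+1)-th preceding
    symbol.  The returned index matches C-order raveling of a count tensor
    whose axes are ordered (layer 1, layer 2, ..., layer d).
    """
    d = codes_2d.shape[1]
    if d == 0:
        return np.zeros(codes_2d.shape[0], dtype=np.int64)
    powers = 4 ** np.arange(d - 1, -1, -1, dtype=np.int64)
    return codes_2d.astype(np.int64) @ powers
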