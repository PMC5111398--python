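"""Internal base-level sequence encoding shared by the simulator and mapper.

Bases are encoded A=0, C=1, G=2, T=3, N=4.  ``N`` is never considered equal
to anything, including another ``N``.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 vector (A=0..T=3, N=4)."""
    arr = _ENCODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted(set(seq) - set(BASES + BASES.lower()))
        raise ValueError(f"invalid bases {bad}")
    return arr


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode()


def revcomp(arr: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis; N maps to N."""
    comp = np.where(arr < 4, 3 - arr, arr).astype(np.uint8)
    return comp[..., ::-1]


def mismatch_count(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance where any N counts as a mismatch."""
    return int(np.count_nonzero((a != b) | (a > 3) | (b > 3)))
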