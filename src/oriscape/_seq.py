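"""Low-level DNA encoding helpers shared across modules.

Bases are encoded A=0, C=1, G=2, T=3 so that complementation is ``3 - code``.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
A, C, G, T = 0, 1, 2, 3

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes; non-ACGT bases become 255."""
    return _ENCODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    if np.any(codes > 3):
        raise ValueError("cannot decode codes outside {0,1,2,3}")
    return _DECODE[codes].tobytes().decode()


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = (3 - codes[::-1]).astype(np.uint8)
    out[codes[::-1] > 3] = 255
    return out


def is_pyrimidine(base: str) -> bool:
    return base.upper() in ("C", "T")


def gc_fraction(codes: np.ndarray) -> float:
    valid = codes <= 3
    n = int(valid.sum())
    if n == 0:
        return float("nan")
    gc = int(np.count_nonzero((codes == C) | (codes == G)))
    return gc / n
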