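"""Small nucleotide-sequence utilities (DNA alphabet internally, U mapped to T)."""

from __future__ import annotations

import numpy as np

from .errors import ParameterError

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# integer codes for vectorised comparison; 255 is a padding sentinel that never matches
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i

A, C, G, T = 0, 1, 2, 3


def normalize(seq: str) -> str:
    """Uppercase and map U->T. Raises on characters outside {A,C,G,T,U}."""
    s = seq.upper().replace("U", "T")
    if not s or any(b not in ALPHABET for b in set(s)):
        bad = sorted(set(s) - set(ALPHABET)) if s else []
        raise ParameterError(f"sequence must be non-empty over ACGTU, got invalid {bad!r}")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 code array (A=0, C=1, G=2, T=3)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)
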