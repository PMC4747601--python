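"""Small DNA sequence helpers used throughout the package.

Sequences travel as plain upper-case strings at module boundaries and as
uint8 code arrays (A=0, C=1, G=2, T=3) inside numeric kernels.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (non-ACGT bases become 255)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back to an ACGT string (255 -> 'N')."""
    out = np.where(codes < 4, _DECODE[np.minimum(codes, 3)], ord("N"))
    return out.astype(np.uint8).tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_RC_TABLE)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a uint8 code array (255 stays 255)."""
    out = np.where(codes < 4, 3 - codes, codes)
    return out[::-1]


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform i.i.d. random DNA string of the given length."""
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))
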