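"""Nucleotide encoding helpers shared across modules.

Sequences are handled as uppercase strings over {A,C,G,T,N} at module
boundaries and as uint8 code arrays (A=0, C=1, G=2, T=3, N=4) internally.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = np.uint8(4)

# ASCII byte -> code lookup (everything unknown collapses to N=4)
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement in code space; N stays N
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into a uint8 code array (non-ACGT -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into an uppercase DNA string."""
    return _DEC[codes].tobytes().decode("ascii")


def normalize(seq: str) -> str:
    """Uppercase and map every non-ACGT character to N."""
    return decode(encode(seq))


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))
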