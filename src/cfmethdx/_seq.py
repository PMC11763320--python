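"""Byte-level sequence helpers shared by the simulator and the caller."""

from __future__ import annotations

import numpy as np

A, C, G, T, N, Y = (ord(b) for b in "ACGTNY")
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# complement lookup (unknown bytes map to N)
COMP = np.full(256, N, dtype=np.uint8)
for x, y in ((A, T), (T, A), (C, G), (G, C), (N, N)):
    COMP[x] = y

# base -> index 0..3 (non-ACGT -> 4)
BASE_INDEX = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(BASES):
    BASE_INDEX[b] = i


def encode(seq: str) -> np.ndarray:
    """ASCII sequence -> uint8 array (copy, writable)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp(arr: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis."""
    return COMP[arr][..., ::-1]


def phred33(qualities: np.ndarray) -> str:
    return (np.asarray(qualities, dtype=np.uint8) + 33).tobytes().decode("ascii")


def qual_from_string(qstr: str) -> np.ndarray:
    return np.frombuffer(qstr.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
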