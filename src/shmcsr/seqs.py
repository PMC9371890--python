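"""Small nucleotide-string utilities shared across the package."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC ambiguity sets used by the hotspot motifs.
W = frozenset("AT")
R = frozenset("AG")
Y = frozenset("CT")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_u8(seq: str) -> np.ndarray:
    """View a base string as a uint8 array (ASCII codes) for vector ops."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def from_u8(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def random_bases(rng: np.random.Generator, length: int, gc_fraction: float = 0.5) -> str:
    """Random sequence with the requested G+C fraction in expectation."""
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return "".join(BASES[i] for i in idx)
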