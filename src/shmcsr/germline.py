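"""Germline V-region model: region annotation and hotspot site classification.

Every position of the germline is assigned exactly one mutation subtype:

* ``GC_AID_HOT`` — a C whose trinucleotide context matches WRC, or a G whose
  context matches GYW (the reverse-complement motif). These are the canonical
  AID deamination hotspots.
* ``GC_OTHER``   — any other G or C.
* ``AT_POL_HOT`` — an A preceded by W (the WA motif) or a T followed by W
  (TW), the error-prone polymerase eta hotspots targeted during
  non-canonical mismatch repair of the AID lesion.
* ``AT_OTHER``   — any other A or T.

IUPAC codes: W = {A,T}, R = {A,G}, Y = {C,T}. Context positions that fall
outside the sequence never match, so terminal bases default to the _OTHER
subtype of their pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError
from .seqs import BASES, R, W, Y, random_bases

GC_AID_HOT = "GC_AID_HOT"
GC_OTHER = "GC_OTHER"
AT_POL_HOT = "AT_POL_HOT"
AT_OTHER = "AT_OTHER"

#: Canonical subtype ordering used in every table and report.
SUBTYPES = (GC_AID_HOT, GC_OTHER, AT_POL_HOT, AT_OTHER)

#: Region label of the clone-identity tag interval (stands in for CDR3).
CDR3_LABEL = "CDR3"


def classify_site(sequence: str, position: int) -> str:
    """Return the mutation subtype of ``position`` in ``sequence``.

    The motif is evaluated on the germline top strand; GYW is the
    reverse-complement image of WRC and TW of WA, so strand symmetry holds
    by construction.
    """
    if not 0 <= position < len(sequence):
        raise IndexError(f"position {position} outside sequence of length {len(sequence)}")
    base = sequence[position]
    if base == "C":
        # WRC: trinucleotide ending at this C.
        if position >= 2 and sequence[position - 2] in W and sequence[position - 1] in R:
            return GC_AID_HOT
        return GC_OTHER
    if base == "G":
        # GYW: trinucleotide starting at this G.
        if position + 2 < len(sequence) and sequence[position + 1] in Y and sequence[position + 2] in W:
            return GC_AID_HOT
        return GC_OTHER
    if base == "A":
        return AT_POL_HOT if position >= 1 and sequence[position - 1] in W else AT_OTHER
    if base == "T":
        return AT_POL_HOT if position + 1 < len(sequence) and sequence[position + 1] in W else AT_OTHER
    raise ValueError(f"cannot classify base {base!r} at position {position}")


def build_subtype_mask(sequence: str) -> tuple[str, ...]:
    """Per-position subtype labels for a germline sequence."""
    return tuple(classify_site(sequence, i) for i in range(len(sequence)))


@dataclass(frozen=True)
class Region:
    """A labeled germline interval, 0-based half-open."""

    label: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GermlineReference:
    """An annotated germline V-region sequence.

    ``subtype_mask`` is derived from the sequence at construction; callers
    never supply it.
    """

    name: str
    sequence: str
    regions: tuple[Region, ...]
    subtype_mask: tuple[str, ...] = field(default=())

    def __post_init__(self):
        _validate_regions(self.regions, len(self.sequence))
        if not self.subtype_mask:
            object.__setattr__(self, "subtype_mask", build_subtype_mask(self.sequence))
        if len(self.subtype_mask) != len(self.sequence):
            raise ConfigurationError("subtype mask length differs from sequence length")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cdr3_region(self) -> Region | None:
        for r in self.regions:
            if r.label == CDR3_LABEL:
                return r
        return None

    def region_of(self, position: int) -> str:
        for r in self.regions:
            if r.start <= position < r.end:
                return r.label
        return "."

    def mask_array(self) -> np.ndarray:
        """Subtype index per position (index into SUBTYPES)."""
        lut = {s: i for i, s in enumerate(SUBTYPES)}
        return np.array([lut[s] for s in self.subtype_mask], dtype=np.int8)

    def position_filter(self, region_filter: Iterable[str] | None = None) -> np.ndarray:
        """Boolean mask of positions included in spectrum analyses.

        ``None`` selects every position outside the CDR3 tag interval (the
        tag is synthetic clone identity, not biology). Otherwise only
        positions whose region label is in ``region_filter`` are selected.
        """
        keep = np.zeros(len(self.sequence), dtype=bool)
        if region_filter is None:
            keep[:] = True
            cdr3 = self.cdr3_region
            if cdr3 is not None:
                keep[cdr3.start:cdr3.end] = False
        else:
            labels = set(region_filter)
            if not labels:
                raise ConfigurationError("region_filter must not be empty")
            for r in self.regions:
                if r.label in labels:
                    keep[r.start:r.end] = True
        return keep


def _validate_regions(regions: Sequence[Region], length: int) -> None:
    problems = []
    prev_end = None
    for r in regions:
        if not (0 <= r.start < r.end <= length):
            problems.append(f"region {r.label} [{r.start},{r.end}) outside [0,{length})")
            continue
        if prev_end is not None and r.start < prev_end:
            problems.append(f"region {r.label} overlaps or is out of order")
        prev_end = r.end
    if problems:
        raise ConfigurationError(problems)


def default_vh_regions(length: int, cdr3_len: int = 15) -> tuple[Region, ...]:
    """Framework/CDR layout for a synthetic VH of the given length.

    For the 294-base default (the span of the murine VH186.2 V region) the
    boundaries approximate the usual FR1-CDR1-FR2-CDR2-FR3 layout; the final
    ``cdr3_len`` bases are reserved as the clone-identity tag interval. Other
    lengths get a single V region plus the tag interval.
    """
    if cdr3_len >= length:
        raise ConfigurationError("cdr3_len must be smaller than germline length")
    if length == 294 and cdr3_len == 15:
        bounds = [("FR1", 0, 75), ("CDR1", 75, 99), ("FR2", 99, 150),
                  ("CDR2", 150, 174), ("FR3", 174, 279), (CDR3_LABEL, 279, 294)]
    else:
        bounds = [("V", 0, length - cdr3_len), (CDR3_LABEL, length - cdr3_len, length)]
    return tuple(Region(lbl, s, e) for lbl, s, e in bounds)


def make_germline(length: int = 294, gc_fraction: float = 0.5,
                  region_bounds: Sequence[Region] | None = None,
                  seed: int = 17, name: str = "synthetic_vh") -> GermlineReference:
    """Generate a random germline reference with region annotations.

    ``length`` defaults to 294 bases, the span of the V region the analysis
    was designed around. ``gc_fraction`` is the expected G+C content.
    """
    if length < 30:
        raise ConfigurationError("germline length must be >= 30")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ConfigurationError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    seq = random_bases(rng, length, gc_fraction)
    regions = tuple(region_bounds) if region_bounds is not None else default_vh_regions(length)
    return GermlineReference(name=name, sequence=seq, regions=regions)
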