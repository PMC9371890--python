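"""Paired-read assembly and UMI consensus collapse.

Read pairs are merged by scanning every suffix(read1)/prefix(revcomp read2)
overlap of at least ``min_overlap`` bases and keeping the overlap with the
fewest mismatches (longest overlap on ties). Merged reads are then grouped
by their leading unique molecular identifier (UMI) and collapsed to one
consensus sequence per molecule by per-position majority vote; a tie votes
``N``, which downstream mutation calling ignores so a sequencing tie can
never fabricate a mutation.

No UMI error correction is performed: collapse is by exact UMI identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import RecordRejected
from .seqs import from_u8, revcomp, to_u8


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read with per-base Phred+33 quality strings."""

    id: str
    r1_seq: str
    r2_seq: str
    r1_qual: str
    r2_qual: str

    def __post_init__(self):
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(self.r2_qual):
            raise RecordRejected("qual_length_mismatch", self.id)


@dataclass(frozen=True)
class ConsensusSequence:
    """Majority consensus of one UMI family."""

    umi: str
    sequence: str
    family_size: int


def merge_pair(pair: ReadPair, min_overlap: int = 10, max_mismatch_frac: float = 0.1) -> str:
    """Merge a read pair into one fragment via its best suffix-prefix overlap.

    Read 2 is reverse-complemented, all overlaps >= ``min_overlap`` are
    scored, and the overlap with the fewest mismatches wins (longest on
    ties). At disagreeing overlap positions the base with the higher quality
    is kept; quality ties keep the read-1 base.

    Raises
    ------
    RecordRejected
        If no overlap meets ``min_overlap`` or the best overlap's mismatch
        fraction exceeds ``max_mismatch_frac``.
    """
    r1, q1 = pair.r1_seq, pair.r1_qual
    r2 = revcomp(pair.r2_seq)
    q2 = pair.r2_qual[::-1]
    l1, l2 = len(r1), len(r2)
    a1, a2 = to_u8(r1), to_u8(r2)

    best_mm, best_o = None, None
    for o in range(min(l1, l2), min_overlap - 1, -1):
        mm = int(np.count_nonzero(a1[l1 - o:] != a2[:o]))
        if best_mm is None or mm < best_mm:
            best_mm, best_o = mm, o
            if mm == 0:
                break
    if best_o is None:
        raise RecordRejected("no_admissible_overlap", pair.id)
    if best_mm / best_o > max_mismatch_frac:
        raise RecordRejected("overlap_mismatch_excess", pair.id)

    o = best_o
    head = r1[: l1 - o]
    tail = r2[o:]
    if best_mm == 0:
        return head + r1[l1 - o:] + tail
    overlap = []
    for i in range(o):
        b1, b2 = r1[l1 - o + i], r2[i]
        if b1 == b2:
            overlap.append(b1)
        else:
            overlap.append(b1 if q1[l1 - o + i] >= q2[i] else b2)
    return head + "".join(overlap) + tail


def extract_umi(merged: str, umi_length: int = 8) -> tuple[str, str]:
    """Split the leading UMI from a merged fragment."""
    if umi_length < 4:
        raise RecordRejected("umi_too_short_config", f"umi_length={umi_length}")
    if len(merged) <= umi_length:
        raise RecordRejected("merged_shorter_than_umi")
    return merged[:umi_length], merged[umi_length:]


def collapse_families(records: Iterable[tuple[str, str]], min_family_size: int = 1,
                      rejects: list | None = None) -> list[ConsensusSequence]:
    """Collapse (umi, insert) records into per-UMI majority consensuses.

    Families whose inserts differ in length are rejected (logged into
    ``rejects`` as ``(umi, reason)`` when provided), as are families smaller
    than ``min_family_size``. Output is sorted by UMI for determinism.
    """
    families: dict[str, list[str]] = {}
    for umi, insert in records:
        families.setdefault(umi, []).append(insert)

    out = []
    for umi in sorted(families):
        inserts = families[umi]
        if len({len(s) for s in inserts}) != 1:
            if rejects is not None:
                rejects.append((umi, "unequal_insert_lengths"))
            continue
        if len(inserts) < min_family_size:
            if rejects is not None:
                rejects.append((umi, "family_too_small"))
            continue
        out.append(ConsensusSequence(umi=umi, sequence=_majority(inserts), family_size=len(inserts)))
    return out


def _majority(inserts: Sequence[str]) -> str:
    if len(inserts) == 1:
        return inserts[0]
    mat = np.stack([to_u8(s) for s in inserts])
    codes = to_u8("ACGT")
    counts = np.stack([(mat == c).sum(axis=0) for c in codes])  # (4, L)
    top = counts.max(axis=0)
    ties = (counts == top).sum(axis=0) > 1
    cons = codes[counts.argmax(axis=0)]
    cons[ties | (top == 0)] = ord("N")
    return from_u8(cons.astype(np.uint8))


def process_read_pairs(pairs: Iterable[ReadPair], umi_length: int = 8, min_overlap: int = 10,
                       max_mismatch_frac: float = 0.1, min_family_size: int = 1
                       ) -> tuple[list[ConsensusSequence], list[tuple[str, str]]]:
    """Merge, split UMIs, and collapse; returns (consensuses, rejection log)."""
    rejects: list[tuple[str, str]] = []
    records = []
    for pair in pairs:
        try:
            merged = merge_pair(pair, min_overlap=min_overlap, max_mismatch_frac=max_mismatch_frac)
            records.append(extract_umi(merged, umi_length))
        except RecordRejected as exc:
            rejects.append((pair.id, exc.reason))
    consensuses = collapse_families(records, min_family_size=min_family_size, rejects=rejects)
    return consensuses, rejects
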