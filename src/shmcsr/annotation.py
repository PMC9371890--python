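"""Alignment of consensus VH sequences to germline, mutation calling,
CDR3 extraction and clonal grouping.

Calling is strictly positional and substitution-only: consensus sequences
must match the germline length (length-changing differences reject the
record), every A/C/G/T mismatch outside the CDR3 tag interval becomes a
point mutation annotated with the germline site's subtype and region, and
consensus ``N`` positions are skipped so a sequencing tie never yields a
call. Clones are defined by exact CDR3 nucleotide identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import RecordRejected
from .germline import GermlineReference
from .seqs import to_u8
from .umi_consensus import ConsensusSequence

_ACGT = frozenset(b"ACGT")


@dataclass(frozen=True)
class Mutation:
    """A called point mutation in 0-based germline coordinates."""

    position: int
    from_base: str
    to_base: str
    subtype: str
    region: str


@dataclass
class AnnotatedSequence:
    id: str
    mutations: tuple[Mutation, ...]
    cdr3: str
    clone_id: str = ""
    family_size: int = 1


def align_and_call(consensus: ConsensusSequence | str, germline: GermlineReference,
                   max_mismatch_frac: float = 0.2, seq_id: str | None = None) -> AnnotatedSequence:
    """Call point mutations by positional comparison against the germline.

    Raises :class:`RecordRejected` on length mismatch or when the mismatch
    fraction over compared (non-N, non-CDR3) positions exceeds
    ``max_mismatch_frac`` (treated as a misassembly).
    """
    if isinstance(consensus, ConsensusSequence):
        seq, sid, fam = consensus.sequence, consensus.umi, consensus.family_size
    else:
        seq, sid, fam = consensus, seq_id or "seq", 1
    if seq_id is not None:
        sid = seq_id
    if len(seq) != len(germline):
        raise RecordRejected("length_mismatch", sid)

    cdr3 = germline.cdr3_region
    a_cons = to_u8(seq)
    a_germ = to_u8(germline.sequence)
    compare = np.ones(len(seq), dtype=bool)
    if cdr3 is not None:
        compare[cdr3.start:cdr3.end] = False
    valid = np.isin(a_cons, np.frombuffer(b"ACGT", dtype=np.uint8))
    compared = compare & valid
    diff = compared & (a_cons != a_germ)

    n_compared = int(compared.sum())
    n_diff = int(diff.sum())
    if n_compared == 0 or n_diff / n_compared > max_mismatch_frac:
        raise RecordRejected("mismatch_excess", sid)

    muts = tuple(Mutation(position=int(p), from_base=germline.sequence[p], to_base=seq[p],
                          subtype=germline.subtype_mask[p], region=germline.region_of(int(p)))
                 for p in np.flatnonzero(diff))
    cdr3_seq = seq[cdr3.start:cdr3.end] if cdr3 is not None else ""
    return AnnotatedSequence(id=sid, mutations=muts, cdr3=cdr3_seq, family_size=fam)


def group_clones(annotated: Sequence[AnnotatedSequence]
                 ) -> tuple[list[AnnotatedSequence], list[tuple[str, str]]]:
    """Assign clone ids by exact CDR3 nucleotide identity.

    Clone ids are stable under input order: distinct CDR3 strings are sorted
    lexicographically and numbered. Sequences with an empty CDR3 are
    rejected. Returns (kept sequences with ``clone_id`` set, rejection log).
    """
    rejects: list[tuple[str, str]] = []
    kept = []
    for a in annotated:
        if not a.cdr3:
            rejects.append((a.id, "empty_cdr3"))
        else:
            kept.append(a)
    ids = {cdr3: f"clone{i:05d}" for i, cdr3 in enumerate(sorted({a.cdr3 for a in kept}))}
    for a in kept:
        a.clone_id = ids[a.cdr3]
    return kept, rejects


def annotate_all(consensuses: Sequence[ConsensusSequence], germline: GermlineReference,
                 max_mismatch_frac: float = 0.2
                 ) -> tuple[list[AnnotatedSequence], list[tuple[str, str]]]:
    """align_and_call + group_clones over a batch; returns (kept, rejects)."""
    rejects: list[tuple[str, str]] = []
    annotated = []
    for cons in consensuses:
        try:
            annotated.append(align_and_call(cons, germline, max_mismatch_frac))
        except RecordRejected as exc:
            rejects.append((exc.detail or "?", exc.reason))
    kept, clone_rejects = group_clones(annotated)
    rejects.extend(clone_rejects)
    return kept, rejects
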