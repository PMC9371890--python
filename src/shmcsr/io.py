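"""Readers and writers for the pipeline's on-disk formats.

FASTA/FASTQ go through Biopython's SeqIO; tabular outputs are TSV with
header lines (written via pandas for deterministic formatting).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import AnnotatedSequence
from .errors import ConfigurationError
from .germline import CDR3_LABEL, GermlineReference, Region
from .junctions import JunctionCohort, SwitchJunction
from .umi_consensus import ConsensusSequence, ReadPair


def write_fasta(path, records: Iterable[tuple[str, str]], descriptions=None) -> None:
    descriptions = descriptions or {}
    recs = [SeqRecord(Seq(seq), id=rid, description=descriptions.get(rid, ""))
            for rid, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str, str]]:
    """[(id, sequence, description), ...]"""
    return [(r.id, str(r.seq), r.description) for r in SeqIO.parse(str(path), "fasta")]


def write_fastq_pairs(r1_path, r2_path, pairs: Iterable[ReadPair]) -> None:
    r1, r2 = [], []
    for p in pairs:
        r1.append(_fastq_record(p.id, p.r1_seq, p.r1_qual))
        r2.append(_fastq_record(p.id, p.r2_seq, p.r2_qual))
    SeqIO.write(r1, str(r1_path), "fastq")
    SeqIO.write(r2, str(r2_path), "fastq")


def _fastq_record(rid: str, seq: str, qual: str) -> SeqRecord:
    rec = SeqRecord(Seq(seq), id=rid, description="")
    rec.letter_annotations["phred_quality"] = [ord(q) - 33 for q in qual]
    return rec


def read_fastq_pairs(r1_path, r2_path) -> list[ReadPair]:
    r1 = list(SeqIO.parse(str(r1_path), "fastq"))
    r2 = list(SeqIO.parse(str(r2_path), "fastq"))
    if len(r1) != len(r2):
        raise ConfigurationError("R1 and R2 FASTQ files differ in record count")
    pairs = []
    for a, b in zip(r1, r2):
        if a.id != b.id:
            raise ConfigurationError(f"unpaired records: {a.id} vs {b.id}")
        pairs.append(ReadPair(
            id=a.id, r1_seq=str(a.seq), r2_seq=str(b.seq),
            r1_qual="".join(chr(q + 33) for q in a.letter_annotations["phred_quality"]),
            r2_qual="".join(chr(q + 33) for q in b.letter_annotations["phred_quality"])))
    return pairs


def write_germline(fasta_path, regions_path, germline: GermlineReference) -> None:
    write_fasta(fasta_path, [(germline.name, germline.sequence)])
    pd.DataFrame([{"name": germline.name, "start": r.start, "end": r.end, "label": r.label}
                  for r in germline.regions]).to_csv(regions_path, sep="\t", index=False)


def read_germline(fasta_path, regions_path) -> GermlineReference:
    records = read_fasta(fasta_path)
    if len(records) != 1:
        raise ConfigurationError("germline FASTA must contain exactly one record")
    name, seq, _ = records[0]
    tab = pd.read_csv(regions_path, sep="\t")
    regions = tuple(Region(row["label"], int(row["start"]), int(row["end"]))
                    for _, row in tab.iterrows())
    return GermlineReference(name=name, sequence=seq, regions=regions)


def write_consensus_fasta(path, consensuses: Sequence[ConsensusSequence]) -> None:
    recs = [(c.umi, c.sequence) for c in consensuses]
    desc = {c.umi: f"family_size={c.family_size}" for c in consensuses}
    write_fasta(path, recs, desc)


def read_consensus_fasta(path) -> list[ConsensusSequence]:
    out = []
    for rid, seq, desc in read_fasta(path):
        fam = 1
        for token in desc.split():
            if token.startswith("family_size="):
                fam = int(token.split("=", 1)[1])
        out.append(ConsensusSequence(umi=rid, sequence=seq, family_size=fam))
    return out


def write_rejects(path, rejects: Sequence[tuple[str, str]]) -> None:
    pd.DataFrame(rejects, columns=["record", "reason"]).to_csv(path, sep="\t", index=False)


def write_annotation(path, annotated: Sequence[AnnotatedSequence]) -> None:
    """One row per mutation; positions are reported 1-based inclusive."""
    rows = []
    for a in annotated:
        for m in a.mutations:
            rows.append({"sequence_id": a.id, "clone_id": a.clone_id,
                         "position": m.position + 1, "from_base": m.from_base,
                         "to_base": m.to_base, "subtype": m.subtype, "region": m.region})
    pd.DataFrame(rows, columns=["sequence_id", "clone_id", "position", "from_base",
                                "to_base", "subtype", "region"]).to_csv(path, sep="\t", index=False)


def write_clone_table(path, annotated: Sequence[AnnotatedSequence]) -> None:
    rows: dict[str, dict] = {}
    for a in annotated:
        entry = rows.setdefault(a.clone_id, {"clone_id": a.clone_id, "cdr3": a.cdr3, "size": 0,
                                             "members": []})
        entry["size"] += 1
        entry["members"].append(a.id)
    frame = pd.DataFrame([{**v, "members": ",".join(v["members"])}
                          for v in rows.values()]).sort_values("clone_id")
    frame.to_csv(path, sep="\t", index=False)


def read_annotated(annotation_path, clone_table_path) -> list[AnnotatedSequence]:
    """Rebuild AnnotatedSequence objects from the annotation + clone TSVs."""
    from .annotation import Mutation

    clones = pd.read_csv(clone_table_path, sep="\t")
    ann = pd.read_csv(annotation_path, sep="\t")
    by_seq: dict[str, list] = {}
    for _, row in ann.iterrows():
        by_seq.setdefault(row["sequence_id"], []).append(Mutation(
            position=int(row["position"]) - 1, from_base=row["from_base"],
            to_base=row["to_base"], subtype=row["subtype"], region=row["region"]))
    out = []
    for _, row in clones.iterrows():
        for sid in str(row["members"]).split(","):
            muts = tuple(sorted(by_seq.get(sid, []), key=lambda m: m.position))
            out.append(AnnotatedSequence(id=sid, mutations=muts, cdr3=row["cdr3"],
                                         clone_id=row["clone_id"]))
    return out


def write_junction_table(path, cohorts: Sequence[JunctionCohort]) -> None:
    rows = []
    for c in cohorts:
        for j in c.junctions:
            rows.append({"genotype": c.genotype, "id": j.id, "resolved": j.resolved,
                         "score": j.score if j.resolved else "",
                         "kind": j.kind, "donor_break": j.donor_break,
                         "acceptor_break": j.acceptor_break, "prefix_len": j.prefix_len,
                         "suffix_len": j.suffix_len, "insert": j.insert})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
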