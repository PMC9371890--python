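"""Synthetic data generator for the whole pipeline, with recorded ground truth.

The generator emulates the statistical structure the downstream analyses
assume:

* clonally structured VH repertoires — each clone carries a private CDR3
  identity tag, a founder ("inherited") mutation set shared by every member,
  and per-sequence private mutations, all drawn from per-subtype per-site
  rates (AID hotspot / other G:C, Pol-eta hotspot / other A:T);
* UMI-tagged paired reads with i.i.d. substitution sequencing error;
* switch junctions built from a donor (S-mu-like) prefix and acceptor
  (S-gamma3-like) suffix joined bluntly, through a k-base microhomology, or
  through m untemplated inserted bases (truth labels 0, +k, -m);
* per-animal class-switch fractions as binomial draws.

All randomness flows from one explicit integer seed through a named
``numpy.random.Generator``; the default seed is 17.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .germline import (AT_OTHER, AT_POL_HOT, GC_AID_HOT, GC_OTHER, SUBTYPES,
                       GermlineReference)
from .seqs import BASES, random_bases, revcomp
from .umi_consensus import ReadPair

DEFAULT_SEED = 17


def _uniform_bias() -> dict[str, dict[str, float]]:
    bias = {}
    for src in BASES:
        others = [b for b in BASES if b != src]
        row = {b: (1.0 / 3.0 if b in others else 0.0) for b in BASES}
        bias[src] = row
    return bias


@dataclass(frozen=True)
class GenotypeProfile:
    """Per-site per-sequence mutation rates for the four site subtypes.

    ``substitution_bias[src][dst]`` is the probability that a mutation at a
    ``src`` base lands on ``dst``; rows sum to 1 with 0 on the diagonal.
    """

    name: str
    mu_gc_hot: float
    mu_gc_other: float
    mu_at_hot: float
    mu_at_other: float
    substitution_bias: Mapping[str, Mapping[str, float]] = field(default_factory=_uniform_bias)

    def __post_init__(self):
        problems = []
        for label, p in (("mu_gc_hot", self.mu_gc_hot), ("mu_gc_other", self.mu_gc_other),
                         ("mu_at_hot", self.mu_at_hot), ("mu_at_other", self.mu_at_other)):
            if not 0.0 <= p <= 1.0:
                problems.append(f"{label}={p} outside [0,1]")
        for src in BASES:
            row = self.substitution_bias.get(src)
            if row is None:
                problems.append(f"substitution_bias missing row {src}")
                continue
            if abs(sum(row.get(b, 0.0) for b in BASES) - 1.0) > 1e-9:
                problems.append(f"substitution_bias[{src}] does not sum to 1")
            if row.get(src, 0.0) != 0.0:
                problems.append(f"substitution_bias[{src}][{src}] must be 0")
        if problems:
            raise ConfigurationError(problems)

    def rate(self, subtype: str) -> float:
        return {GC_AID_HOT: self.mu_gc_hot, GC_OTHER: self.mu_gc_other,
                AT_POL_HOT: self.mu_at_hot, AT_OTHER: self.mu_at_other}[subtype]


#: Preset profiles emulating the three study genotypes: a wild-type-like
#: spectrum with robust A:T / Pol-eta hotspot mutagenesis, and two
#: EXO1-compromised spectra (nuclease-dead-like and knockout-like) in which
#: A:T mutations collapse and G:C / AID-hotspot mutations rise.
PROFILES: dict[str, GenotypeProfile] = {
    "WT-like": GenotypeProfile("WT-like", mu_gc_hot=0.02, mu_gc_other=0.005,
                               mu_at_hot=0.015, mu_at_other=0.003),
    "DA-like": GenotypeProfile("DA-like", mu_gc_hot=0.030, mu_gc_other=0.008,
                               mu_at_hot=0.006, mu_at_other=0.0015),
    "KO-like": GenotypeProfile("KO-like", mu_gc_hot=0.032, mu_gc_other=0.009,
                               mu_at_hot=0.003, mu_at_other=0.001),
}


@dataclass(frozen=True)
class TruthMutation:
    position: int
    from_base: str
    to_base: str
    inherited: bool


@dataclass
class Molecule:
    id: str
    clone_id: str
    sequence: str


@dataclass
class SimulationTruth:
    """Hidden parameters and per-molecule records for recovery tests."""

    profile: GenotypeProfile
    n_clones: int
    clone_sizes: list[int]
    clone_of: dict[str, str]                       # molecule id -> clone id
    cdr3_of_clone: dict[str, str]
    mutations: dict[str, list[TruthMutation]]      # molecule id -> sorted mutations
    umi_of: dict[str, str] = field(default_factory=dict)  # molecule id -> UMI

    def clone_partition(self) -> set[frozenset[str]]:
        groups: dict[str, set[str]] = {}
        for mol, clone in self.clone_of.items():
            groups.setdefault(clone, set()).add(mol)
        return {frozenset(v) for v in groups.values()}


def _resolve_clone_sizes(clone_size_dist, n_clones: int, rng: np.random.Generator) -> list[int]:
    if isinstance(clone_size_dist, int):
        return [clone_size_dist] * n_clones
    if callable(clone_size_dist):
        return [max(1, int(clone_size_dist(rng))) for _ in range(n_clones)]
    if clone_size_dist == "geometric":
        return [int(s) for s in rng.geometric(0.5, size=n_clones)]
    sizes = [int(s) for s in clone_size_dist]
    if len(sizes) != n_clones:
        raise ConfigurationError("explicit clone_sizes length must equal n_clones")
    return sizes


def _draw_targets(rng: np.random.Generator, from_bases: Sequence[str],
                  bias: Mapping[str, Mapping[str, float]]) -> list[str]:
    out = []
    for src in from_bases:
        row = bias[src]
        probs = [row.get(b, 0.0) for b in BASES]
        out.append(BASES[rng.choice(4, p=probs)])
    return out


def simulate_repertoire(germline: GermlineReference, profile: GenotypeProfile,
                        n_clones: int, clone_size_dist="geometric",
                        inherited_fraction: float = 0.25,
                        seed: int = DEFAULT_SEED) -> tuple[list[Molecule], SimulationTruth]:
    """Simulate a clonally structured mutated VH repertoire.

    Each clone receives a distinct random CDR3 tag (written into the
    germline's CDR3 interval) and a founder mutation set drawn at
    ``inherited_fraction`` times the per-subtype rates, shared by every
    member. Each member adds private mutations at ``1 - inherited_fraction``
    times the rates, at sites not already mutated in the founder, so a site
    mutates at most once per molecule and the marginal per-site rate stays
    close to the configured rate.
    """
    if n_clones < 1:
        raise ConfigurationError("n_clones must be >= 1")
    if not 0.0 <= inherited_fraction <= 1.0:
        raise ConfigurationError("inherited_fraction must be in [0,1]")
    cdr3 = germline.cdr3_region
    if cdr3 is None:
        raise ConfigurationError("germline has no CDR3 tag interval")

    rng = np.random.default_rng(seed)
    L = len(germline)
    clone_sizes = _resolve_clone_sizes(clone_size_dist, n_clones, rng)

    # Per-position mutation rate vectors; the tag interval never mutates.
    pos_rates = np.array([profile.rate(s) for s in germline.subtype_mask])
    pos_rates[cdr3.start:cdr3.end] = 0.0

    founder = rng.random((n_clones, L)) < inherited_fraction * pos_rates

    tags: list[str] = []
    seen = set()
    while len(tags) < n_clones:
        tag = random_bases(rng, len(cdr3), 0.5)
        if tag not in seen:
            seen.add(tag)
            tags.append(tag)

    molecules: list[Molecule] = []
    clone_of: dict[str, str] = {}
    cdr3_of_clone: dict[str, str] = {}
    mutations: dict[str, list[TruthMutation]] = {}

    mol_idx = 0
    for c in range(n_clones):
        clone_id = f"trueclone{c:04d}"
        cdr3_of_clone[clone_id] = tags[c]
        f_pos = np.flatnonzero(founder[c])
        f_from = [germline.sequence[p] for p in f_pos]
        f_to = _draw_targets(rng, f_from, profile.substitution_bias)
        for _ in range(clone_sizes[c]):
            mol_id = f"mol{mol_idx:05d}"
            mol_idx += 1
            private = rng.random(L) < (1.0 - inherited_fraction) * pos_rates
            private[f_pos] = False
            p_pos = np.flatnonzero(private)
            p_from = [germline.sequence[p] for p in p_pos]
            p_to = _draw_targets(rng, p_from, profile.substitution_bias)

            muts = ([TruthMutation(int(p), fb, tb, True) for p, fb, tb in zip(f_pos, f_from, f_to)]
                    + [TruthMutation(int(p), fb, tb, False) for p, fb, tb in zip(p_pos, p_from, p_to)])
            muts.sort(key=lambda m: m.position)

            seq = list(germline.sequence)
            seq[cdr3.start:cdr3.end] = tags[c]
            for m in muts:
                seq[m.position] = m.to_base
            molecules.append(Molecule(id=mol_id, clone_id=clone_id, sequence="".join(seq)))
            clone_of[mol_id] = clone_id
            mutations[mol_id] = muts

    truth = SimulationTruth(profile=profile, n_clones=n_clones, clone_sizes=clone_sizes,
                            clone_of=clone_of, cdr3_of_clone=cdr3_of_clone, mutations=mutations)
    return molecules, truth


def simulate_reads(molecules: Sequence[Molecule], umi_length: int = 8,
                   reads_per_molecule: int = 3, error_rate: float = 0.001,
                   overlap: int = 60, seed: int = DEFAULT_SEED,
                   umi_errors: bool = False) -> tuple[list[ReadPair], dict[str, str]]:
    """Simulate UMI-tagged paired reads covering each molecule.

    The sequenced fragment is ``UMI + molecule``; read 1 is its prefix and
    read 2 the reverse complement of its suffix, with read length chosen so
    the mates overlap by ~``overlap`` bases. Substitution errors are
    injected i.i.d. at ``error_rate`` per sequenced base; qualities are a
    flat Phred+33 'I'. UMI bases are error-free unless ``umi_errors`` is
    set, since exact-identity collapse performs no UMI error correction.
    Returns the read pairs and the truth UMI->molecule map.
    """
    if umi_length < 4:
        raise ConfigurationError("umi_length must be >= 4")
    if reads_per_molecule < 1:
        raise ConfigurationError("reads_per_molecule must be >= 1")
    if not molecules:
        return [], {}
    min_frag = min(len(m.sequence) for m in molecules) + umi_length
    if overlap >= min_frag:
        raise ConfigurationError("requested overlap longer than molecule fragment")

    rng = np.random.default_rng(seed)
    umi_of: dict[str, str] = {}
    seen = set()
    for mol in molecules:
        while True:
            umi = random_bases(rng, umi_length, 0.5)
            if umi not in seen:
                seen.add(umi)
                umi_of[mol.id] = umi
                break

    def with_errors(seq: str, protect_prefix: int = 0) -> str:
        if error_rate <= 0:
            return seq
        hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
        hits = hits[hits >= protect_prefix]
        if hits.size == 0:
            return seq
        out = list(seq)
        for i in hits:
            alts = [b for b in BASES if b != out[i]]
            out[i] = alts[rng.integers(3)]
        return "".join(out)

    protect = 0 if umi_errors else umi_length
    pairs: list[ReadPair] = []
    for mol in molecules:
        frag = umi_of[mol.id] + mol.sequence
        read_len = (len(frag) + overlap + 1) // 2
        read_len = min(read_len, len(frag))
        r1_t = frag[:read_len]
        r2_t = revcomp(frag[len(frag) - read_len:])
        # read 2 only reaches back into the UMI when mates nearly span the
        # whole fragment; protect that suffix too so exact-UMI collapse holds
        r2_protect = 0 if umi_errors else max(0, umi_length - (len(frag) - read_len))
        qual = "I" * read_len
        for j in range(reads_per_molecule):
            r2 = with_errors(r2_t[::-1], r2_protect)[::-1] if r2_protect else with_errors(r2_t)
            pairs.append(ReadPair(id=f"{mol.id}/{j}", r1_seq=with_errors(r1_t, protect),
                                  r2_seq=r2, r1_qual=qual, r2_qual=qual))
    return pairs, umi_of


# ---------------------------------------------------------------------------
# Switch junctions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionMixture:
    """Mixture over junction resolution classes.

    ``mh_length_dist`` / ``ins_length_dist`` map positive lengths to
    probabilities (each summing to 1). ``p_blunt + p_mh + p_ins`` must be 1.
    """

    p_blunt: float
    p_mh: float
    p_ins: float
    mh_length_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.30, 2: 0.25, 3: 0.18, 4: 0.12, 5: 0.08, 6: 0.07})
    ins_length_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2})

    def __post_init__(self):
        problems = []
        if abs(self.p_blunt + self.p_mh + self.p_ins - 1.0) > 1e-9:
            problems.append("p_blunt + p_mh + p_ins must equal 1")
        for nm, dist in (("mh_length_dist", self.mh_length_dist), ("ins_length_dist", self.ins_length_dist)):
            if dist and abs(sum(dist.values()) - 1.0) > 1e-9:
                problems.append(f"{nm} must sum to 1")
            if any(int(k) < 1 for k in dist):
                problems.append(f"{nm} lengths must be positive")
        if problems:
            raise ConfigurationError(problems)

    def label_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """(values, probabilities) of the signed truth-label distribution."""
        vals, probs = [0], [self.p_blunt]
        for k, p in sorted(self.mh_length_dist.items()):
            vals.append(int(k))
            probs.append(self.p_mh * p)
        for m, p in sorted(self.ins_length_dist.items()):
            vals.append(-int(m))
            probs.append(self.p_ins * p)
        return np.array(vals), np.array(probs)


@dataclass(frozen=True)
class SimulatedJunction:
    id: str
    sequence: str
    label: int                 # 0 blunt, +k microhomology, -m insertion
    donor_break: int
    acceptor_break: int


def make_switch_references(donor_length: int = 400, acceptor_length: int = 400,
                           gc_fraction: float = 0.5, seed: int = DEFAULT_SEED) -> tuple[str, str]:
    """Random donor/acceptor reference pair standing in for Smu and Sgamma3."""
    rng = np.random.default_rng(seed)
    return random_bases(rng, donor_length, gc_fraction), random_bases(rng, acceptor_length, gc_fraction)


def _mh_site_pool(donor: str, acceptor: str, k: int, anchor_min: int) -> list[tuple[int, int]]:
    """All (donor_break, acceptor_break) pairs sharing a k-mer with
    non-extendable flanks, so the engineered microhomology is exactly k."""
    kmer_pos: dict[str, list[int]] = {}
    lo_a, hi_a = max(k + 1, 1), len(acceptor) - anchor_min
    for a in range(lo_a, hi_a + 1):
        kmer_pos.setdefault(acceptor[a - k:a], []).append(a)
    pool = []
    lo_d, hi_d = max(anchor_min, k + 1), len(donor) - 2
    for d in range(lo_d, hi_d + 1):
        for a in kmer_pos.get(donor[d - k:d], ()):
            if donor[d] != acceptor[a] and donor[d - k - 1] != acceptor[a - k - 1]:
                pool.append((d, a))
    return pool


def simulate_junctions(donor: str, acceptor: str, mixture: JunctionMixture, n: int,
                       seed: int = DEFAULT_SEED, anchor_min: int = 10
                       ) -> list[SimulatedJunction]:
    """Generate switch junctions with known signed truth labels.

    Blunt: ``donor[:d] + acceptor[a:]`` with the flanking bases chosen so no
    accidental 1-base microhomology appears. Microhomology +k: breakpoints
    are drawn from positions where donor and acceptor naturally share an
    exact k-mer whose flanks differ (written once in the junction).
    Insertion -m: m untemplated bases whose boundary bases match neither
    reference continuation. If no admissible k-mer site exists for a drawn
    microhomology length, the length is decremented until one does.
    """
    if len(donor) < 40 or len(acceptor) < 40:
        raise ConfigurationError("donor and acceptor must each be >= 40 bases")
    rng = np.random.default_rng(seed)
    kinds = rng.choice(3, size=n, p=[mixture.p_blunt, mixture.p_mh, mixture.p_ins])

    mh_lengths = sorted(mixture.mh_length_dist)
    mh_probs = [mixture.mh_length_dist[k] for k in mh_lengths]
    ins_lengths = sorted(mixture.ins_length_dist)
    ins_probs = [mixture.ins_length_dist[m] for m in ins_lengths]
    pools: dict[int, list[tuple[int, int]]] = {}

    def draw_breaks() -> tuple[int, int]:
        d = int(rng.integers(anchor_min, len(donor) - 1))
        a = int(rng.integers(1, len(acceptor) - anchor_min + 1))
        return d, a

    out: list[SimulatedJunction] = []
    for i, kind in enumerate(kinds):
        if kind == 0:  # blunt
            while True:
                d, a = draw_breaks()
                if donor[d] != acceptor[a] and donor[d - 1] != acceptor[a - 1]:
                    break
            seq, label = donor[:d] + acceptor[a:], 0
        elif kind == 1:  # microhomology
            k = int(mh_lengths[rng.choice(len(mh_lengths), p=mh_probs)])
            while k >= 1:
                if k not in pools:
                    pools[k] = _mh_site_pool(donor, acceptor, k, anchor_min)
                if pools[k]:
                    break
                k -= 1
            if k < 1:
                raise ConfigurationError("no admissible microhomology site in references")
            d, a = pools[k][rng.integers(len(pools[k]))]
            seq, label = donor[:d] + acceptor[a:], k
        else:  # insertion
            m = int(ins_lengths[rng.choice(len(ins_lengths), p=ins_probs)])
            while True:
                d, a = draw_breaks()
                if donor[d - 1] == acceptor[a - 1] or donor[d] == acceptor[a]:
                    continue  # keep the flanks unambiguous
                ins = random_bases(rng, m, 0.5)
                if ins[0] == donor[d]:
                    continue
                if ins[-1] == acceptor[a - 1]:
                    continue
                break
            seq, label = donor[:d] + ins + acceptor[a:], -m
        out.append(SimulatedJunction(id=f"jx{i:04d}", sequence=seq, label=int(label),
                                     donor_break=d, acceptor_break=a))
    return out


def simulate_csr_counts(p_switch: float, n_cells: int, n_animals: int,
                        seed: int = DEFAULT_SEED) -> np.ndarray:
    """Per-animal switched-cell fractions: Binomial(n_cells, p_switch)/n_cells."""
    if not 0.0 <= p_switch <= 1.0:
        raise ConfigurationError("p_switch must be in [0,1]")
    rng = np.random.default_rng(seed)
    return rng.binomial(n_cells, p_switch, size=n_animals) / n_cells
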