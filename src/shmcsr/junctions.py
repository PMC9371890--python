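"""Switch-junction microhomology/insertion scoring and cohort statistics.

Each junction is decomposed exactly against the donor (S-mu) and acceptor
(S-gamma3) references: the longest junction prefix occurring contiguously in
the donor and the longest suffix occurring in the acceptor. If prefix and
suffix overlap by k bases in the junction the join used a k-base
microhomology (score +k, written once); if they abut it is blunt (score 0);
if g junction bases lie between them they are untemplated insertion (score
-g). Ties prefer maximal microhomology, then minimal insertion, then the
leftmost donor breakpoint. Junctions whose prefix or suffix anchor is
shorter than ``anchor_min`` are reported unresolved and excluded from the
distributions.

Cohort statistics: tie-corrected Kruskal-Wallis on the signed scores with
Dunn's pairwise post tests (exact permutation p for small pooled samples),
Fisher's exact test on insertion frequencies, and relative class-switch
efficiencies normalized so the reference-group mean is 100%.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError


@dataclass(frozen=True)
class SwitchJunction:
    """A scored junction. ``score`` is 0 (blunt), +k (microhomology) or -m
    (insertion); unresolved junctions carry ``resolved=False`` and no score."""

    id: str
    sequence: str
    score: int
    donor_break: int
    acceptor_break: int
    prefix_len: int
    suffix_len: int
    insert: str
    resolved: bool = True

    @property
    def kind(self) -> str:
        if not self.resolved:
            return "unresolved"
        if self.score > 0:
            return "microhomology"
        return "blunt" if self.score == 0 else "insertion"


@dataclass
class JunctionCohort:
    genotype: str
    junctions: list[SwitchJunction]

    @property
    def resolved(self) -> list[SwitchJunction]:
        return [j for j in self.junctions if j.resolved]

    @property
    def scores(self) -> np.ndarray:
        return np.array([j.score for j in self.resolved], dtype=int)

    @property
    def insertion_count(self) -> int:
        return int(np.sum(self.scores < 0))

    @property
    def total_count(self) -> int:
        return len(self.resolved)


def _longest_prefix_in(text: str, query: str) -> int:
    """Length of the longest prefix of ``query`` occurring in ``text``."""
    lo = 0
    hi = min(len(query), len(text))
    # monotone: query[:p] in text implies query[:p-1] in text
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if query[:mid] in text:
            lo = mid
        else:
            hi = mid - 1
    return lo


def score_junction(junction: str, donor: str, acceptor: str, anchor_min: int = 10,
                   junction_id: str = "junction") -> SwitchJunction:
    """Score one junction sequence against the donor/acceptor references."""
    if len(junction) < 20:
        raise ConfigurationError("junction must be >= 20 bases")
    L = len(junction)
    P = _longest_prefix_in(donor, junction)
    rev = junction[::-1]
    S = _longest_prefix_in(acceptor[::-1], rev)  # longest suffix of junction in acceptor

    if P < anchor_min or S < anchor_min:
        return SwitchJunction(id=junction_id, sequence=junction, score=0, donor_break=-1,
                              acceptor_break=-1, prefix_len=P, suffix_len=S, insert="",
                              resolved=False)

    donor_break = donor.index(junction[:P]) + P          # leftmost occurrence, end coordinate
    acceptor_break = acceptor.index(junction[L - S:])    # leftmost occurrence, start coordinate
    k = P + S - L
    if k >= 0:
        return SwitchJunction(id=junction_id, sequence=junction, score=k,
                              donor_break=donor_break, acceptor_break=acceptor_break,
                              prefix_len=P, suffix_len=S, insert="")
    insert = junction[P:L - S]
    return SwitchJunction(id=junction_id, sequence=junction, score=-len(insert),
                          donor_break=donor_break, acceptor_break=acceptor_break,
                          prefix_len=P, suffix_len=S, insert=insert)


def score_cohort(genotype: str, junction_seqs: Sequence[tuple[str, str]], donor: str,
                 acceptor: str, anchor_min: int = 10) -> JunctionCohort:
    """Score a list of (id, sequence) junctions into a cohort."""
    return JunctionCohort(genotype=genotype, junctions=[
        score_junction(seq, donor, acceptor, anchor_min=anchor_min, junction_id=jid)
        for jid, seq in junction_seqs])


def insertion_frequency(cohort: JunctionCohort) -> float:
    """Fraction of resolved junctions carrying an untemplated insertion."""
    if cohort.total_count < 1:
        raise ConfigurationError("cohort has no resolved junctions")
    return cohort.insertion_count / cohort.total_count


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _as_score_arrays(cohorts) -> tuple[list[str], list[np.ndarray]]:
    names, arrays = [], []
    for i, c in enumerate(cohorts):
        if isinstance(c, JunctionCohort):
            names.append(c.genotype)
            arrays.append(np.asarray(c.scores, dtype=float))
        else:
            names.append(f"group{i}")
            arrays.append(np.asarray(c, dtype=float))
    return names, arrays


def _kw_h(rank_sums: np.ndarray, sizes: np.ndarray, N: int, tie_term: float) -> float:
    h = 12.0 / (N * (N + 1)) * np.sum(rank_sums ** 2 / sizes) - 3.0 * (N + 1)
    correction = 1.0 - tie_term / (N ** 3 - N)
    if correction <= 0:
        return 0.0
    return h / correction


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts ** 3 - counts))


def _exact_kruskal_p(arrays: list[np.ndarray]) -> tuple[float, float]:
    """Exact permutation Kruskal-Wallis p by enumerating group assignments."""
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = np.array([a.size for a in arrays])
    tie = _tie_term(pooled)
    bounds = np.cumsum(sizes)
    obs_sums = np.array([ranks[(0 if i == 0 else bounds[i - 1]):bounds[i]].sum()
                         for i in range(len(arrays))])
    h_obs = _kw_h(obs_sums, sizes, N, tie)

    idx = list(range(N))
    count = total = 0

    def recurse(remaining: list[int], gi: int, sums: list[float]):
        nonlocal count, total
        if gi == len(sizes) - 1:
            s = sums + [ranks[remaining].sum()]
            total += 1
            if _kw_h(np.array(s), sizes, N, tie) >= h_obs - 1e-12:
                count += 1
            return
        for combo in itertools.combinations(range(len(remaining)), int(sizes[gi])):
            chosen = [remaining[i] for i in combo]
            rest = [remaining[i] for i in range(len(remaining)) if i not in set(combo)]
            recurse(rest, gi + 1, sums + [ranks[chosen].sum()])

    recurse(idx, 0, [])
    return h_obs, count / total


def compare_mh_distributions(cohorts: Sequence, method: str = "auto",
                             p_adjust: str | None = None) -> dict:
    """Kruskal-Wallis across cohorts of signed junction scores, with Dunn's
    pairwise post tests.

    ``method`` is ``"auto"`` (exact permutation when the pooled sample has
    <= 12 observations, chi-square approximation otherwise), ``"exact"`` or
    ``"asymptotic"``. ``p_adjust`` (e.g. ``"bonferroni"``) adjusts the Dunn
    pairwise p-values; default is unadjusted.
    """
    names, arrays = _as_score_arrays(cohorts)
    if len(arrays) < 2:
        raise ConfigurationError("need at least 2 cohorts")
    for nm, a in zip(names, arrays):
        if a.size < 2:
            raise ConfigurationError(f"cohort {nm} has fewer than 2 junctions")
    pooled = np.concatenate(arrays)
    N = pooled.size

    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
        method_used = "degenerate"
    else:
        if method == "auto":
            method = "exact" if N <= 12 else "asymptotic"
        if method == "exact":
            h, p = _exact_kruskal_p(arrays)
            method_used = "exact_permutation"
        else:
            h, p = stats.kruskal(*arrays)
            h, p = float(h), float(p)
            method_used = "chi2_approx"

    dunn = _dunn_posthoc(names, arrays, p_adjust)
    return {"H": float(h), "p": float(p), "method": method_used, "dunn": dunn}


def _dunn_posthoc(names: list[str], arrays: list[np.ndarray],
                  p_adjust: str | None) -> pd.DataFrame:
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    bounds = np.cumsum([a.size for a in arrays])
    mean_ranks, sizes = [], []
    start = 0
    for b in bounds:
        mean_ranks.append(ranks[start:b].mean())
        sizes.append(b - start)
        start = b
    tie = _tie_term(pooled)
    base_var = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1))

    rows = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": names[i], "group_b": names[j], "z": z, "pvalue": p})
    frame = pd.DataFrame(rows)
    if p_adjust and not frame.empty:
        frame["p_adjusted"] = multipletests(frame["pvalue"], method=p_adjust)[1]
    else:
        frame["p_adjusted"] = frame["pvalue"] if not frame.empty else []
    return frame


def compare_insertion_frequencies(cohort_a: JunctionCohort, cohort_b: JunctionCohort
                                  ) -> tuple[float, float]:
    """Two-sided Fisher exact test on insertion counts; returns (p, odds ratio).

    The odds ratio is the conditional maximum-likelihood estimate. A zero
    table margin yields p = 1 by convention.
    """
    table = np.array([[cohort_a.insertion_count, cohort_a.total_count - cohort_a.insertion_count],
                      [cohort_b.insertion_count, cohort_b.total_count - cohort_b.insertion_count]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    try:
        oratio = float(stats.contingency.odds_ratio(table, kind="conditional").statistic)
    except Exception:
        oratio = float("nan")
    return float(p), oratio


def relative_csr_efficiency(sample_fractions: Sequence[float],
                            reference_fractions: Sequence[float]) -> np.ndarray:
    """Per-animal switching normalized so the reference-group mean is 100%."""
    ref = np.asarray(reference_fractions, dtype=float)
    if ref.size == 0 or ref.mean() <= 0:
        raise ConfigurationError("reference group must be non-empty with mean > 0")
    return 100.0 * np.asarray(sample_fractions, dtype=float) / ref.mean()


def proportion_percent(k: int, n: int) -> int:
    """``round(100*k/n)`` to the nearest integer, halves away from zero."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if not 0 <= k <= n:
        raise ConfigurationError("require 0 <= k <= n")
    return int(math.floor(100.0 * k / n + 0.5))
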