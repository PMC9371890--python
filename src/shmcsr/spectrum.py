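"""Clonal-resampling somatic-hypermutation spectrum analysis.

The repertoire is resampled for ``n_iterations`` rounds; each round draws
one sequence uniformly at random from every CDR3 clone, so mutations
inherited within a clonal lineage are counted once per round instead of
once per member. Within a round, mutations are tallied per site subtype and
normalized to the potential maximum of that subtype,

    f_s = N_s / (S_s * n_seq),

where ``S_s`` is the number of eligible germline sites of subtype ``s`` in
the analyzed region and ``n_seq`` the number of sampled sequences (= number
of clones). Because each site mutates at most once per molecule, every
``f_s`` lies in [0, 1]; the denominator corrects for base composition, so
frequencies are comparable across the G:C/A:T hotspot/non-hotspot classes.

Positional profiles accumulate, per germline position, the number of
(iteration x sampled sequence) events carrying a mutation there, then
rescale within each subtype to a maximum of 1.

Genotype contrasts build, per subtype, a 2x2 table of rounded mean mutated
site-opportunities against unmutated opportunities and apply Pearson's
chi-squared test with the Yates continuity correction
(``max(|O-E|-0.5, 0)`` per cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotatedSequence
from .errors import ConfigurationError
from .germline import SUBTYPES, GermlineReference


@dataclass(frozen=True)
class SpectrumConfig:
    n_iterations: int = 1000
    seed: int = 17
    region_filter: tuple[str, ...] | None = None  # None = all non-CDR3 positions
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0,1)")


@dataclass
class SpectrumResult:
    subtypes: tuple[str, ...]
    per_iteration: np.ndarray          # (n_iterations, 4), NaN for empty subtypes
    mean: dict[str, float]
    sd: dict[str, float]
    ci: dict[str, tuple[float, float]]  # 2.5-97.5 percentile over iterations
    site_counts: dict[str, int]
    n_seq: int
    n_iterations: int
    seed: int
    positional_profile: pd.DataFrame   # columns: position (1-based), subtype, value

    def spectrum_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subtypes:
            lo, hi = self.ci[s]
            rows.append({"subtype": s, "mean": self.mean[s], "sd": self.sd[s],
                         "ci_low": lo, "ci_high": hi, "eligible_sites": self.site_counts[s],
                         "n_seq": self.n_seq, "n_iterations": self.n_iterations})
        return pd.DataFrame(rows)


def eligible_site_counts(germline: GermlineReference,
                         region_filter: Iterable[str] | None = None) -> dict[str, int]:
    """Number of analyzed germline positions per subtype (the S_s)."""
    keep = germline.position_filter(region_filter)
    counts = {s: 0 for s in SUBTYPES}
    for pos in np.flatnonzero(keep):
        counts[germline.subtype_mask[pos]] += 1
    return counts


def resample_iteration(clones: Sequence[Sequence[int]], rng: np.random.Generator) -> list[int]:
    """One uniformly chosen member index per clone."""
    return [clone[rng.integers(len(clone))] for clone in clones]


def _clone_members(annotated: Sequence[AnnotatedSequence]) -> list[np.ndarray]:
    groups: dict[str, list[int]] = {}
    for i, a in enumerate(annotated):
        if not a.clone_id:
            raise ConfigurationError(f"sequence {a.id} has no clone_id; run group_clones first")
        groups.setdefault(a.clone_id, []).append(i)
    return [np.array(groups[c], dtype=np.intp) for c in sorted(groups)]


def _mutation_arrays(annotated: Sequence[AnnotatedSequence], germline: GermlineReference,
                     keep: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(per-seq per-subtype counts (n,4), per-seq per-position indicator (n,L))
    restricted to the filtered positions."""
    n, L = len(annotated), len(germline)
    sub_idx = {s: i for i, s in enumerate(SUBTYPES)}
    counts = np.zeros((n, 4), dtype=np.int64)
    indic = np.zeros((n, L), dtype=np.int64)
    for i, a in enumerate(annotated):
        for m in a.mutations:
            if keep[m.position]:
                counts[i, sub_idx[m.subtype]] += 1
                indic[i, m.position] = 1
    return counts, indic


def iteration_frequencies(sampled: Sequence[AnnotatedSequence], germline: GermlineReference,
                          region_filter: Iterable[str] | None = None) -> dict[str, float]:
    """Composition-normalized frequencies f_s for one sampled sequence set."""
    if not sampled:
        raise ConfigurationError("sampled set must be non-empty")
    keep = germline.position_filter(region_filter)
    S = eligible_site_counts(germline, region_filter)
    counts, _ = _mutation_arrays(sampled, germline, keep)
    totals = counts.sum(axis=0)
    out = {}
    for i, s in enumerate(SUBTYPES):
        out[s] = float(totals[i] / (S[s] * len(sampled))) if S[s] > 0 else float("nan")
    return out


def aggregate(annotated: Sequence[AnnotatedSequence], germline: GermlineReference,
              config: SpectrumConfig = SpectrumConfig()) -> SpectrumResult:
    """Run the full resampling analysis and aggregate over iterations."""
    clones = _clone_members(annotated)
    n_clones = len(clones)
    keep = germline.position_filter(config.region_filter)
    S = eligible_site_counts(germline, config.region_filter)
    counts, indic = _mutation_arrays(annotated, germline, keep)

    rng = np.random.default_rng(config.seed)
    n_iter = config.n_iterations
    # (n_iter, n_clones) member indices into the annotated list.
    sel = np.empty((n_iter, n_clones), dtype=np.intp)
    for j, members in enumerate(clones):
        sel[:, j] = members[rng.integers(0, len(members), size=n_iter)]

    per_sub_totals = counts[sel].sum(axis=1)  # (n_iter, 4)
    denom = np.array([S[s] * n_clones if S[s] > 0 else -1 for s in SUBTYPES], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = np.where(denom > 0, per_sub_totals / denom, np.nan)

    times_chosen = np.bincount(sel.ravel(), minlength=len(annotated))
    pos_counts = times_chosen @ indic  # (L,)

    mask_idx = germline.mask_array()
    rows = []
    for si, s in enumerate(SUBTYPES):
        sel_pos = np.flatnonzero(keep & (mask_idx == si))
        if sel_pos.size == 0:
            continue
        peak = pos_counts[sel_pos].max()
        vals = pos_counts[sel_pos] / peak if peak > 0 else np.zeros(sel_pos.size)
        for p, v in zip(sel_pos, vals):
            rows.append({"position": int(p) + 1, "subtype": s, "value": float(v)})
    profile = pd.DataFrame(rows, columns=["position", "subtype", "value"]).sort_values(
        ["position"], kind="stable").reset_index(drop=True)

    mean, sd, ci = {}, {}, {}
    for i, s in enumerate(SUBTYPES):
        col = freqs[:, i]
        if np.all(np.isnan(col)):
            mean[s], sd[s], ci[s] = float("nan"), float("nan"), (float("nan"), float("nan"))
        else:
            mean[s] = float(np.mean(col))
            if n_iter == 1 or np.all(col == col[0]):
                sd[s] = 0.0  # no resampling variance (e.g. all clones size 1)
            else:
                sd[s] = float(np.std(col, ddof=1))
            ci[s] = (float(np.percentile(col, 2.5)), float(np.percentile(col, 97.5)))

    return SpectrumResult(subtypes=SUBTYPES, per_iteration=freqs, mean=mean, sd=sd, ci=ci,
                          site_counts=S, n_seq=n_clones, n_iterations=n_iter,
                          seed=config.seed, positional_profile=profile)


def pooled_frequencies(annotated: Sequence[AnnotatedSequence], germline: GermlineReference,
                       region_filter: Iterable[str] | None = None) -> dict[str, float]:
    """Naive (non-resampled) frequencies counting every sequence once.

    This is the quantity the clonal resampling protects against: inherited
    mutations in large clones inflate it by roughly the clone size.
    """
    return iteration_frequencies(annotated, germline, region_filter)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def compare_genotypes(result_a: SpectrumResult, result_b: SpectrumResult,
                      pooled: bool = False) -> pd.DataFrame:
    """Yates-corrected chi-square contrasts between two spectra.

    Per subtype (default) or pooled over subtypes, builds the 2x2 table
    [[mutated_a, unmutated_a], [mutated_b, unmutated_b]] from rounded mean
    mutated site-opportunities and tests it with 1 df. Contrasts whose
    expected table contains a zero cell are flagged not computable.
    """
    if result_a.site_counts != result_b.site_counts:
        raise ConfigurationError("spectra computed on different germline/region filters")
    items = []
    specs = [("ALL", SUBTYPES)] if pooled else [(s, (s,)) for s in SUBTYPES]
    for label, members in specs:
        o_a = o_b = opp_a = opp_b = 0
        usable = True
        for s in members:
            if result_a.site_counts[s] == 0:
                continue
            opp_sa = result_a.site_counts[s] * result_a.n_seq
            opp_sb = result_b.site_counts[s] * result_b.n_seq
            if np.isnan(result_a.mean[s]) or np.isnan(result_b.mean[s]):
                usable = False
                break
            o_a += _round_half_up(result_a.mean[s] * opp_sa)
            o_b += _round_half_up(result_b.mean[s] * opp_sb)
            opp_a += opp_sa
            opp_b += opp_sb
        if not usable or opp_a == 0 or opp_b == 0:
            items.append({"contrast": label, "statistic": float("nan"), "pvalue": float("nan"),
                          "mutated_a": np.nan, "mutated_b": np.nan, "computable": False})
            continue
        table = np.array([[o_a, opp_a - o_a], [o_b, opp_b - o_b]])
        try:
            res = stats.chi2_contingency(table, correction=True)
            stat, p = float(res.statistic), float(res.pvalue)
            computable = True
        except ValueError:  # zero expected cell
            stat, p, computable = float("nan"), float("nan"), False
        items.append({"contrast": label, "statistic": stat, "pvalue": p,
                      "mutated_a": o_a, "mutated_b": o_b, "computable": computable})
    return pd.DataFrame(items)
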