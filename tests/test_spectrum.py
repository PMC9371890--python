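"""Clonal-resampling spectrum statistic: counts, normalization, contrasts."""

import numpy as np
import pytest

from shmcsr.annotation import AnnotatedSequence, Mutation
from shmcsr.germline import (AT_OTHER, AT_POL_HOT, GC_AID_HOT, GC_OTHER, SUBTYPES,
                             GermlineReference, Region)
from shmcsr.spectrum import (SpectrumConfig, SpectrumResult, aggregate, compare_genotypes,
                             eligible_site_counts, iteration_frequencies,
                             pooled_frequencies, resample_iteration)


def _seq(i, cdr3, muts=(), clone=""):
    return AnnotatedSequence(id=f"s{i}", mutations=tuple(muts), cdr3=cdr3, clone_id=clone)


def _mut(germline, position):
    return Mutation(position=position, from_base=germline.sequence[position],
                    to_base={"A": "G", "C": "T", "G": "A", "T": "C"}[germline.sequence[position]],
                    subtype=germline.subtype_mask[position],
                    region=germline.region_of(position))


def test_eligible_site_counts_toy(toy_germline):
    counts = eligible_site_counts(toy_germline)
    assert counts == {GC_AID_HOT: 2, GC_OTHER: 0, AT_POL_HOT: 1, AT_OTHER: 2}
    assert sum(counts.values()) == 5


def test_eligible_site_counts_partition(germline294):
    counts = eligible_site_counts(germline294)
    assert sum(counts.values()) == 294 - 15  # everything outside the CDR3 tag


def test_at_only_germline_gc_missing():
    g = GermlineReference("at", "ATATATATATATAT", regions=(Region("V", 0, 14),))
    counts = eligible_site_counts(g)
    assert counts[GC_AID_HOT] == 0 and counts[GC_OTHER] == 0
    ann = [_seq(0, "x", clone="c0")]
    freqs = iteration_frequencies(ann, g)
    assert np.isnan(freqs[GC_AID_HOT])  # missing, not 0
    assert freqs[AT_POL_HOT] == 0.0


def test_iteration_frequency_toy_arithmetic(toy_germline):
    """One sequence, one AID-hotspot mutation, S=2 hotspot sites -> f=0.5."""
    ann = [_seq(0, "x", [_mut(toy_germline, 3)], clone="c0")]
    freqs = iteration_frequencies(ann, toy_germline)
    assert freqs[GC_AID_HOT] == 0.5
    assert freqs[AT_POL_HOT] == 0.0


def test_frequency_upper_bound_attained(toy_germline):
    """Every eligible hotspot site mutated in every sequence -> f = 1."""
    ann = [_seq(i, "x", [_mut(toy_germline, 2), _mut(toy_germline, 3)], clone=f"c{i}")
           for i in range(3)]
    freqs = iteration_frequencies(ann, toy_germline)
    assert freqs[GC_AID_HOT] == 1.0


def test_resample_uniform_over_members(rng):
    clones = [np.array([0, 1]), np.array([2, 3])]
    picks = [tuple(resample_iteration(clones, rng)) for _ in range(4000)]
    assert all(p[0] in (0, 1) and p[1] in (2, 3) for p in picks)
    freq0 = sum(p[0] == 0 for p in picks) / 4000
    # enumeration: 4 equally likely samples, each member appears w.p. 1/2
    assert abs(freq0 - 0.5) < 3 * np.sqrt(0.25 / 4000)


def test_resample_determinism():
    clones = [np.array([0, 1, 2]), np.array([3, 4])]
    a = [resample_iteration(clones, np.random.default_rng(5)) for _ in range(3)]
    b = [resample_iteration(clones, np.random.default_rng(5)) for _ in range(3)]
    assert a == b


def test_aggregate_singleton_clones_no_variance(germline294):
    ann = [_seq(i, f"cdr{i}", [_mut(germline294, 10 + i)], clone=f"c{i}") for i in range(5)]
    res = aggregate(ann, germline294, SpectrumConfig(n_iterations=50, seed=1))
    for s in SUBTYPES:
        if not np.isnan(res.sd[s]):
            assert res.sd[s] == 0.0
    assert res.n_seq == 5


def test_aggregate_bounds_and_profile(small_repertoire, germline294):
    from shmcsr.umi_consensus import process_read_pairs
    from shmcsr.annotation import annotate_all

    _, _, pairs = small_repertoire
    consensuses, _ = process_read_pairs(pairs)
    annotated, _ = annotate_all(consensuses, germline294)
    res = aggregate(annotated, germline294, SpectrumConfig(n_iterations=200, seed=2))
    valid = res.per_iteration[~np.isnan(res.per_iteration)]
    assert np.all((valid >= 0) & (valid <= 1))
    for i, s in enumerate(SUBTYPES):
        col = res.per_iteration[:, i]
        if not np.all(np.isnan(col)):
            assert col.min() <= res.mean[s] <= col.max()
    prof = res.positional_profile
    assert ((prof["value"] >= 0) & (prof["value"] <= 1)).all()
    for s, grp in prof.groupby("subtype"):
        if grp["value"].sum() > 0:
            assert grp["value"].max() == 1.0


def test_aggregate_seeded_determinism(germline294):
    ann = [_seq(i, f"cdr{i % 3}", [_mut(germline294, 20 + i)], clone="") for i in range(9)]
    from shmcsr.annotation import group_clones

    kept, _ = group_clones(ann)
    r1 = aggregate(kept, germline294, SpectrumConfig(n_iterations=100, seed=9))
    r2 = aggregate(kept, germline294, SpectrumConfig(n_iterations=100, seed=9))
    assert np.array_equal(r1.per_iteration, r2.per_iteration, equal_nan=True)
    assert r1.mean == r2.mean and r1.positional_profile.equals(r2.positional_profile)


def test_deinflation_closed_form(germline294):
    """One 3-member clone carrying an inherited hotspot mutation + two clean
    singletons: the resampled frequency equals the closed form with the
    clone counted once, while pooling counts it 3 times."""
    pos = next(i for i in range(279) if germline294.subtype_mask[i] == GC_AID_HOT)
    S = eligible_site_counts(germline294)[GC_AID_HOT]
    ann = ([_seq(i, "SHARED", [_mut(germline294, pos)]) for i in range(3)]
           + [_seq(3, "U1"), _seq(4, "U2")])
    from shmcsr.annotation import group_clones

    kept, _ = group_clones(ann)
    res = aggregate(kept, germline294, SpectrumConfig(n_iterations=100, seed=3))
    assert res.mean[GC_AID_HOT] == pytest.approx(1 / (S * 3), abs=1e-12)
    pooled = pooled_frequencies(kept, germline294)
    assert pooled[GC_AID_HOT] == pytest.approx(3 / (S * 5), abs=1e-12)


def _result_from_mean(mean_hot, site_counts, n_seq):
    """Minimal SpectrumResult carrying just what compare_genotypes reads."""
    mean = {s: 0.0 for s in SUBTYPES}
    mean[GC_AID_HOT] = mean_hot
    return SpectrumResult(subtypes=SUBTYPES, per_iteration=np.zeros((1, 4)), mean=mean,
                          sd={s: 0.0 for s in SUBTYPES}, ci={s: (0.0, 0.0) for s in SUBTYPES},
                          site_counts=site_counts, n_seq=n_seq, n_iterations=1, seed=0,
                          positional_profile=None)


def _yates_oracle(table):
    """Hand formula: sum of (max(|O-E|-0.5, 0))^2 / E over the 2x2 cells."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = table[i].sum() * table[:, j].sum() / total
            stat += max(abs(table[i, j] - e) - 0.5, 0.0) ** 2 / e
    return stat


def test_compare_genotypes_identical_is_null():
    sc = {GC_AID_HOT: 100, GC_OTHER: 0, AT_POL_HOT: 0, AT_OTHER: 0}
    a = _result_from_mean(0.10, sc, 1)
    out = compare_genotypes(a, a)
    row = out[out["contrast"] == GC_AID_HOT].iloc[0]
    assert row["statistic"] == 0.0 and row["pvalue"] == 1.0


def test_compare_genotypes_matches_hand_formula():
    """Table [[20,80],[5,95]] built from means 0.20 vs 0.05 over 100
    opportunities; the statistic must equal the brute-force Yates value."""
    from scipy import stats as sps

    sc = {GC_AID_HOT: 100, GC_OTHER: 0, AT_POL_HOT: 0, AT_OTHER: 0}
    a = _result_from_mean(0.20, sc, 1)
    b = _result_from_mean(0.05, sc, 1)
    out = compare_genotypes(a, b)
    row = out[out["contrast"] == GC_AID_HOT].iloc[0]
    expected = _yates_oracle([[20, 80], [5, 95]])
    assert row["statistic"] == pytest.approx(expected, rel=1e-12)
    assert row["pvalue"] == pytest.approx(sps.chi2.sf(expected, 1), rel=1e-12)
    # swapping the rows leaves the statistic unchanged
    swapped = compare_genotypes(b, a)
    assert swapped[swapped["contrast"] == GC_AID_HOT].iloc[0]["statistic"] == \
        pytest.approx(expected, rel=1e-12)


def test_compare_genotypes_zero_expected_not_computable():
    sc = {GC_AID_HOT: 100, GC_OTHER: 0, AT_POL_HOT: 0, AT_OTHER: 0}
    a = _result_from_mean(0.0, sc, 1)
    out = compare_genotypes(a, a)
    row = out[out["contrast"] == GC_AID_HOT].iloc[0]
    assert not row["computable"]
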