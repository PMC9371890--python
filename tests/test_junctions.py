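"""Switch-junction decomposition scoring and cohort statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats

from conftest import enumerate_junction_decompositions
from shmcsr.errors import ConfigurationError
from shmcsr.junctions import (JunctionCohort, SwitchJunction,
                              compare_insertion_frequencies, compare_mh_distributions,
                              insertion_frequency, proportion_percent,
                              relative_csr_efficiency, score_junction)
from shmcsr.seqs import random_bases
from shmcsr.synthetic_data import (JunctionMixture, make_switch_references,
                                   simulate_junctions)


def _refs(seed, n=120):
    rng = np.random.default_rng(seed)
    return random_bases(rng, n, 0.5), random_bases(rng, n, 0.5)


def test_blunt_by_construction():
    donor, acceptor = _refs(1)
    # choose breakpoints whose flanks cannot extend the match
    d, a = next((d, a) for d in range(30, 60) for a in range(40, 70)
                if donor[d] != acceptor[a] and donor[d - 1] != acceptor[a - 1])
    j = score_junction(donor[:d] + acceptor[a:], donor, acceptor)
    assert j.resolved and j.score == 0 and j.kind == "blunt"
    assert j.donor_break == d and j.acceptor_break == a


def test_engineered_microhomology_scores_plus_k():
    """Donor and acceptor share an engineered 3-mer at the breakpoints; the
    junction writes it once. Brute-force enumeration confirms max k = 3."""
    rng = np.random.default_rng(2)
    donor = random_bases(rng, 120, 0.5)
    acceptor = random_bases(rng, 120, 0.5)
    d, a = 40, 60
    core = donor[d - 3:d]
    flank_l = "A" if donor[d - 4] != "A" else "C"
    flank_r = "A" if donor[d] != "A" else "C"
    acceptor = acceptor[:a - 4] + flank_l + core + flank_r + acceptor[a + 1:]
    if donor[d - 4] == acceptor[a - 4] or donor[d] == acceptor[a]:
        pytest.fail("engineering failed")
    junction = donor[:d] + acceptor[a:]
    resolved, oracle = enumerate_junction_decompositions(junction, donor, acceptor)
    assert resolved and oracle == 3
    j = score_junction(junction, donor, acceptor)
    assert j.score == 3 and j.kind == "microhomology"
    assert j.prefix_len + j.suffix_len - j.score == len(junction)


def test_untemplated_insertion_scores_minus_m():
    donor, acceptor = _refs(3)
    d, a, ins = next(
        (d, a, b * 2)
        for d in range(40, 55) for a in range(50, 65) for b in "ACGT"
        if donor[d] != acceptor[a] and donor[d - 1] != acceptor[a - 1]
        and b != donor[d] and b != acceptor[a - 1])
    junction = donor[:d] + ins + acceptor[a:]
    resolved, oracle = enumerate_junction_decompositions(junction, donor, acceptor)
    assert resolved and oracle == -2
    j = score_junction(junction, donor, acceptor)
    assert j.score == -2 and j.kind == "insertion" and j.insert == ins


def test_unresolvable_junction_flagged():
    donor, acceptor = _refs(4)
    rng = np.random.default_rng(5)
    alien = random_bases(rng, 40, 0.5)  # unrelated to either reference
    j = score_junction(alien, donor, acceptor)
    assert not j.resolved and j.kind == "unresolved"


def test_short_junction_rejected():
    donor, acceptor = _refs(6)
    with pytest.raises(ConfigurationError):
        score_junction("ACGTACGTACGT", donor, acceptor)


def test_decomposition_conservation_random():
    """prefix + |insert| + suffix - overlap == junction length on random
    resolvable junctions; score agrees with exhaustive enumeration."""
    rng = np.random.default_rng(7)
    checked = 0
    for trial in range(120):
        donor = random_bases(rng, 60, 0.5)
        acceptor = random_bases(rng, 60, 0.5)
        kind = trial % 3
        d = int(rng.integers(12, 28))
        if kind == 0:
            a = 60 - (40 - d)
            junction = donor[:d] + acceptor[a:]
        elif kind == 1:
            k = int(rng.integers(1, 4))
            a = 60 - (40 - d) + k
            acceptor = acceptor[:a - k] + donor[d - k:d] + acceptor[a:]
            junction = donor[:d] + acceptor[a:]
        else:
            m = int(rng.integers(1, 4))
            a = 60 - (40 - d) + m
            junction = donor[:d] + random_bases(rng, m, 0.5) + acceptor[a:]
        resolved, oracle = enumerate_junction_decompositions(junction, donor, acceptor)
        j = score_junction(junction, donor, acceptor)
        assert j.resolved == resolved
        if resolved:
            checked += 1
            assert j.score == oracle
            overlap = max(j.score, 0)
            assert j.prefix_len + len(j.insert) + j.suffix_len - overlap == len(junction)
    assert checked >= 100


def test_truth_recovery_on_simulated_junctions():
    donor, acceptor = make_switch_references(400, 400, seed=8)
    mix = JunctionMixture(p_blunt=0.3, p_mh=0.5, p_ins=0.2)
    sims = simulate_junctions(donor, acceptor, mix, 150, seed=9)
    for s in sims:
        j = score_junction(s.sequence, donor, acceptor)
        assert j.resolved and j.score == s.label


def _cohort(scores, genotype="g"):
    juncs = [SwitchJunction(id=f"j{i}", sequence="A" * 40, score=int(s), donor_break=0,
                            acceptor_break=0, prefix_len=20, suffix_len=20, insert="")
             for i, s in enumerate(scores)]
    return JunctionCohort(genotype=genotype, junctions=juncs)


def test_insertion_frequency_counts():
    assert insertion_frequency(_cohort([0, 1, 2])) == 0.0
    assert insertion_frequency(_cohort([-1, -2])) == 1.0
    scores = [-1] * 3 + [0] * 10 + [2] * 12
    assert insertion_frequency(_cohort(scores)) == pytest.approx(0.12)


def test_kruskal_identical_cohorts_null():
    out = compare_mh_distributions([_cohort([0, 1, 2, 3], "a"), _cohort([0, 1, 2, 3], "b")])
    assert out["H"] == pytest.approx(0.0, abs=1e-12)
    assert out["p"] == pytest.approx(1.0)
    out = compare_mh_distributions([_cohort([2, 2, 2], "a"), _cohort([2, 2, 2], "b")])
    assert out["H"] == 0.0 and out["p"] == 1.0  # fully degenerate


def test_kruskal_exact_matches_permutation_oracle():
    """{0,0,0} vs {5,5,5}: enumerate all C(6,3)=20 rank assignments; the
    observed tie-corrected H (=5) is attained by exactly 2 of them."""
    pooled = [0, 0, 0, 5, 5, 5]
    ranks = stats.rankdata(pooled)
    tie = sum(c ** 3 - c for c in (3, 3))
    corr = 1 - tie / (6 ** 3 - 6)

    def h_of(idx):
        r1 = sum(ranks[i] for i in idx)
        r2 = ranks.sum() - r1
        h = 12 / (6 * 7) * (r1 ** 2 / 3 + r2 ** 2 / 3) - 3 * 7
        return h / corr

    h_obs = h_of((0, 1, 2))
    hits = sum(h_of(c) >= h_obs - 1e-12 for c in itertools.combinations(range(6), 3))
    p_oracle = hits / 20
    assert p_oracle == pytest.approx(0.1)

    out = compare_mh_distributions([_cohort([0, 0, 0], "a"), _cohort([5, 5, 5], "b")])
    assert out["method"] == "exact_permutation"
    assert out["H"] == pytest.approx(h_obs)
    assert out["p"] == pytest.approx(p_oracle)


def test_dunn_pairwise_structure():
    rng = np.random.default_rng(10)
    cohorts = [_cohort(rng.integers(-3, 8, 25), f"g{i}") for i in range(3)]
    out = compare_mh_distributions(cohorts, p_adjust="bonferroni")
    dunn = out["dunn"]
    assert len(dunn) == 3
    assert ((dunn["pvalue"] >= 0) & (dunn["pvalue"] <= 1)).all()
    assert (dunn["p_adjusted"] >= dunn["pvalue"] - 1e-12).all()


def _fisher_oracle(table):
    """Two-sided Fisher p by hypergeometric enumeration over all tables with
    the observed margins."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c
    xs = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(xs, n, c1, r1)
    obs = stats.hypergeom.pmf(a, n, c1, r1)
    return float(pmf[pmf <= obs * (1 + 1e-9)].sum())


def test_fisher_examples_and_symmetry():
    p, _ = compare_insertion_frequencies(_cohort([1] * 10), _cohort([2] * 12))
    assert p == 1.0  # zero insertion margin
    p, oratio = compare_insertion_frequencies(_cohort([-1] * 5), _cohort([1] * 5))
    assert p == pytest.approx(2 / 252)
    assert _fisher_oracle([[5, 0], [0, 5]]) == pytest.approx(2 / 252)
    # invariance under transposing the table
    a = _cohort([-1] * 4 + [0] * 8)
    b = _cohort([-1] * 1 + [0] * 11)
    p_ab, _ = compare_insertion_frequencies(a, b)
    table_t = np.array([[4, 1], [8, 11]])
    p_t = stats.fisher_exact(table_t)[1]
    assert p_ab == pytest.approx(p_t)


def test_relative_csr_efficiency():
    assert relative_csr_efficiency([0.3], [0.2, 0.4])[0] == pytest.approx(100.0)
    assert relative_csr_efficiency([0.15], [0.2, 0.4])[0] == pytest.approx(50.0)
    assert relative_csr_efficiency([0.0], [0.2, 0.4])[0] == 0.0
    with pytest.raises(ConfigurationError):
        relative_csr_efficiency([0.1], [0.0, 0.0])


@pytest.mark.parametrize("k,n,expected", [(14, 24, 58), (17, 17, 100), (0, 24, 0),
                                          (5, 24, 21), (2, 24, 8), (1, 8, 13)])
def test_proportion_percent(k, n, expected):
    assert proportion_percent(k, n) == expected


def test_proportion_percent_validation():
    with pytest.raises(ConfigurationError):
        proportion_percent(1, 0)
    with pytest.raises(ConfigurationError):
        proportion_percent(5, 4)
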