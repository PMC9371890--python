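import numpy as np
import pytest

from shmcsr import PROFILES, make_germline, simulate_reads, simulate_repertoire
from shmcsr.germline import GermlineReference, Region


@pytest.fixture(scope="session")
def germline294():
    """Default-size synthetic VH germline (294 bases, VH186.2-like layout)."""
    return make_germline(294, 0.5, seed=101)


@pytest.fixture(scope="session")
def toy_germline():
    """The 5-base worked-example germline with a fully analyzed region."""
    return GermlineReference(name="toy", sequence="AAGCT", regions=(Region("V", 0, 5),))


@pytest.fixture(scope="session")
def small_repertoire(germline294):
    """Clonal repertoire + error-free reads, shared by recovery tests."""
    mols, truth = simulate_repertoire(germline294, PROFILES["WT-like"], n_clones=60,
                                      clone_size_dist="geometric", inherited_fraction=0.3,
                                      seed=202)
    pairs, umi_of = simulate_reads(mols, umi_length=8, reads_per_molecule=3,
                                   error_rate=0.0, overlap=60, seed=303)
    truth.umi_of = umi_of
    return mols, truth, pairs


def enumerate_junction_decompositions(junction: str, donor: str, acceptor: str,
                                      anchor_min: int = 10):
    """Brute-force junction scoring oracle: enumerate every (prefix, suffix)
    decomposition and apply the max-microhomology / min-insertion preference.

    Returns (resolved, score)."""
    L = len(junction)
    ps = [p for p in range(anchor_min, L + 1) if junction[:p] in donor]
    ss = [s for s in range(anchor_min, L + 1) if junction[L - s:] in acceptor]
    if not ps or not ss:
        return False, None
    best = None
    for p in ps:
        for s in ss:
            k = p + s - L
            if best is None or k > best:
                best = k
    return True, best


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
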