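import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from epiunwarp import phantom as ph  # noqa: E402


@pytest.fixture(scope="session")
def small_spec():
    """Phantom at a size where every stage (including exact per-voxel
    confidence) runs in seconds."""
    return ph.default_spec(grid_shape=(24, 24, 12))


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return ph.generate_true_phase(small_spec)


@pytest.fixture(scope="session")
def small_magnitude(small_spec):
    return ph.generate_magnitude(small_spec)


@pytest.fixture(scope="session")
def small_mask(small_spec):
    return ph.head_mask(small_spec)


@pytest.fixture(scope="session")
def default_spec_full():
    """The study-condition phantom (64x64x32, resection enabled)."""
    return ph.default_spec()


def random_submodular_mrf(rng, n_max=12, dyadic=16.0):
    """A random binary pairwise MRF with dyadic-rational energies (so flow
    arithmetic and float enumeration agree bit-for-bit) plus its exhaustive
    energy table.  Returns (n, unary, pairs) with pairs as (i, j, e) and e
    the 4-vector (e00, e01, e10, e11)."""
    n = int(rng.integers(2, n_max + 1))
    unary = rng.integers(0, 64, size=(n, 2)) / dyadic
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                e = rng.integers(0, 64, size=4) / dyadic
                excess = (e[0] + e[3]) - (e[1] + e[2])
                if excess > 0:
                    e[1] += excess  # force submodularity
                pairs.append((i, j, e))
    return n, unary, pairs


def mrf_energy_table(n, unary, pairs):
    """Energies of all 2^n labellings (brute-force oracle)."""
    labels = np.arange(2**n)[:, None] >> np.arange(n)[None, :] & 1
    energies = unary[np.arange(n), labels].sum(axis=1).astype(float)
    for i, j, e in pairs:
        energies += np.asarray(e, dtype=float)[2 * labels[:, i] + labels[:, j]]
    return labels, energies


def build_network(n, unary, pairs):
    from epiunwarp.graphcore import FlowNetwork, PairwiseTerm

    net = FlowNetwork(n)
    for i in range(n):
        net.add_unary(i, unary[i, 0], unary[i, 1])
    for i, j, e in pairs:
        net.add_pairwise(i, j, PairwiseTerm(*e))
    return net
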