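import numpy as np
import pytest

import funcgrad as fg


@pytest.fixture(scope="session")
def small_scheme():
    """28-parcel scheme, 4 parcels per network, 14 per hemisphere."""
    return fg.generate_parcel_scheme(28, (4,) * 7, seed=7)


@pytest.fixture(scope="session")
def scheme400():
    return fg.generate_parcel_scheme(400, seed=7)


@pytest.fixture(scope="session")
def small_spec():
    """Fast cohort: 8 pairs, 2 controls, 56 parcels, 80 timepoints."""
    return fg.CohortSpec(
        n_pairs=8,
        n_controls=2,
        n_timepoints=80,
        n_parcels=56,
        network_sizes=(8,) * 7,
        effect_size=0.15,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return fg.generate_cohort(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def three_block_affinity(block_size=6, within=(1.0, 0.9, 0.8), between=0.01):
    """Affinity with 3 weakly coupled dense blocks.

    Distinct within-block weights break the eigenvalue degeneracy of three
    exactly identical blocks, so the leading non-trivial eigenvector is
    constant within blocks and takes three distinct values.
    """
    n = 3 * block_size
    w = np.full((n, n), between)
    for b in range(3):
        sl = slice(b * block_size, (b + 1) * block_size)
        w[sl, sl] = within[b]
    np.fill_diagonal(w, 1.0)
    return w
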