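import numpy as np
import pytest

from complexome.datatypes import ComplexomeDataset, Membership, Role
from complexome.synthetic import SyntheticSpec, figure1_toy, generate


@pytest.fixture(scope="session")
def toy():
    """Three-complex worked example: A{a,b,c}, B{b,d,e}, C{b,e}."""
    return figure1_toy()


@pytest.fixture(scope="session")
def small_world():
    """A small noisy synthetic complexome shared across tests."""
    spec = SyntheticSpec(
        n_complexes=60,
        n_proteins=200,
        mean_complex_size=6.0,
        mean_membership=1.8,
        n_functions=40,
        seed=1,
    )
    return generate(spec)


def grid_minimum_chunked(S, p, step):
    """Brute-force minimum leftover over a copy-number grid.

    Scans every c vector with entries in {0, step, 2·step, ..., max p},
    chunked over the first coordinate to bound memory. Independent of
    the LP route by construction.
    """
    S = np.asarray(S, dtype=float)
    n, m = S.shape
    axis = np.arange(0.0, p.max() + step / 2, step)
    best = float(p.sum())
    if m == 1:
        tail = axis.reshape(-1, 1)
        first = [0.0]
    else:
        grids = np.meshgrid(*([axis] * (m - 1)), indexing="ij")
        tail = np.stack([g.ravel() for g in grids], axis=1)
        first = axis
    for c0 in first:
        if m == 1:
            C = tail
        else:
            C = np.concatenate(
                [np.full((len(tail), 1), c0), tail], axis=1
            )
        usage = C @ S.T
        feasible = np.all(usage <= p + 1e-12, axis=1)
        if feasible.any():
            best = min(best, float(p.sum() - usage[feasible].sum(axis=1).max()))
    return best


def random_dataset(rng, n_complexes, n_proteins, p_edge=0.3, core_prob=0.6):
    """Random bipartite membership structure for oracle comparisons."""
    memberships = []
    for j in range(n_complexes):
        for i in range(n_proteins):
            if rng.random() < p_edge:
                role = Role.CORE if rng.random() < core_prob else Role.ATTACHMENT
                memberships.append(Membership(f"C{j:02d}", f"P{i:02d}", role))
    if not memberships:
        memberships.append(Membership("C00", "P00", Role.CORE))
    return ComplexomeDataset.from_memberships(memberships)
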