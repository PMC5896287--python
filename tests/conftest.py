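import numpy as np
import pytest

import spacecohort as sc


@pytest.fixture
def path3():
    """Path graph a - b - c."""
    return sc.graph_from_edges(["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture
def lattice5():
    return sc.make_lattice_graph(5, 5)


@pytest.fixture
def standard_ages():
    """The ten 5-year age bands from 40 up, open-ended at 85."""
    return tuple((lo, lo + 5) for lo in range(40, 85, 5)) + ((85, None),)


@pytest.fixture
def standard_periods():
    return (
        (1971, 1974),
        (1975, 1979),
        (1980, 1984),
        (1985, 1989),
        (1990, 1994),
        (1995, 1999),
        (2000, 2004),
        (2005, 2010),
    )


def random_connected_graph(rng: np.random.Generator, n: int) -> sc.AdjacencyGraph:
    """Random connected graph: a spanning path plus random extra edges."""
    order = rng.permutation(n)
    edges = {(min(a, b), max(a, b)) for a, b in zip(order[:-1], order[1:])}
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        a, b = rng.integers(0, n, size=2)
        if a != b:
            edges.add((min(a, b), max(a, b)))
    ids = [str(i) for i in range(n)]
    return sc.graph_from_edges(ids, [(str(a), str(b)) for a, b in edges])
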