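import numpy as np
import pytest

import spotfuse as sf


@pytest.fixture(scope="session")
def small_grid():
    """10 × 10 hexagonal lattice (100 spots)."""
    return sf.generate_visium_grid(n_rows=10, spots_per_row=10)


@pytest.fixture(scope="session")
def small_experiment(small_grid):
    """One simulated experiment at default conditions, seed 7."""
    params = sf.default_params(seed=7)
    return sf.simulate_experiment(small_grid, params)


@pytest.fixture(scope="session")
def fused(small_experiment):
    grid, truth, deconv, counts = small_experiment
    cells = sf.assign_cells_to_spots(truth.cells, grid)
    labelled, type_counts = sf.fuse(cells, deconv, sf.FusionConfig(seed=7))
    return grid, truth, deconv, counts, labelled, type_counts


def morans_i_bruteforce(values, graph):
    """Independent double-loop Moran's I on the dense weight matrix."""
    n = graph.n_nodes
    w = np.zeros((n, n))
    for (i, j), wt in zip(graph.edges, graph.weights):
        w[i, j] = wt
        w[j, i] = wt
    x = np.asarray(values, float)
    z = x - x.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * z[i] * z[j]
    return (n / w.sum()) * num / (z @ z)


def distinct_labelings(counts):
    """All distinct label vectors with exactly counts[k] entries of type k."""
    n = int(sum(counts))

    def rec(remaining, prefix):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for k, c in enumerate(remaining):
            if c > 0:
                nxt = list(remaining)
                nxt[k] -= 1
                yield from rec(nxt, prefix + [k])

    return rec(list(counts), [])
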