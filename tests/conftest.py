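import numpy as np
import pytest

import phylogrid as pg


@pytest.fixture(scope="session")
def balanced_tree():
    """Four-tip balanced tree with unit branches; the hand-oracle workhorse."""
    return pg.Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def pe_tree():
    """Three-tip tree used for the hand phylogenetic-endemism computation."""
    return pg.Phylogeny.from_newick("((A:1,B:1)E:1,C:2);")


@pytest.fixture(scope="session")
def default_dataset():
    """Desk-scale synthetic dataset: 10x10 grid, 64 species, neutral assembly."""
    return pg.simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def default_dendrogram(default_dataset):
    return pg.upgma_dendrogram(pg.gower_distance(default_dataset["traits"]))


def canape_endemic_fixture(endemic_length: float):
    """20-cell community of 10 widespread short-branch species plus one
    single-cell species on a terminal branch of the given length; the focal
    cell c5 holds only the endemic."""
    rng = np.random.default_rng(0)
    n_cells, n_wide = 20, 10
    inc = np.zeros((n_cells, n_wide + 1), dtype=int)
    inc[:, :n_wide] = (rng.random((n_cells, n_wide)) < 0.6).astype(int)
    inc[5, :n_wide] = 0
    for j in range(n_wide):
        if inc[:, j].sum() == 0:
            inc[0, j] = 1
    inc[5, n_wide] = 1
    names = [f"w{i}" for i in range(n_wide)] + ["endemic"]
    nwk = "(" * n_wide + names[0] + ":0.1"
    for t in names[1:-1]:
        nwk += f",{t}:0.1):0.1"
    nwk += f",endemic:{endemic_length}):0.1;"
    tree = pg.Phylogeny.from_newick(nwk)
    matrix = pg.OccurrenceMatrix([f"c{i}" for i in range(n_cells)], names, inc)
    return tree, matrix
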