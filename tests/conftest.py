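import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import coactivate as ca


@pytest.fixture(scope="session")
def signatures():
    return {s.name: s for s in ca.default_signatures()}


@pytest.fixture(scope="session")
def panel():
    return ca.default_marker_panel()


@pytest.fixture(scope="session")
def small_dataset():
    """A small well-separated simulated tissue, normalized, with truth."""
    cfg = ca.SyntheticConfig(seed=42, n_cells=600, n_genes=400)
    matrix, truth = ca.simulate_dataset(cfg)
    return ca.normalize(matrix), truth


def make_matrix(counts, genes=None, cells=None, species="mouse"):
    """Build a tiny ExpressionMatrix from a dense array."""
    counts = np.asarray(counts)
    n, g = counts.shape
    genes = list(genes) if genes is not None else [f"G{j}" for j in range(g)]
    cells = list(cells) if cells is not None else [f"c{i}" for i in range(n)]
    gene_meta = pd.DataFrame(
        {"species": species, "canonical": ca.harmonize_genes(genes, species, species)},
        index=pd.Index(genes, name="gene"),
    )
    return ca.ExpressionMatrix(
        counts=sparse.csr_matrix(counts),
        cell_meta=pd.DataFrame(index=pd.Index(cells, name="cell")),
        gene_meta=gene_meta,
    )


@pytest.fixture
def toy_matrix():
    return make_matrix([[1, 2, 0], [0, 5, 3], [4, 0, 1]], genes=["Kdr", "Flt1", "Actb"])
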