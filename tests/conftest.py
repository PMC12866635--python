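import anndata as ad
import numpy as np
import pandas as pd
import pytest

import cellsnv as c


def random_matrix(rng: np.random.Generator, max_cells: int = 50, max_snvs: int = 20) -> c.CellSNVMatrix:
    """A random cells x SNVs matrix with a mix of all four allelic states."""
    n_cells = int(rng.integers(2, max_cells + 1))
    n_snvs = int(rng.integers(1, max_snvs + 1))
    cells = [f"BC{i:03d}-1" for i in range(n_cells)]
    snvs = [c.SNVKey(str(j % 22 + 1), 100 + j, "A", "G") for j in range(n_snvs)]
    observed = rng.random((n_cells, n_snvs)) < 0.6
    nv = np.where(observed, rng.integers(0, 6, (n_cells, n_snvs)), 0)
    nr = np.where(observed, rng.integers(0, 6, (n_cells, n_snvs)), 0)
    # entries drawn (0, 0) while "observed" are genuinely uncovered
    observed = (nv + nr) >= 1
    return c.CellSNVMatrix(cells, snvs, nv.astype(np.int64), nr.astype(np.int64), observed)


def matrix_from_columns(columns: list[list[tuple[int, int]]]) -> c.CellSNVMatrix:
    """Build a matrix from per-SNV lists of (n_var, n_ref) per cell."""
    n_cells = len(columns[0])
    cells = [f"BC{i:03d}" for i in range(n_cells)]
    snvs = [c.SNVKey("1", 100 + j, "C", "T") for j in range(len(columns))]
    nv = np.array([[col[i][0] for col in columns] for i in range(n_cells)], dtype=np.int64)
    nr = np.array([[col[i][1] for col in columns] for i in range(n_cells)], dtype=np.int64)
    return c.CellSNVMatrix(cells, snvs, nv, nr, (nv + nr) >= 1)


@pytest.fixture(scope="session")
def default_dataset():
    return c.simulate_dataset(c.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_matrix(default_dataset):
    return c.build_matrix(default_dataset.snv_table, default_dataset.barcodes)


@pytest.fixture(scope="session")
def expression_adata(default_dataset):
    ds = default_dataset
    return ad.AnnData(
        X=ds.expression.T.astype(np.float64),
        obs=pd.DataFrame(index=pd.Index(ds.barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(ds.gene_ids, name="gene")),
    )


@pytest.fixture
def small_embedding():
    rng = np.random.default_rng(7)
    barcodes = [f"BC{i:02d}" for i in range(10)]
    return c.Embedding(
        barcodes=barcodes,
        coordinates={("umap", 2): rng.normal(size=(10, 2)), ("umap", 3): rng.normal(size=(10, 3))},
        clusters=np.array([0] * 5 + [1] * 5),
    )
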