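import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scrobust.io_qc import CountMatrix, NormalizedMatrix, filter_cells, normalize
from scrobust.synthetic import CohortConfig, generate_cohort


def random_count_matrix(
    rng: np.random.Generator,
    n_cells: int = 50,
    n_genes: int = 40,
    n_mito: int = 3,
    density_lam: float = 2.0,
) -> CountMatrix:
    """Small random integer matrix with a few mt- genes, for QC/oracle tests."""
    X = rng.poisson(density_lam, size=(n_cells, n_genes))
    symbols = [f"mt-G{i}" if i < n_mito else f"G{i}" for i in range(n_genes)]
    obs = pd.DataFrame(index=pd.Index([f"c{i}" for i in range(n_cells)], name="barcode"))
    var = pd.DataFrame(index=pd.Index(symbols, name="symbol"))
    return CountMatrix(sp.csr_matrix(X), obs, var)


def dense_normalized(X: np.ndarray, symbols=None) -> NormalizedMatrix:
    """Wrap a dense array as a NormalizedMatrix with generic labels."""
    n_cells, n_genes = X.shape
    symbols = symbols or [f"G{i}" for i in range(n_genes)]
    obs = pd.DataFrame(index=pd.Index([f"c{i}" for i in range(n_cells)], name="barcode"))
    var = pd.DataFrame(index=pd.Index(symbols, name="symbol"))
    var["mito"] = False
    return NormalizedMatrix(np.asarray(X, float), obs, var)


@pytest.fixture(scope="session")
def small_cohort():
    """One 600-cell, 1000-gene dataset with 4 planted programs, QC'd and normalized."""
    cfg = CohortConfig(
        n_datasets=1, replicates_per_dataset=1, cells_per_dataset=600,
        n_genes=1000, n_programs=4, seed=11,
    )
    (matrix, truth), = generate_cohort(cfg)
    filtered, report = filter_cells(matrix)
    norm = normalize(filtered)
    return {"raw": matrix, "filtered": filtered, "norm": norm,
            "truth": truth, "report": report, "config": cfg}


@pytest.fixture(scope="session")
def replicate_pair():
    """One tissue profiled in two replicates with batch effects, for matching tests."""
    cfg = CohortConfig(
        n_datasets=1, replicates_per_dataset=2, cells_per_dataset=600,
        n_genes=1000, n_programs=4, batch_sd=0.8, seed=7,
    )
    out = []
    for matrix, truth in generate_cohort(cfg):
        filtered, _ = filter_cells(matrix)
        out.append({"matrix": filtered, "norm": normalize(filtered), "truth": truth})
    return out
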