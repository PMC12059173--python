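import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from tlsarch.gene_sets import GeneSet
from tlsarch.matrix import CountMatrix


@pytest.fixture
def toy_matrix() -> CountMatrix:
    """3 cells x 4 genes with hand-checkable sums (MT-CO1 mitochondrial)."""
    X = np.array(
        [
            [5, 0, 3, 2],   # cellA: 3 genes, 10 UMIs, 2/10 mito
            [0, 0, 0, 0],   # cellB: empty
            [0, 0, 0, 7],   # cellC: all counts on the mito gene
        ]
    )
    return CountMatrix(
        sp.csr_matrix(X),
        pd.Index(["cellA", "cellB", "cellC"]),
        pd.Index(["GENE1", "GENE2", "GENE3", "MT-CO1"]),
    )


def make_cells(counts: dict[tuple[str, str], int]) -> pd.DataFrame:
    """Cell table from {(status, cluster): n_cells} counts."""
    rows = []
    for (status, cluster), n in counts.items():
        for i in range(n):
            rows.append(
                (f"{status}_{cluster}_{i}", f"{status}_s1", status, cluster, "all")
            )
    return pd.DataFrame(
        rows, columns=["cell_id", "sample_id", "tls_status", "subcluster", "lineage"]
    )


def chain(cell_id, locus, junction, v_call="V1", j_call="J1"):
    return {"cell_id": cell_id, "locus": locus, "junction": junction,
            "v_call": v_call, "j_call": j_call}


@pytest.fixture
def random_count_matrix():
    def _make(n_cells=20, n_genes=50, seed=0, mean=2.0):
        rng = np.random.default_rng(seed)
        X = rng.poisson(mean, size=(n_cells, n_genes))
        return CountMatrix(
            sp.csr_matrix(X),
            pd.Index([f"c{i}" for i in range(n_cells)]),
            pd.Index([f"g{i}" for i in range(n_genes)]),
        )
    return _make


@pytest.fixture
def small_gene_set():
    return GeneSet("toy", frozenset(["g0", "g1", "g2"]))
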