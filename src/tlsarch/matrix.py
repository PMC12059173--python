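"""Sparse cell x gene count matrix with labeled axes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class CountMatrix:
    """Cells x genes matrix of nonnegative integer counts.

    Attributes
    ----------
    X : scipy.sparse.csr_matrix
        cells x genes counts.
    cell_ids : pd.Index
        Unique cell identifiers (rows).
    gene_ids : pd.Index
        Unique gene symbols (columns).
    """

    X: sp.csr_matrix
    cell_ids: pd.Index
    gene_ids: pd.Index

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.cell_ids = pd.Index(self.cell_ids)
        self.gene_ids = pd.Index(self.gene_ids)
        if self.X.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if not self.cell_ids.is_unique:
            raise ValueError("cell ids are not unique")
        if not self.gene_ids.is_unique:
            raise ValueError("gene ids are not unique")
        if self.X.nnz and self.X.data.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(self.X[mask], self.cell_ids[mask], self.gene_ids)

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(self.X[:, mask], self.cell_ids, self.gene_ids[mask])

    def to_dense(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.X.toarray(), index=self.cell_ids, columns=self.gene_ids
        )
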