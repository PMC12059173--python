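"""Spot-level cell-type co-occurrence scores.

Given a spots x cell-types matrix C of predicted abundances (e.g. from a
spatial deconvolution of capture spots), the co-occurrence score of types A
and B is

    score(A, B) = (sum_j C_Aj * C_Bj / N) * 1000

— the mean per-spot product of the two types' abundances, scaled by 1000.
Abundances are used as provided (no per-spot renormalization); spots with
all-zero abundance still count in N. A compositional mode that row-
normalizes spots first is offered for sensitivity analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SCALE = 1000.0


def _validate(abund: pd.DataFrame) -> pd.DataFrame:
    if abund.shape[0] < 1:
        raise ValueError("need at least one spot")
    if (abund.to_numpy() < 0).any():
        raise ValueError("abundances must be nonnegative")
    return abund


def cooccurrence_score(abund: pd.DataFrame, a: str, b: str) -> float:
    """Co-occurrence score of types ``a`` and ``b`` (spots x types input)."""
    _validate(abund)
    for t in (a, b):
        if t not in abund.columns:
            raise KeyError(f"unknown cell type {t!r}")
    n = len(abund)
    return float((abund[a].to_numpy() * abund[b].to_numpy()).sum() / n * SCALE)


def cooccurrence_matrix(abund: pd.DataFrame, compositional: bool = False) -> pd.DataFrame:
    """All pairwise co-occurrence scores, symmetric, diagonal included.

    ``compositional=True`` row-normalizes each spot to sum 1 first
    (all-zero spots stay zero).
    """
    _validate(abund)
    if abund.shape[1] < 2:
        raise ValueError("need at least two cell types")
    C = abund.to_numpy(dtype=float)
    if compositional:
        rowsum = C.sum(axis=1, keepdims=True)
        C = np.divide(C, rowsum, out=np.zeros_like(C), where=rowsum > 0)
    M = C.T @ C / C.shape[0] * SCALE
    return pd.DataFrame(M, index=abund.columns, columns=abund.columns)


def cooccurrence_long(matrix: pd.DataFrame) -> pd.DataFrame:
    """Heatmap-ready long format (type_a, type_b, score)."""
    long = matrix.stack().rename("score").reset_index()
    long.columns = ["type_a", "type_b", "score"]
    return long
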