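"""Rank-based gene-set activity scoring.

The per-cell score is the area under the recovery curve (cumulative count of
signature genes found while walking down the cell's expression-ranked gene
list) over the top fraction of ranks, normalized by the maximum attainable
area for the set size, so scores lie in [0, 1] and are comparable across
sets. Because only ranks enter, the score is invariant to any monotone
per-cell transform of expression (raw counts, CPM, log — all equivalent).

Ties are broken deterministically by gene index (stable order after sorting
by expression); a seeded random tie-break is available for sensitivity
checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tlsarch.gene_sets import GeneSet
from tlsarch.matrix import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class ScoreVector:
    scores: pd.Series  # per cell, in [0, 1]
    gene_set: str
    top_fraction: float
    n_set_genes_present: int


def aucell_score(
    matrix: CountMatrix,
    gene_set: GeneSet,
    top_fraction: float = 0.05,
    tie_seed: int | None = None,
) -> ScoreVector:
    """AUC of the gene-set recovery curve per cell.

    Genes are ranked per cell by descending expression. With threshold
    k = ceil(top_fraction x n_genes) and cum(r) the number of set genes at
    ranks 1..r, the raw area is sum_{r=1..k} cum(r) and the score is that
    area divided by its maximum sum_{r=1..k} min(r, m) for m set genes
    present — 1 when the set occupies the very top ranks, 0 when no set gene
    enters the top k.

    ``tie_seed`` switches to a seeded random tie-break instead of the
    deterministic gene-index order.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    present = matrix.gene_ids.isin(gene_set.genes)
    m = int(present.sum())
    if m == 0:
        raise ValueError(f"no genes of set {gene_set.name!r} present in matrix")
    missing = gene_set.genes - set(matrix.gene_ids)
    if missing:
        logger.warning(
            "%d/%d genes of %s absent from matrix", len(missing),
            len(gene_set), gene_set.name,
        )

    n_genes = matrix.n_genes
    k = int(np.ceil(top_fraction * n_genes))
    X = matrix.X.toarray().astype(float)
    if tie_seed is not None:
        rng = np.random.default_rng(tie_seed)
        jitter = rng.random(X.shape) * 1e-9
        order = np.argsort(-(X + jitter), axis=1, kind="stable")
    else:
        order = np.argsort(-X, axis=1, kind="stable")  # ties -> gene index

    hits = np.asarray(present)[order]  # (cells, genes) membership along ranks
    cum = np.cumsum(hits[:, :k], axis=1)
    raw = cum.sum(axis=1)
    max_area = np.minimum(np.arange(1, k + 1), m).sum()
    scores = raw / max_area
    return ScoreVector(
        scores=pd.Series(scores, index=matrix.cell_ids, name=gene_set.name),
        gene_set=gene_set.name,
        top_fraction=top_fraction,
        n_set_genes_present=m,
    )


def scale_module_score(
    matrix: CountMatrix,
    gene_set: GeneSet,
    cell_order: list | np.ndarray,
    target_sum: float = 1e4,
) -> pd.Series:
    """Scaled mean module score along a given cell ordering.

    Expression is library-size normalized to ``target_sum`` and log1p
    transformed, z-scored per gene across cells, averaged over the set genes
    and min-max scaled to [0, 1], then emitted in ``cell_order`` (e.g. a
    pseudotime ordering computed upstream). Zero-variance genes are dropped
    from the mean with a warning; if every cell scores identically the
    min-max guard returns 0.5.
    """
    cell_order = pd.Index(cell_order)
    if not cell_order.sort_values().equals(matrix.cell_ids.sort_values()):
        raise ValueError("cell_order must be a permutation of the matrix cells")
    present = matrix.gene_ids.isin(gene_set.genes)
    if not present.any():
        raise ValueError(f"no genes of set {gene_set.name!r} present")

    X = matrix.X.toarray().astype(float)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    logX = np.log1p(X / lib * target_sum)[:, np.asarray(present)]

    mu = logX.mean(axis=0)
    sd = logX.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance set genes", int((~keep).sum()))
    if keep.any():
        z = (logX[:, keep] - mu[keep]) / sd[keep]
        score = z.mean(axis=1)
    else:
        score = np.zeros(matrix.n_cells)

    lo, hi = score.min(), score.max()
    scaled = (score - lo) / (hi - lo) if hi > lo else np.full_like(score, 0.5)
    return pd.Series(scaled, index=matrix.cell_ids, name=gene_set.name).loc[cell_order]
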