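"""Cell and gene quality-control filters.

Thresholds follow the study's processing rules: cells are excluded when they
express fewer than 200 or more than 4,000 genes, carry more than 20%
mitochondrial content or more than 25,000 total UMIs, or have a doublet score
greater than 0.2; genes expressed in fewer than three cells are dropped. All
exclusion bounds are strict inequalities, so boundary cells (exactly 200
genes, doublet score exactly 0.2, ...) are kept.

Doublet scores are an upstream input (e.g. Scrublet); this module only
thresholds them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tlsarch.matrix import CountMatrix

logger = logging.getLogger(__name__)

#: Fixed order used to attribute each removed cell to the first failing rule.
RULE_ORDER = ("genes_low", "genes_high", "mito", "umi", "doublet")


@dataclass
class QCReport:
    """Accounting of a cell-filter pass."""

    n_input: int
    n_kept: int
    removed_by_rule: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept


def compute_cell_qc(
    matrix: CountMatrix,
    mito_genes: set | None = None,
    doublet_scores: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-cell QC metrics: genes detected, total UMIs, mitochondrial %.

    Parameters
    ----------
    matrix
        Cells x genes counts.
    mito_genes
        Gene symbols treated as mitochondrial. Defaults to symbols with the
        human ``MT-`` prefix. Symbols absent from the matrix are warned about.
    doublet_scores
        Optional per-cell doublet scores (index = cell id), carried through.

    Returns
    -------
    DataFrame indexed by cell id with columns ``n_genes``, ``total_umi``,
    ``pct_mito`` and, when provided, ``doublet_score``. ``pct_mito`` is 0 for
    all-zero cells.
    """
    if matrix.n_cells == 0 or matrix.n_genes == 0:
        raise ValueError("empty count matrix")
    if mito_genes is None:
        mito_mask = matrix.gene_ids.str.startswith("MT-")
    else:
        mito_genes = set(mito_genes)
        missing = mito_genes - set(matrix.gene_ids)
        if missing:
            logger.warning(
                "%d mitochondrial genes absent from matrix: %s",
                len(missing), sorted(missing)[:5],
            )
        mito_mask = matrix.gene_ids.isin(mito_genes)

    X = matrix.X
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    mito = np.asarray(X[:, np.asarray(mito_mask)].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(total > 0, 100.0 * mito / np.maximum(total, 1), 0.0)

    qc = pd.DataFrame(
        {
            "n_genes": n_genes.astype(int),
            "total_umi": total.astype(int),
            "pct_mito": pct_mito,
        },
        index=matrix.cell_ids,
    )
    if doublet_scores is not None:
        qc["doublet_score"] = doublet_scores.reindex(matrix.cell_ids)
    return qc


def apply_cell_filters(
    qc: pd.DataFrame,
    min_genes: int = 200,
    max_genes: int = 4000,
    max_pct_mito: float = 20.0,
    max_umi: int = 25000,
    max_doublet: float = 0.2,
) -> tuple[pd.Series, QCReport]:
    """Keep-mask for cells under the study's exclusion rules.

    A cell is kept iff ``min_genes <= n_genes <= max_genes`` and
    ``pct_mito <= max_pct_mito`` and ``total_umi <= max_umi`` and
    ``doublet_score <= max_doublet``. If ``doublet_score`` is absent that
    rule is skipped with a warning. The report attributes each removed cell
    to its first failing rule in :data:`RULE_ORDER`; the mask itself is the
    conjunction of all rules.
    """
    fails = {
        "genes_low": qc["n_genes"] < min_genes,
        "genes_high": qc["n_genes"] > max_genes,
        "mito": qc["pct_mito"] > max_pct_mito,
        "umi": qc["total_umi"] > max_umi,
    }
    if "doublet_score" in qc.columns and qc["doublet_score"].notna().any():
        fails["doublet"] = qc["doublet_score"] > max_doublet
    else:
        logger.warning("no doublet scores present; doublet rule skipped")
        fails["doublet"] = pd.Series(False, index=qc.index)

    keep = ~pd.concat(fails, axis=1).any(axis=1)

    attributed = pd.Series(False, index=qc.index)
    removed_by_rule = {}
    for rule in RULE_ORDER:
        first_fail = fails[rule] & ~attributed
        removed_by_rule[rule] = int(first_fail.sum())
        attributed |= fails[rule]
    report = QCReport(
        n_input=len(qc), n_kept=int(keep.sum()), removed_by_rule=removed_by_rule
    )
    return keep, report


def apply_gene_filter(matrix: CountMatrix, min_cells: int = 3) -> CountMatrix:
    """Drop genes expressed (count > 0) in fewer than ``min_cells`` cells.

    A gene detected in exactly ``min_cells`` cells is retained; the cell set
    is unchanged.
    """
    n_cells_per_gene = np.asarray((matrix.X > 0).sum(axis=0)).ravel()
    return matrix.subset_genes(n_cells_per_gene >= min_cells)


def qc_pipeline(
    matrix: CountMatrix,
    mito_genes: set | None = None,
    doublet_scores: pd.Series | None = None,
    min_cells: int = 3,
    recompute_after_gene_filter: bool = True,
    **thresholds,
) -> tuple[CountMatrix, pd.DataFrame, QCReport]:
    """Gene filter, then cell QC + filters, in the study's order.

    ``recompute_after_gene_filter`` controls whether n_genes / totals are
    recomputed on the gene-filtered matrix before thresholding (default yes).
    """
    filtered = apply_gene_filter(matrix, min_cells=min_cells)
    basis = filtered if recompute_after_gene_filter else matrix
    qc = compute_cell_qc(basis, mito_genes=mito_genes, doublet_scores=doublet_scores)
    keep, report = apply_cell_filters(qc, **thresholds)
    out = filtered.subset_cells(keep.to_numpy())
    logger.info(
        "QC: %d -> %d cells, %d -> %d genes",
        matrix.n_cells, out.n_cells, matrix.n_genes, out.n_genes,
    )
    return out, qc, report
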