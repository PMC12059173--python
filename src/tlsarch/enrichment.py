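"""Compositional enrichment of cell clusters across TLS statuses.

Per-cluster enrichment is quantified with a binomial GLM with a logit link:
membership of a cell in the cluster (one-vs-rest) is modeled as a binary
choice with TLS status as the factor. Contrasts between statuses are the
differences of estimated marginal means on the logit scale — for a single
factor these are the empirical logits, so the contrast equals the log odds
ratio of the corresponding 2x2 contingency table. Results are reported as
log2-transformed odds ratios with Wald standard errors and two-sided p-values,
Bonferroni-adjusted over the rendered grid of (cluster x contrast) tests.

Cells are pooled across samples within status by default (binary-choice
framing); a per-sample aggregation mode is available, which leaves the
maximum-likelihood estimate unchanged (the model has only the status factor,
so the binomial likelihood pools counts either way) but keeps sample-level
rows in the fit for diagnostics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class EnrichmentResult:
    """One cluster x status-contrast enrichment estimate."""

    cluster: str
    contrast: tuple[str, str]  # (status_a, status_b): a vs b
    log2_or: float
    se: float
    p: float
    p_adj: float
    n_family: int
    zero_corrected: bool = False

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["contrast"] = f"{self.contrast[0]}_vs_{self.contrast[1]}"
        return d


def _membership_table(
    cells: pd.DataFrame,
    cluster: str,
    statuses: tuple[str, str],
    cluster_field: str = "subcluster",
    status_field: str = "tls_status",
    sample_field: str = "sample_id",
    per_sample: bool = False,
) -> pd.DataFrame:
    """Success/failure counts of cluster membership per status (or sample)."""
    sub = cells[cells[status_field].isin(statuses)]
    member = (sub[cluster_field] == cluster).astype(int)
    keys = [status_field, sample_field] if per_sample else [status_field]
    grouped = member.groupby([sub[k] for k in keys], observed=True)
    tab = grouped.agg(successes="sum", total="count").reset_index()
    tab["failures"] = tab["total"] - tab["successes"]
    return tab


def fit_cluster_enrichment(
    cells: pd.DataFrame,
    cluster: str,
    contrast: tuple[str, str],
    cluster_field: str = "subcluster",
    status_field: str = "tls_status",
    sample_field: str = "sample_id",
    per_sample: bool = False,
    n_family: int = 1,
) -> EnrichmentResult:
    """Binomial-logit enrichment of ``cluster`` for status ``contrast[0]``
    versus ``contrast[1]``.

    The log2 odds ratio is the estimated-marginal-mean difference on the
    logit scale divided by ln 2, with Wald standard error and two-sided
    p-value. When the cluster is empty (or exhaustive) in either status, 0.5
    is added to all four cells of the implied 2x2 table (Haldane–Anscombe)
    and the model refitted on the pseudo-counts; the result is flagged.

    Raises
    ------
    ValueError
        If the cluster is absent from the table or a status has no cells.
    """
    a, b = contrast
    if not (cells[cluster_field] == cluster).any():
        raise ValueError(f"cluster {cluster!r} absent from cell table")
    for s in contrast:
        if not (cells[status_field] == s).any():
            raise ValueError(f"status {s!r} has no cells")

    tab = _membership_table(
        cells, cluster, contrast, cluster_field, status_field, sample_field,
        per_sample=per_sample,
    )
    by_status = tab.groupby(status_field, observed=True)[["successes", "failures"]].sum()
    corrected = bool((by_status.to_numpy() == 0).any())
    if corrected:
        # Haldane–Anscombe: +0.5 on every cell of the 2x2, refit on pseudo-data
        tab = by_status.loc[[a, b]].reset_index()
        tab[["successes", "failures"]] += 0.5

    endog = tab[["successes", "failures"]].to_numpy(dtype=float)
    exog = sm.add_constant((tab[status_field] == a).astype(float).to_numpy())
    import warnings

    with warnings.catch_warnings():
        # the status-aggregated model is saturated (df_resid = 0), which
        # statsmodels flags as perfect separation; the fit is still exact
        warnings.simplefilter("ignore")
        fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()

    logit_diff = fit.params[1]
    se_logit = fit.bse[1]
    z = logit_diff / se_logit if se_logit > 0 else np.inf * np.sign(logit_diff)
    from scipy import stats

    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    ln2 = np.log(2.0)
    return EnrichmentResult(
        cluster=cluster,
        contrast=(a, b),
        log2_or=float(logit_diff / ln2),
        se=float(se_logit / ln2),
        p=p,
        p_adj=min(1.0, p * n_family),
        n_family=n_family,
        zero_corrected=corrected,
    )


def enrichment_grid(
    cells: pd.DataFrame,
    compartment: str | None = None,
    lineage_field: str = "lineage",
    cluster_field: str = "subcluster",
    status_field: str = "tls_status",
    statuses: list[str] | None = None,
    max_neglog10: float = 10.0,
    per_sample: bool = False,
) -> pd.DataFrame:
    """All (cluster x pairwise status contrast) enrichment results.

    The Bonferroni family is the full rendered grid: n_clusters x n_pairs
    tests. Emits dot-plot-ready columns: ``color`` (log2 OR) and ``size``
    (-log10 adjusted p, capped at ``max_neglog10``).
    """
    sub = cells if compartment is None else cells[cells[lineage_field] == compartment]
    if statuses is None:
        statuses = list(pd.unique(sub[status_field]))
    if len(statuses) < 2:
        raise ValueError("need at least two statuses")
    clusters = list(pd.unique(sub[cluster_field]))
    if not clusters:
        raise ValueError("no clusters in compartment")
    pairs = list(itertools.combinations(statuses, 2))
    n_family = len(clusters) * len(pairs)

    rows = []
    for cluster in clusters:
        for pair in pairs:
            res = fit_cluster_enrichment(
                sub, cluster, pair,
                cluster_field=cluster_field, status_field=status_field,
                per_sample=per_sample, n_family=n_family,
            )
            rows.append(res.to_dict())
    out = pd.DataFrame(rows)
    with np.errstate(divide="ignore"):
        out["size"] = np.minimum(-np.log10(out["p_adj"]), max_neglog10)
    out["color"] = out["log2_or"]
    return out
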