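"""Nearest-neighbor distance statistics for multiplex-imaging point patterns.

Each tissue core is a set of phenotype-labeled cell positions (x, y in
micrometers). For an ordered phenotype pair (from, to), every from-cell's
distance to its nearest to-cell is computed (self excluded by cell id when
from = to, so coincident distinct cells count at distance 0) and summarized
per core by the median; cores are grouped by TLS status for reporting. Raw
Euclidean distances, no edge correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

REQUIRED_COLUMNS = ("core_id", "tls_status", "x", "y", "phenotype")


def pairwise_distances(points: pd.DataFrame) -> np.ndarray:
    """Symmetric Euclidean distance matrix over all cells of one core."""
    if len(points) < 2:
        raise ValueError("need at least two cells")
    xy = points[["x", "y"]].to_numpy(dtype=float)
    return cdist(xy, xy)


def nn_distance(points: pd.DataFrame, from_phenotype: str, to_phenotype: str) -> pd.Series:
    """Per from-cell distance to the nearest to-cell, in input cell order.

    Empty when either phenotype is missing; a from-cell with no eligible
    neighbor (single cell, from = to) yields NaN.
    """
    src = points[points["phenotype"] == from_phenotype]
    dst = points[points["phenotype"] == to_phenotype]
    if src.empty or dst.empty:
        return pd.Series(dtype=float, name="nn_distance")

    src_xy = src[["x", "y"]].to_numpy(dtype=float)
    dst_xy = dst[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(dst_xy)
    if from_phenotype != to_phenotype:
        d, _ = tree.query(src_xy, k=1)
    else:
        if len(dst) < 2:
            return pd.Series(
                np.nan, index=_ids(src), name="nn_distance", dtype=float
            )
        # k=2: nearest excluding self (by cell id; coincident cells allowed)
        d2, idx = tree.query(src_xy, k=2)
        src_pos = {cid: i for i, cid in enumerate(_ids(dst))}
        d = np.empty(len(src))
        for row, cid in enumerate(_ids(src)):
            self_i = src_pos[cid]
            take = 1 if idx[row, 0] == self_i else 0
            d[row] = d2[row, take]
    return pd.Series(d, index=_ids(src), name="nn_distance")


def _ids(df: pd.DataFrame) -> pd.Index:
    return pd.Index(df["cell_id"]) if "cell_id" in df.columns else df.index


def proximity_summary(
    cores: pd.DataFrame,
    pairs: list[tuple[str, str]],
    pooled: bool = False,
) -> pd.DataFrame:
    """Median nearest-neighbor distances per core (or pooled per status).

    One row per (core, pair) — or per (status, pair) when ``pooled`` — with
    the median NN distance and the counts of source/target cells. Cores
    missing a phenotype yield a row with a missing median.
    """
    rows = []
    for core_id, core in cores.groupby("core_id", observed=True):
        status = core["tls_status"].iloc[0]
        for frm, to in pairs:
            d = nn_distance(core, frm, to)
            rows.append(
                {
                    "core_id": core_id,
                    "tls_status": status,
                    "from_phenotype": frm,
                    "to_phenotype": to,
                    "median_nn": float(d.median()) if len(d) else np.nan,
                    "n_from": int((core["phenotype"] == frm).sum()),
                    "n_to": int((core["phenotype"] == to).sum()),
                }
            )
    out = pd.DataFrame(rows)
    if pooled:
        # pool per-cell NN distances (still computed within each core) across
        # cores of a status before taking the median
        pooled_rows = []
        for (status, frm, to), grp in out.groupby(
            ["tls_status", "from_phenotype", "to_phenotype"], observed=True
        ):
            dists = []
            for core_id in grp["core_id"]:
                core = cores[cores["core_id"] == core_id]
                dists.append(nn_distance(core, frm, to))
            d = pd.concat(dists) if dists else pd.Series(dtype=float)
            pooled_rows.append(
                {"tls_status": status, "from_phenotype": frm, "to_phenotype": to,
                 "median_nn": float(d.median()) if len(d) else np.nan,
                 "n_from": int(grp["n_from"].sum()), "n_to": int(grp["n_to"].sum())}
            )
        return pd.DataFrame(pooled_rows)
    return out


def status_medians(summary: pd.DataFrame) -> pd.DataFrame:
    """Median of per-core medians by (status, pair) — the reporting grouping."""
    return (
        summary.dropna(subset=["median_nn"])
        .groupby(["tls_status", "from_phenotype", "to_phenotype"], observed=True)[
            "median_nn"
        ]
        .median()
        .reset_index()
    )
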