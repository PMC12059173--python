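"""TCR/BCR clonotype calling, expansion, diversity and sharing.

Chain records follow the AIRR Rearrangement vocabulary (``cell_id``,
``locus``, ``junction`` — the CDR3 nucleotide sequence, ``v_call``,
``j_call``). Cells carrying both TCR and BCR chains are "ambiguous"; cells
with more than two chains of one paired arm (a third alpha/beta or
heavy/light chain beyond one secondary) are "multichain"; both are excluded
from clonotype calling.

A TCR clonotype is a unique TRA+TRB pair: exact CDR3 nucleotide identity on
both arms (all chains of each arm enter the key, so cells with a secondary
alpha form distinct keys from single-alpha cells). BCR clonotypes are called
hierarchically: heavy chains are partitioned by (V gene, J gene, junction
length) and single-linkage clustered on the normalized Hamming distance of
their junctions, cut at a threshold estimated from the bimodal
distance-to-nearest distribution (valley between the within-clone and
between-clone modes), falling back to 0.15 when no bimodality is detected.

A clonotype is "expanded"/"clonal" when present in at least two cells.
Diversity is summarized per group by Shannon entropy (natural log) and D50,
the percent of clonotypes (largest first) needed to cover half the cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

TR_LOCI = {"TRA", "TRB"}
IG_LOCI = {"IGH", "IGK", "IGL"}
DEFAULT_BCR_THRESHOLD = 0.15


@dataclass
class ClonotypeAssignment:
    """Partition of cells into clonotypes.

    ``cell_to_clonotype`` maps cell_id -> clonotype_id for assigned cells
    only; ambiguous/multichain cells never receive a clonotype.
    ``clone_size`` counts cells per clonotype over all assigned cells.
    """

    cell_to_clonotype: pd.Series
    receptor_class: pd.Series
    clone_size: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.clone_size = self.cell_to_clonotype.value_counts()

    def expanded_clonotypes(self) -> pd.Index:
        """Clonotypes present in at least two cells."""
        return self.clone_size.index[self.clone_size >= 2]

    def is_clonal(self) -> pd.Series:
        """Per assigned cell: does its clonotype have >= 2 cells."""
        return self.cell_to_clonotype.map(self.clone_size) >= 2


@dataclass
class DiversityResult:
    group: str
    shannon: float
    d50: float
    n_cells: int
    n_clonotypes: int


def _dedup(chains: pd.DataFrame) -> pd.DataFrame:
    dup = chains.duplicated(subset=["cell_id", "locus", "junction"])
    if dup.any():
        logger.warning("deduplicated %d duplicate chain records", int(dup.sum()))
        chains = chains[~dup]
    return chains


def classify_cells(chains: pd.DataFrame) -> pd.Series:
    """Receptor class per cell: TCR, BCR, ambiguous, or multichain.

    ambiguous: the cell has at least one TR locus and one IG locus.
    multichain: more than two chains of a single paired arm of the cell's
    receptor class (TRA | TRB for TCR; IGH | IGK+IGL for BCR) — i.e. more
    than two receptor pairs' worth of chains. Two chains of one arm
    (a secondary alpha or light chain) are allowed.
    """
    chains = _dedup(chains)
    out = {}
    for cell_id, grp in chains.groupby("cell_id", sort=False):
        loci = grp["locus"]
        has_tr = loci.isin(TR_LOCI).any()
        has_ig = loci.isin(IG_LOCI).any()
        if has_tr and has_ig:
            out[cell_id] = "ambiguous"
            continue
        if has_tr:
            arms = [(loci == "TRA").sum(), (loci == "TRB").sum()]
            cls = "TCR"
        else:
            arms = [(loci == "IGH").sum(), loci.isin({"IGK", "IGL"}).sum()]
            cls = "BCR"
        out[cell_id] = "multichain" if max(arms) > 2 else cls
    return pd.Series(out, name="receptor_class")


def define_tcr_clonotypes(
    chains: pd.DataFrame, receptor_class: pd.Series | None = None
) -> ClonotypeAssignment:
    """Clonotypes for TCR cells by exact paired-CDR3 nucleotide identity.

    The clonotype key is (sorted TRA junctions, sorted TRB junctions); both
    arms must match exactly. Single-arm cells form keys distinct from any
    paired key.
    """
    chains = _dedup(chains)
    if receptor_class is None:
        receptor_class = classify_cells(chains)
    tcr_cells = receptor_class.index[receptor_class == "TCR"]
    sub = chains[chains["cell_id"].isin(tcr_cells)]

    keys = {}
    for cell_id, grp in sub.groupby("cell_id", sort=False):
        tra = tuple(sorted(grp.loc[grp["locus"] == "TRA", "junction"]))
        trb = tuple(sorted(grp.loc[grp["locus"] == "TRB", "junction"]))
        keys[cell_id] = (tra, trb)

    key_to_id = {}
    assignment = {}
    for cell_id in sorted(keys):  # stable ids independent of record order
        key = keys[cell_id]
        if key not in key_to_id:
            key_to_id[key] = f"TCR_{len(key_to_id):05d}"
        assignment[cell_id] = key_to_id[key]
    return ClonotypeAssignment(
        pd.Series(assignment, name="clonotype_id", dtype=object), receptor_class
    )


def _first_call(call: str) -> str:
    """Resolve ambiguous multi-gene V/J annotations to the first listed."""
    return str(call).split(",")[0].strip()


def _hamming_matrix(seqs: list[str]) -> np.ndarray:
    """Pairwise normalized Hamming distances of equal-length sequences."""
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)
    neq = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    return neq / arr.shape[1]


def _heavy_partitions(chains: pd.DataFrame, receptor_class: pd.Series):
    """IGH chains of BCR cells grouped by (V gene, J gene, junction length)."""
    bcr_cells = receptor_class.index[receptor_class == "BCR"]
    heavy = chains[
        (chains["locus"] == "IGH") & chains["cell_id"].isin(bcr_cells)
    ].copy()
    heavy["v_first"] = heavy["v_call"].map(_first_call)
    heavy["j_first"] = heavy["j_call"].map(_first_call)
    heavy["jlen"] = heavy["junction"].str.len()
    # one heavy chain per cell enters clustering (first by junction order,
    # deterministic); secondary heavies do not alter the clone partition
    heavy = heavy.sort_values(["cell_id", "junction"]).drop_duplicates("cell_id")
    return heavy.groupby(["v_first", "j_first", "jlen"], sort=True)


def dist_to_nearest(chains: pd.DataFrame, receptor_class: pd.Series | None = None) -> np.ndarray:
    """Each heavy chain's normalized Hamming distance to its nearest
    non-identical neighbor within its (V, J, junction length) partition.

    Chains without a non-identical partner in their partition contribute
    nothing. Duplicating every sequence leaves the result unchanged.
    """
    chains = _dedup(chains)
    if receptor_class is None:
        receptor_class = classify_cells(chains)
    dists = []
    for _, part in _heavy_partitions(chains, receptor_class):
        seqs = part["junction"].tolist()
        if len(set(seqs)) < 2:
            continue
        D = _hamming_matrix(seqs)
        D[D == 0] = np.inf  # skip identical sequences (incl. self)
        nn = D.min(axis=1)
        dists.extend(nn[np.isfinite(nn)])
    return np.asarray(dists)


def estimate_bcr_threshold(
    chains: pd.DataFrame,
    receptor_class: pd.Series | None = None,
    min_chains: int = 20,
    fallback: float = DEFAULT_BCR_THRESHOLD,
) -> float:
    """Clonal distance threshold from the distance-to-nearest distribution.

    With clonally related sequences present, the distribution is bimodal
    (a within-clone mode near 0 and a between-clone mode further out); the
    threshold is the minimum-density valley between the two largest modes of
    a Gaussian KDE. Falls back to ``fallback`` with a warning when fewer
    than ``min_chains`` heavy chains are available or no bimodality is found.
    """
    chains = _dedup(chains)
    if receptor_class is None:
        receptor_class = classify_cells(chains)
    n_heavy = int(
        (
            (chains["locus"] == "IGH")
            & chains["cell_id"].isin(receptor_class.index[receptor_class == "BCR"])
        ).sum()
    )
    if n_heavy < min_chains:
        logger.warning("only %d heavy chains; falling back to %.2f", n_heavy, fallback)
        return fallback
    d = dist_to_nearest(chains, receptor_class)
    d = np.unique(d)  # multiplicity-invariant support of the distribution
    if len(d) < 2 or d.std() == 0:
        logger.warning("degenerate distance-to-nearest; falling back to %.2f", fallback)
        return fallback

    from scipy.stats import gaussian_kde

    grid = np.linspace(0, max(1.0, d.max()), 512)
    dens = gaussian_kde(d)(grid)
    # interior local maxima (modes) of the smoothed distribution
    is_max = np.r_[False, (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:]), False]
    modes = np.flatnonzero(is_max)
    if len(modes) < 2:
        logger.warning("unimodal distance-to-nearest; falling back to %.2f", fallback)
        return fallback
    top2 = sorted(sorted(modes, key=lambda i: dens[i], reverse=True)[:2])
    lo, hi = top2
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    return float(grid[valley])


def define_bcr_clonotypes(
    chains: pd.DataFrame,
    threshold: float,
    receptor_class: pd.Series | None = None,
) -> ClonotypeAssignment:
    """Hierarchical BCR clonotypes within V/J/junction-length partitions.

    Within each (IGH V gene, J gene, junction length) partition, heavy-chain
    junctions are single-linkage clustered on normalized Hamming distance and
    the dendrogram cut at ``threshold`` (merges at distance <= threshold);
    each cluster is one clonotype. Light chains do not enter the distance.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    chains = _dedup(chains)
    if receptor_class is None:
        receptor_class = classify_cells(chains)

    assignment = {}
    n_clones = 0
    for (v, j, jlen), part in _heavy_partitions(chains, receptor_class):
        part = part.sort_values("cell_id")
        seqs = part["junction"].tolist()
        assert all(len(s) == jlen for s in seqs)
        if len(seqs) == 1:
            labels = np.array([1])
        else:
            D = _hamming_matrix(seqs)
            Z = linkage(squareform(D, checks=False), method="single")
            labels = fcluster(Z, t=threshold, criterion="distance")
        for cell_id, lab in zip(part["cell_id"], labels):
            assignment[cell_id] = f"BCR_{v}_{j}_{jlen}_{lab:04d}"
        n_clones += len(set(labels))
    logger.info("BCR clustering: %d cells -> %d clonotypes", len(assignment), n_clones)
    return ClonotypeAssignment(
        pd.Series(assignment, name="clonotype_id", dtype=object), receptor_class
    )


def clonal_diversity(
    assignment: ClonotypeAssignment,
    cells: pd.Index | None = None,
    group: str = "all",
) -> DiversityResult:
    """Shannon entropy (nats) and D50 of the clonotype distribution.

    With p_i the fraction of cells in clone i: shannon = -sum p_i ln p_i.
    D50 = 100 x (smallest number of clonotypes, largest first, whose
    cumulative cell fraction reaches >= 0.5) / n_clonotypes.
    """
    assigned = assignment.cell_to_clonotype
    if cells is not None:
        assigned = assigned[assigned.index.isin(cells)]
    if assigned.empty:
        raise ValueError(f"no assigned cells in group {group!r}")
    sizes = assigned.value_counts().to_numpy()
    p = sizes / sizes.sum()
    shannon = float(-(p * np.log(p)).sum())
    cum = np.cumsum(np.sort(p)[::-1])
    k = int(np.argmax(cum >= 0.5)) + 1  # first index reaching half the cells
    return DiversityResult(
        group=group,
        shannon=shannon,
        d50=100.0 * k / len(sizes),
        n_cells=int(sizes.sum()),
        n_clonotypes=len(sizes),
    )


def diversity_by_group(
    assignment: ClonotypeAssignment, cells: pd.DataFrame, group_field: str
) -> pd.DataFrame:
    rows = []
    for gname, sub in cells.groupby(group_field, observed=True):
        idx = pd.Index(sub["cell_id"]) if "cell_id" in sub.columns else sub.index
        try:
            rows.append(clonal_diversity(assignment, idx, str(gname)).__dict__)
        except ValueError:
            continue
    return pd.DataFrame(rows)


def _membership(assignment: ClonotypeAssignment, cells: pd.DataFrame, cluster_field: str):
    """clonotype -> set of clusters it occupies (cells indexed by cell_id)."""
    cell_ids = cells["cell_id"] if "cell_id" in cells.columns else cells.index.to_series()
    clusters = pd.Series(
        cells[cluster_field].to_numpy(), index=pd.Index(cell_ids), name="cluster"
    )
    df = assignment.cell_to_clonotype.rename("clonotype").to_frame()
    df["cluster"] = clusters.reindex(df.index)
    return df.dropna(subset=["cluster"])


def sharing_matrix(
    assignment: ClonotypeAssignment,
    cells: pd.DataFrame,
    cluster_field: str = "subcluster",
    status_field: str | None = None,
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Counts of clonotypes shared between cluster pairs.

    Entry (i, j) is the number of clonotypes with at least one cell in
    cluster i and one in cluster j; the diagonal counts clonotypes present
    in the cluster. With ``status_field`` given, also returns the per-status
    decomposition (the same matrix restricted to each status's cells).
    """
    df = _membership(assignment, cells, cluster_field)
    labels = sorted(df["cluster"].unique())

    def _matrix(sub: pd.DataFrame) -> pd.DataFrame:
        occupancy = {
            lab: set(sub.loc[sub["cluster"] == lab, "clonotype"]) for lab in labels
        }
        M = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
        for i, a in enumerate(labels):
            for b in labels[i:]:
                n = len(occupancy[a] & occupancy[b])
                M.loc[a, b] = M.loc[b, a] = n
        return M

    full = _matrix(df)
    if status_field is None:
        return full
    cell_ids = cells["cell_id"] if "cell_id" in cells.columns else cells.index.to_series()
    status = pd.Series(cells[status_field].to_numpy(), index=pd.Index(cell_ids))
    df["status"] = status.reindex(df.index)
    by_status = {s: _matrix(sub) for s, sub in df.groupby("status", observed=True)}
    return full, by_status


def shared_feature_fraction(
    assignment: ClonotypeAssignment,
    cells: pd.DataFrame,
    group_a: set,
    group_b: set,
    cluster_field: str = "subcluster",
    expanded_only: bool = True,
    by: str | None = None,
) -> pd.DataFrame:
    """Fraction of clonotypes spanning two disjoint cluster groups.

    Numerator: clonotypes (clone size >= 2 when ``expanded_only``) with at
    least one cell in ``group_a`` and one in ``group_b``; denominator: such
    clonotypes with any cell in the union. Computed per grouping unit
    (``by`` — e.g. sample or status); an empty denominator yields NaN.
    """
    group_a, group_b = set(group_a), set(group_b)
    if group_a & group_b:
        raise ValueError("cluster groups must be disjoint")
    df = _membership(assignment, cells, cluster_field)
    if expanded_only:
        keep = assignment.expanded_clonotypes()
        df = df[df["clonotype"].isin(keep)]
    if by is not None:
        cell_ids = cells["cell_id"] if "cell_id" in cells.columns else cells.index.to_series()
        unit = pd.Series(cells[by].to_numpy(), index=pd.Index(cell_ids))
        df = df.assign(unit=unit.reindex(df.index))
        groups = df.groupby("unit", observed=True)
    else:
        groups = [("all", df)]

    rows = []
    for uname, sub in groups:
        in_a = set(sub.loc[sub["cluster"].isin(group_a), "clonotype"])
        in_b = set(sub.loc[sub["cluster"].isin(group_b), "clonotype"])
        denom = len(in_a | in_b)
        frac = len(in_a & in_b) / denom if denom else np.nan
        rows.append({"unit": uname, "fraction": frac, "n_spanning": len(in_a & in_b),
                     "n_total": denom})
    return pd.DataFrame(rows)
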