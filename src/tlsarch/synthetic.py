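"""Synthetic pipeline inputs with known planted parameters.

Every downstream stage gets an input generator whose ground truth is emitted
alongside the data, so each statistic has a parameter-recovery test without
access to the study's controlled-access accessions:

* cell tables with multinomial cluster composition whose per-cluster
  one-vs-rest odds differ between TLS statuses by exact planted log2 odds
  ratios (the inverse of the composition GLM),
* negative-binomial count matrices with signature genes elevated in flagged
  cells (feeds AUC scoring and QC),
* paired-chain receptor tables with power-law clone sizes, planted
  cross-cluster clonotype sharing, and designated ambiguous/multichain
  fractions (feeds clonotype calling, diversity, sharing),
* spot x cell-type abundance tables where co-localized pairs share a Gamma
  latent factor (feeds the co-occurrence score),
* imaging point patterns: Neyman–Scott clustered phenotypes (optionally
  sharing parents across phenotypes) versus complete spatial randomness
  (feeds nearest-neighbor proximity).

All generators are pure functions of their spec including its seed. One
global seed expands to per-generator child seeds by fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from tlsarch.gene_sets import GeneSet
from tlsarch.matrix import CountMatrix

DEFAULT_STATUSES = ("nTLS", "imTLS", "mTLS")

#: fixed offsets expanding one global seed into per-generator child seeds
SEED_OFFSETS = {
    "composition": 1, "embedding": 2, "expression": 3, "repertoire": 4,
    "spots": 5, "points": 6,
}


def child_seed(global_seed: int, generator: str) -> int:
    return (int(global_seed) * 7 + SEED_OFFSETS[generator]) % (2**31 - 1)


# ---------------------------------------------------------------------------
# cluster composition


@dataclass
class CompositionSpec:
    """Multinomial cluster composition with planted status effects.

    ``planted_log2_or`` maps (cluster, status) to the log2 odds ratio of
    one-vs-rest cluster membership in that status relative to the first
    (reference) status. The planted odds ratio is exact: the target
    cluster's odds are multiplied by 2**lor and the remaining probability
    mass redistributed over the other clusters proportionally to base.
    """

    statuses: tuple[str, ...] = DEFAULT_STATUSES
    samples_per_status: int = 4
    cells_per_sample: int = 500
    clusters: tuple[str, ...] = ("c1", "c2", "c3", "c4")
    base_proportions: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    planted_log2_or: dict = field(default_factory=dict)
    cluster_lineages: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.base_proportions, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1) > 1e-12:
            raise ValueError("base_proportions must be nonnegative and sum to 1")
        if len(p) != len(self.clusters):
            raise ValueError("base_proportions length must match clusters")
        if self.cells_per_sample < 1 or self.samples_per_status < 1:
            raise ValueError("need at least one cell per sample and one sample")

    def status_proportions(self, status: str) -> np.ndarray:
        """Adjusted cluster proportions for one status (exact planted ORs)."""
        base = np.asarray(self.base_proportions, dtype=float)
        if status == self.statuses[0]:
            return base
        p = base.copy()
        planted = {}
        for (cluster, st), lor in self.planted_log2_or.items():
            if st != status:
                continue
            i = self.clusters.index(cluster)
            odds = base[i] / (1 - base[i]) * 2.0**lor
            planted[i] = odds / (1 + odds)
        if planted:
            rest = 1.0 - sum(planted.values())
            others = [i for i in range(len(base)) if i not in planted]
            other_mass = base[others].sum()
            if rest <= 0 or other_mass <= 0:
                raise ValueError(
                    f"adjusted proportions fail to normalize for status {status!r}"
                )
            for i, v in planted.items():
                p[i] = v
            p[others] = base[others] / other_mass * rest
        return p


def simulate_composition(spec: CompositionSpec) -> pd.DataFrame:
    """Cell table with sample, TLS status and cluster per cell."""
    rng = np.random.default_rng(spec.seed)
    frames = []
    cluster_arr = np.asarray(spec.clusters, dtype=object)
    for status in spec.statuses:
        probs = spec.status_proportions(status)
        for s in range(spec.samples_per_status):
            sample_id = f"{status}_s{s + 1}"
            draws = rng.choice(len(spec.clusters), size=spec.cells_per_sample, p=probs)
            frames.append(pd.DataFrame({
                "cell_id": [f"{sample_id}_cell{k:05d}"
                            for k in range(spec.cells_per_sample)],
                "sample_id": sample_id,
                "tls_status": status,
                "subcluster": cluster_arr[draws],
            }))
    cells = pd.concat(frames, ignore_index=True)
    lineages = spec.cluster_lineages or {}
    cells["lineage"] = cells["subcluster"].map(lambda c: lineages.get(c, "all"))
    return cells


def simulate_embedding(
    cells: pd.DataFrame,
    seed: int = 0,
    spread: float = 1.0,
    status_shift: dict | None = None,
) -> pd.DataFrame:
    """Attach 2-D embedding coordinates: a Gaussian blob per cluster.

    ``status_shift`` maps status -> (dx, dy) applied to that status's cells,
    planting a density mode shift recoverable by the KDE contrast.
    """
    rng = np.random.default_rng(seed)
    clusters = sorted(cells["subcluster"].unique())
    centers = {c: rng.uniform(-8, 8, size=2) for c in clusters}
    out = cells.copy()
    xy = np.stack([centers[c] for c in out["subcluster"]])
    xy = xy + rng.normal(scale=spread, size=(len(out), 2))
    if status_shift:
        for status, (dx, dy) in status_shift.items():
            m = (out["tls_status"] == status).to_numpy()
            xy[m] += (dx, dy)
    out["dim1"], out["dim2"] = xy[:, 0], xy[:, 1]
    return out


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    cells: pd.DataFrame,
    signature: GeneSet,
    effect: float,
    nb_dispersion: float = 2.0,
    seed: int = 0,
    n_genes: int = 200,
    base_mean: float = 2.0,
    positive_field: str = "signature_positive",
) -> CountMatrix:
    """Negative-binomial counts with signature genes elevated in flagged cells.

    Genes = the signature plus background genes up to ``n_genes`` total.
    Per-gene baseline means are lognormal around ``base_mean``; in cells
    flagged true in ``positive_field`` the signature means are multiplied by
    (1 + effect). Counts are Gamma–Poisson with shape ``nb_dispersion``
    (variance mu + mu^2/dispersion; the dispersion -> infinity limit is
    Poisson).
    """
    if effect < 0:
        raise ValueError("effect must be nonnegative")
    if len(signature) == 0:
        raise ValueError("empty gene set")
    if positive_field not in cells.columns:
        raise ValueError(f"cells must carry a boolean {positive_field!r} column")
    rng = np.random.default_rng(seed)
    sig_genes = sorted(signature.genes)
    n_bg = max(n_genes - len(sig_genes), 0)
    genes = sig_genes + [f"BG{i:04d}" for i in range(n_bg)]
    mu = base_mean * rng.lognormal(mean=0.0, sigma=0.5, size=len(genes))

    pos = cells[positive_field].to_numpy(dtype=bool)
    M = np.tile(mu, (len(cells), 1))
    M[np.ix_(pos, np.arange(len(sig_genes)))] *= 1.0 + effect

    lam = rng.gamma(shape=nb_dispersion, scale=M / nb_dispersion)
    counts = rng.poisson(lam)
    return CountMatrix(
        sp.csr_matrix(counts), pd.Index(cells["cell_id"]), pd.Index(genes)
    )


# ---------------------------------------------------------------------------
# receptor repertoire

_NT = np.array(list("ACGT"))
_JUNCTION_LENGTHS = (30, 33, 36, 39, 42, 45)


@dataclass
class RepertoireSpec:
    """Clone-size and sharing structure of a simulated repertoire.

    Clone sizes follow a zeta (discrete power-law) distribution with
    exponent ``clone_size_exponent`` truncated at the cluster's cell count.
    ``sharing_prob`` maps unordered cluster pairs to the probability that a
    clonotype homed in the first cluster is merged with one in the second,
    making it span both.
    """

    clone_size_exponent: float = 2.5
    sharing_prob: dict = field(default_factory=dict)
    ambiguous_frac: float = 0.0
    multichain_frac: float = 0.0
    bcr_mutation_rate: float = 0.02
    bcr_lineages: frozenset = frozenset({"B"})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clone_size_exponent <= 1:
            raise ValueError("clone_size_exponent must exceed 1")
        for p in (self.ambiguous_frac, self.multichain_frac, self.bcr_mutation_rate,
                  *self.sharing_prob.values()):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


def _random_junction(rng: np.random.Generator, length: int | None = None) -> str:
    if length is None:
        length = int(rng.choice(_JUNCTION_LENGTHS))
    return "".join(rng.choice(_NT, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        arr[i] = rng.choice(_NT[_NT != arr[i]])
    return "".join(arr)


def _clone_partition(rng: np.random.Generator, n_cells: int, exponent: float) -> list[int]:
    """Zeta clone sizes truncated at n_cells, covering all cells."""
    sizes = []
    left = n_cells
    while left > 0:
        s = min(int(rng.zipf(exponent)), left)
        sizes.append(s)
        left -= s
    return sizes


def simulate_repertoire(
    cells: pd.DataFrame, spec: RepertoireSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired-chain records plus ground-truth clonotype labels.

    T cells (lineage not in ``bcr_lineages``) get TRA+TRB chains with
    clonotype identity encoded by identical paired CDR3 nucleotide strings;
    B cells get IGH plus IGK or IGL, with heavy junctions mutated copies of
    a per-clone ancestor within a shared (V, J, length) partition. Cells
    drawn as ambiguous receive a chain of the other receptor class; cells
    drawn as multichain receive two extra chains of one arm. Ground truth
    records each cell's latent clonotype and intended class.
    """
    unknown = {a for a, _ in spec.sharing_prob} | {b for _, b in spec.sharing_prob}
    unknown -= set(cells["subcluster"].unique())
    if unknown:
        raise ValueError(f"sharing_prob references unknown clusters: {sorted(unknown)}")

    rng = np.random.default_rng(spec.seed)
    is_b = cells["lineage"].isin(spec.bcr_lineages).to_numpy()
    chains, truth = [], []
    clone_of_cell: dict[str, str] = {}
    clone_members: dict[str, list[str]] = {}
    clone_cluster: dict[str, str] = {}

    counter = 0
    for cls_name, sub in (("TCR", cells[~is_b]), ("BCR", cells[is_b])):
        for cluster, cgrp in sub.groupby("subcluster", observed=True, sort=True):
            ids = cgrp["cell_id"].tolist()
            rng.shuffle(ids)
            pos = 0
            for size in _clone_partition(rng, len(ids), spec.clone_size_exponent):
                cid = f"{cls_name}_true_{counter:05d}"
                counter += 1
                members = ids[pos:pos + size]
                pos += size
                clone_members[cid] = members
                clone_cluster[cid] = cluster
                for m in members:
                    clone_of_cell[m] = cid

    # planted sharing: merge clonotypes across cluster pairs
    merged_into: dict[str, str] = {}
    for (a, b), prob in sorted(spec.sharing_prob.items()):
        clones_a = [c for c, cl in clone_cluster.items() if cl == a and c not in merged_into]
        clones_b = [c for c, cl in clone_cluster.items() if cl == b and c not in merged_into]
        rng.shuffle(clones_b)
        bi = 0
        for ca in clones_a:
            if bi >= len(clones_b):
                break
            if rng.random() < prob:
                cb = clones_b[bi]
                bi += 1
                merged_into[cb] = ca
                for m in clone_members[cb]:
                    clone_of_cell[m] = ca
                clone_members[ca].extend(clone_members.pop(cb))

    # emit chains per (surviving) clonotype
    v_t = [f"TRAV{i}" for i in range(1, 9)], [f"TRBV{i}" for i in range(1, 9)]
    clone_chains: dict[str, list[tuple]] = {}
    for cid in sorted(clone_members):
        if cid.startswith("TCR"):
            tra = _random_junction(rng)
            trb = _random_junction(rng)
            clone_chains[cid] = [
                ("TRA", tra, rng.choice(v_t[0]), "TRAJ1"),
                ("TRB", trb, rng.choice(v_t[1]), "TRBJ1"),
            ]
        else:
            length = int(rng.choice(_JUNCTION_LENGTHS))
            ancestor = _random_junction(rng, length)
            light_locus = str(rng.choice(["IGK", "IGL"]))
            clone_chains[cid] = [
                ("IGH", ancestor, f"IGHV{int(rng.integers(1, 5))}", "IGHJ4"),
                (light_locus, _random_junction(rng), f"{light_locus}V1", f"{light_locus}J1"),
            ]

    other_class = {"TCR": ("IGH", "IGHV1", "IGHJ4"), "BCR": ("TRB", "TRBV1", "TRBJ1")}
    for _, cell in cells.iterrows():
        cell_id = cell["cell_id"]
        cid = clone_of_cell[cell_id]
        cls = "TCR" if cid.startswith("TCR") else "BCR"
        u = rng.random()
        flagged = "none"
        if u < spec.ambiguous_frac:
            flagged = "ambiguous"
        elif u < spec.ambiguous_frac + spec.multichain_frac:
            flagged = "multichain"

        for locus, junction, v, j in clone_chains[cid]:
            if cls == "BCR" and locus == "IGH":
                junction = _mutate(rng, junction, spec.bcr_mutation_rate)
            chains.append((cell_id, locus, junction, v, j))
        if flagged == "ambiguous":
            locus, v, j = other_class[cls]
            chains.append((cell_id, locus, _random_junction(rng), v, j))
        elif flagged == "multichain":
            locus = "TRA" if cls == "TCR" else "IGH"
            length = len(clone_chains[cid][0][1]) if locus == "IGH" else None
            for _ in range(2):  # third+fourth chain of one arm -> >2 of that arm
                chains.append(
                    (cell_id, locus, _random_junction(rng, length), "Vx", "Jx")
                )
        truth.append(
            (cell_id, cid, cls if flagged == "none" else flagged,
             cell["subcluster"])
        )

    chains_df = pd.DataFrame(
        chains, columns=["cell_id", "locus", "junction", "v_call", "j_call"]
    )
    chains_df["junction_aa"] = ""
    truth_df = pd.DataFrame(
        truth, columns=["cell_id", "true_clonotype", "true_class", "subcluster"]
    )
    return chains_df, truth_df


# ---------------------------------------------------------------------------
# spatial spots


@dataclass
class SpotSpec:
    """Spot x cell-type abundances with planted pairwise co-localization.

    Each type's abundance per spot is an independent Gamma draw with shape
    ``base_concentration``; a pair listed in ``colocalized_pairs`` with
    loading rho additionally shares a per-spot Gamma(1) latent factor scaled
    by rho, making the pair's abundances positively correlated while keeping
    marginals nonnegative.
    """

    n_spots: int = 300
    cell_types: tuple[str, ...] = ("B", "CD4T", "CD8T", "DC")
    base_concentration: tuple[float, ...] | float = 1.0
    colocalized_pairs: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        conc = np.broadcast_to(
            np.asarray(self.base_concentration, dtype=float), (len(self.cell_types),)
        )
        if (conc <= 0).any():
            raise ValueError("concentrations must be positive")
        for rho in self.colocalized_pairs.values():
            if rho < 0:
                raise ValueError("co-localization loading must be >= 0")


def simulate_spots(spec: SpotSpec) -> tuple[pd.DataFrame, dict]:
    """Abundance table (spots x types) and the planted loadings."""
    rng = np.random.default_rng(spec.seed)
    conc = np.broadcast_to(
        np.asarray(spec.base_concentration, dtype=float), (len(spec.cell_types),)
    )
    A = rng.gamma(shape=conc, scale=1.0, size=(spec.n_spots, len(spec.cell_types)))
    for (a, b), rho in sorted(spec.colocalized_pairs.items()):
        if rho == 0:
            continue
        latent = rng.gamma(shape=1.0, scale=1.0, size=spec.n_spots)
        ia, ib = spec.cell_types.index(a), spec.cell_types.index(b)
        A[:, ia] += rho * latent
        A[:, ib] += rho * latent
    abund = pd.DataFrame(
        A, columns=list(spec.cell_types),
        index=[f"spot{i:04d}" for i in range(spec.n_spots)],
    )
    return abund, {"colocalized_pairs": dict(spec.colocalized_pairs)}


# ---------------------------------------------------------------------------
# imaging point patterns


@dataclass
class PointSpec:
    """Per-core labeled point patterns: Neyman–Scott clusters vs CSR.

    Cores whose status is in ``clustered_statuses`` draw the phenotypes in
    ``clustered_phenotypes`` from a Neyman–Scott process (Poisson parents of
    intensity ``parent_intensity`` per um^2, Poisson(``offspring_per_parent``)
    offspring scattered Normal(0, ``cluster_radius``) around each parent),
    all clustered phenotypes sharing one parent set so they co-cluster.
    Everything else is complete spatial randomness at the matched intensity
    ``parent_intensity * offspring_per_parent``.
    """

    n_cores: int = 6
    core_status: tuple[str, ...] = ("nTLS", "nTLS", "imTLS", "imTLS", "mTLS", "mTLS")
    phenotypes: tuple[str, ...] = ("CD4_TexProg_Tfh", "B")
    clustered_phenotypes: tuple[str, ...] = ("CD4_TexProg_Tfh", "B")
    clustered_statuses: frozenset = frozenset({"mTLS"})
    parent_intensity: float = 5e-5   # parents per um^2
    offspring_per_parent: float = 20.0
    cluster_radius: float = 25.0     # um
    window: tuple[float, float, float, float] = (0.0, 1000.0, 0.0, 1000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        x0, x1, y0, y1 = self.window
        if x1 <= x0 or y1 <= y0:
            raise ValueError("window must have positive area")
        if len(self.core_status) != self.n_cores:
            raise ValueError("core_status must list one status per core")
        if min(self.parent_intensity, self.offspring_per_parent, self.cluster_radius) <= 0:
            raise ValueError("process parameters must be positive")

    @property
    def area(self) -> float:
        x0, x1, y0, y1 = self.window
        return (x1 - x0) * (y1 - y0)


def _csr(rng, n, window):
    x0, x1, y0, y1 = window
    return np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])


def simulate_points(spec: PointSpec) -> pd.DataFrame:
    """Point table (core_id, tls_status, cell_id, x, y, phenotype)."""
    rng = np.random.default_rng(spec.seed)
    x0, x1, y0, y1 = spec.window
    rows = []
    for c in range(spec.n_cores):
        core_id = f"core{c + 1:02d}"
        status = spec.core_status[c]
        clustered_here = status in spec.clustered_statuses
        parents = _csr(rng, rng.poisson(spec.parent_intensity * spec.area), spec.window)
        k = 0
        for pheno in spec.phenotypes:
            if clustered_here and pheno in spec.clustered_phenotypes and len(parents):
                counts = rng.poisson(spec.offspring_per_parent, size=len(parents))
                pts = np.repeat(parents, counts, axis=0) + rng.normal(
                    scale=spec.cluster_radius, size=(counts.sum(), 2)
                )
                pts[:, 0] = np.clip(pts[:, 0], x0, x1)
                pts[:, 1] = np.clip(pts[:, 1], y0, y1)
            else:
                lam = spec.parent_intensity * spec.offspring_per_parent * spec.area
                pts = _csr(rng, rng.poisson(lam), spec.window)
            for x, y in pts:
                rows.append((core_id, status, f"{core_id}_cell{k:05d}", x, y, pheno))
                k += 1
    return pd.DataFrame(
        rows, columns=["core_id", "tls_status", "cell_id", "x", "y", "phenotype"]
    )
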