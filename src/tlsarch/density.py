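"""Kernel-density estimates and contrasts on 2-D embeddings.

Each TLS status's cells are smoothed with a product-Gaussian kernel on a
shared regular grid over the (UMAP-like) embedding; the contrast map between
two statuses is the node-wise difference of their unit-mass densities, so it
compares the *shape* of the distributions rather than raw cell abundance.
Bandwidths follow the normal-reference rule computed on the pooled embedding
and are shared across statuses, because contrasting densities smoothed at
different scales would confound shape with smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_MIN_BANDWIDTH = 1e-6


@dataclass
class DensityGrid:
    grid_x: np.ndarray  # (n_x,) strictly increasing
    grid_y: np.ndarray  # (n_y,)
    density: np.ndarray  # (n_x, n_y), >= 0
    bandwidth: tuple[float, float]
    n_points: int

    def mass(self) -> float:
        """Riemann-sum mass captured inside the grid window (<= 1)."""
        dx = np.diff(self.grid_x).mean()
        dy = np.diff(self.grid_y).mean()
        return float(self.density.sum() * dx * dy)


@dataclass
class ContrastGrid:
    grid_x: np.ndarray
    grid_y: np.ndarray
    contrast: np.ndarray
    status_pair: tuple[str, str]


def reference_bandwidth(values: np.ndarray) -> float:
    """Normal-reference rule for one axis of a 2-D product-Gaussian KDE:
    ``sigma * n**(-1/6)``. Degenerate (zero-variance) axes fall back to a
    fixed minimal bandwidth."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1) if len(values) > 1 else 0.0
    if sd <= 0:
        return _MIN_BANDWIDTH
    return float(sd * len(values) ** (-1.0 / 6.0))


def grid_bounds_from_points(
    x: np.ndarray, y: np.ndarray, bandwidth: tuple[float, float], pad_bandwidths: float = 3.0
) -> tuple[float, float, float, float]:
    """Bounding box of the points padded by ``pad_bandwidths`` bandwidths."""
    hx, hy = bandwidth
    return (
        float(x.min() - pad_bandwidths * hx),
        float(x.max() + pad_bandwidths * hx),
        float(y.min() - pad_bandwidths * hy),
        float(y.max() + pad_bandwidths * hy),
    )


def estimate_density_2d(
    points: np.ndarray,
    grid_bounds: tuple[float, float, float, float],
    n_grid: int = 100,
    bandwidth: tuple[float, float] | None = None,
) -> DensityGrid:
    """Product-Gaussian KDE evaluated on a regular ``n_grid x n_grid`` grid.

    ``points`` is an (n, 2) array. The density integrates to 1 over the
    plane; the grid window truncates some of that mass (see
    :meth:`DensityGrid.mass`). ``bandwidth=None`` applies the
    normal-reference rule per axis to these points.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("need at least one point")
    x, y = pts[:, 0], pts[:, 1]
    if bandwidth is None:
        bandwidth = (reference_bandwidth(x), reference_bandwidth(y))
    hx, hy = bandwidth
    if hx <= 0 or hy <= 0:
        raise ValueError("bandwidths must be positive")

    x0, x1, y0, y1 = grid_bounds
    gx = np.linspace(x0, x1, n_grid)
    gy = np.linspace(y0, y1, n_grid)

    # separable kernel: (n_grid, n) Gaussian factors per axis
    kx = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / hx) ** 2) / (hx * np.sqrt(2 * np.pi))
    ky = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / hy) ** 2) / (hy * np.sqrt(2 * np.pi))
    dens = (kx @ ky.T) / len(x)
    return DensityGrid(gx, gy, dens, (float(hx), float(hy)), len(x))


def density_contrast(a: DensityGrid, b: DensityGrid, status_pair=("A", "B")) -> ContrastGrid:
    """Node-wise difference of two unit-mass densities on identical grids."""
    if not (
        np.array_equal(a.grid_x, b.grid_x)
        and np.array_equal(a.grid_y, b.grid_y)
        and a.bandwidth == b.bandwidth
    ):
        raise ValueError("density grids must share grid nodes and bandwidth")
    return ContrastGrid(a.grid_x, a.grid_y, a.density - b.density, tuple(status_pair))


def status_density_contrasts(
    cells: pd.DataFrame,
    status_field: str = "tls_status",
    coord_fields: tuple[str, str] = ("dim1", "dim2"),
    group_field: str | None = None,
    n_grid: int = 100,
    normalized: bool = True,
) -> pd.DataFrame:
    """Per-status densities and all pairwise contrasts, long format.

    Bandwidth and grid are computed once on the pooled embedding so every
    status is smoothed at a common scale. ``group_field`` restricts the
    computation to each cluster/compartment separately. ``normalized=False``
    weights each status map by its cell count instead of unit mass.
    """
    frames = []
    groups = [(None, cells)] if group_field is None else cells.groupby(group_field, observed=True)
    for gname, sub in groups:
        pts = sub[list(coord_fields)].to_numpy(dtype=float)
        bw = (reference_bandwidth(pts[:, 0]), reference_bandwidth(pts[:, 1]))
        bounds = grid_bounds_from_points(pts[:, 0], pts[:, 1], bw)
        dens = {}
        for status, scells in sub.groupby(status_field, observed=True):
            g = estimate_density_2d(
                scells[list(coord_fields)].to_numpy(dtype=float), bounds, n_grid, bw
            )
            if not normalized:
                g.density = g.density * (len(scells) / len(sub))
            dens[status] = g
            frames.append(_grid_long(g, kind="density", label=str(status), group=gname))
        statuses = list(dens)
        for i, a in enumerate(statuses):
            for b in statuses[i + 1:]:
                c = density_contrast(dens[a], dens[b], (a, b))
                frames.append(_contrast_long(c, group=gname))
    return pd.concat(frames, ignore_index=True)


def _grid_long(g: DensityGrid, kind: str, label: str, group) -> pd.DataFrame:
    xx, yy = np.meshgrid(g.grid_x, g.grid_y, indexing="ij")
    return pd.DataFrame(
        {"x": xx.ravel(), "y": yy.ravel(), "value": g.density.ravel(),
         "kind": kind, "label": label, "group": group}
    )


def _contrast_long(c: ContrastGrid, group) -> pd.DataFrame:
    xx, yy = np.meshgrid(c.grid_x, c.grid_y, indexing="ij")
    return pd.DataFrame(
        {"x": xx.ravel(), "y": yy.ravel(), "value": c.contrast.ravel(),
         "kind": "contrast", "label": f"{c.status_pair[0]}_vs_{c.status_pair[1]}",
         "group": group}
    )
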