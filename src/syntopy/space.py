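"""Kernel utilization distributions, isopleth home ranges, and overlap.

Space use of each group (a species, or a species-sex class) is summarized by
a kernel utilization distribution (KUD): a bivariate-normal kernel density
over the group's observed positions, evaluated on a regular grid and
normalized to integrate to one. The p% isopleth is the smallest set of grid
cells holding p% of the utilization mass — 50% is conventionally the "core"
home range and 95% the "extended" home range. Pairwise overlap between
groups i and j is

    HR[i][j] = A_ij / A_i,

the shared isopleth area divided by group i's own isopleth area, so the
matrix is generally asymmetric even though the intersection area A_ij is
symmetric. All groups must share one grid so intersection areas are
cell-exact.

The default bandwidth is the ad-hoc reference rule of the home-range
literature, h = 0.5 (sigma_x + sigma_y) n^(-1/6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box
from shapely.ops import unary_union

__all__ = [
    "KUDResult",
    "OverlapMatrix",
    "href_bandwidth",
    "make_grid",
    "estimate_kud",
    "isopleth",
    "overlap_matrix",
    "shared_grid",
]


@dataclass(frozen=True)
class Grid:
    """Regular square-cell grid given by cell-center coordinate vectors."""

    x: np.ndarray  # cell-center x coordinates, shape (nx,)
    y: np.ndarray  # cell-center y coordinates, shape (ny,)

    @property
    def cell_size(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    def same_as(self, other: "Grid") -> bool:
        return (
            self.x.shape == other.x.shape
            and self.y.shape == other.y.shape
            and np.allclose(self.x, other.x)
            and np.allclose(self.y, other.y)
        )


@dataclass
class KUDResult:
    """A gridded utilization density for one group."""

    label: str
    grid: Grid
    density: np.ndarray  # shape (ny, nx); integrates to 1 over the grid
    bandwidth: float
    n_points: int
    isopleths: dict = field(default_factory=dict)  # p -> (mask, polygons, area)


@dataclass
class OverlapMatrix:
    """Pairwise home-range overlap proportions at one isopleth level."""

    labels: list[str]
    hr: np.ndarray  # hr[i, j] = A_ij / A_i
    intersection_areas: np.ndarray  # symmetric A_ij, m^2
    level: float


def href_bandwidth(points: np.ndarray) -> float:
    """Reference bandwidth h = 0.5 (sigma_x + sigma_y) n^(-1/6) in meters."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    sx = pts[:, 0].std(ddof=1)
    sy = pts[:, 1].std(ddof=1)
    if sx + sy <= 0:
        raise ValueError("zero spatial variance: cannot resolve 'href' bandwidth")
    return 0.5 * (sx + sy) * n ** (-1.0 / 6.0)


def make_grid(
    points: np.ndarray,
    grid_cells: int = 200,
    extent_pad: float = 0.5,
    min_pad: float = 0.0,
) -> Grid:
    """Square-cell grid covering the points' bounding box, padded on each side
    by ``extent_pad`` times the larger span (at least ``min_pad`` meters, so a
    tight cluster still gets a grid wide enough for its kernel)."""
    pts = np.asarray(points, dtype=float)
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    span = max(xmax - xmin, ymax - ymin, 1e-9)
    pad = max(extent_pad * span, min_pad, 1e-6)
    cx, cy = (xmin + xmax) / 2, (ymin + ymax) / 2
    half = span / 2 + pad
    edges = np.linspace(-half, half, grid_cells + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    return Grid(x=cx + centers, y=cy + centers)


def estimate_kud(
    points,
    bandwidth: float | str = "href",
    grid_cells: int = 200,
    extent_pad: float = 0.5,
    grid: Grid | None = None,
    label: str = "",
) -> KUDResult:
    """Bivariate-normal KUD of a point set on a regular grid.

    ``bandwidth`` is ``"href"`` or meters. The density is renormalized so
    that sum(density) * cell_area = 1 on the grid.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 5:
        raise ValueError(f"need at least 5 points, got {len(pts)}")
    h = href_bandwidth(pts) if bandwidth == "href" else float(bandwidth)
    if not h > 0:
        raise ValueError(f"bandwidth must be positive, got {h}")
    if grid is None:
        # pad by >= 4h so essentially all kernel mass lies on the grid
        grid = make_grid(pts, grid_cells=grid_cells, extent_pad=extent_pad, min_pad=4 * h)

    # Gaussian kernel evaluated cell-center x point, separably in x and y.
    dx = (grid.x[None, :] - pts[:, 0][:, None]) / h  # (n, nx)
    dy = (grid.y[None, :] - pts[:, 1][:, None]) / h  # (n, ny)
    gx = np.exp(-0.5 * dx ** 2)
    gy = np.exp(-0.5 * dy ** 2)
    dens = (gy[:, :, None] * gx[:, None, :]).sum(axis=0)  # (ny, nx)
    dens /= 2 * np.pi * h ** 2 * len(pts)
    total = dens.sum() * grid.cell_area
    if total <= 0:
        raise ValueError("density mass vanished on the grid; widen the extent")
    dens /= total
    return KUDResult(
        label=label, grid=grid, density=dens, bandwidth=h, n_points=len(pts)
    )


def isopleth(kud: KUDResult, p: float):
    """Smallest grid-cell region holding at least p% of the utilization mass.

    Cells are accumulated in order of decreasing density (ties broken by
    row-major order) until the cumulative mass first reaches p/100. Returns
    ``(mask, polygons, area_m2)`` with polygons tracing the cell-block
    boundary; the result is cached on ``kud.isopleths[p]``.
    """
    if not 0 < p <= 100:
        raise ValueError(f"isopleth level must be in (0, 100], got {p}")
    if p in kud.isopleths:
        return kud.isopleths[p]
    flat = kud.density.ravel()
    order = np.argsort(-flat, kind="stable")  # stable: ties in row-major order
    mass = np.cumsum(flat[order]) * kud.grid.cell_area
    if p == 100:
        k = int(np.count_nonzero(flat))  # exhaustion: every positive-mass cell
    else:
        target = p / 100.0
        k = int(np.searchsorted(mass, target - 1e-12)) + 1
        k = min(k, int(np.count_nonzero(flat)))
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(kud.density.shape)
    area = float(k * kud.grid.cell_area)
    polygons = _mask_polygons(mask, kud.grid)
    kud.isopleths[p] = (mask, polygons, area)
    return kud.isopleths[p]


def _mask_polygons(mask: np.ndarray, grid: Grid):
    """Union of the masked cells' squares as a list of shapely polygons."""
    half = grid.cell_size / 2
    iy, ix = np.nonzero(mask)
    cells = [
        box(grid.x[j] - half, grid.y[i] - half, grid.x[j] + half, grid.y[i] + half)
        for i, j in zip(iy, ix)
    ]
    if not cells:
        return []
    merged = unary_union(cells)
    return list(getattr(merged, "geoms", [merged]))


def shared_grid(point_sets, grid_cells: int = 200, extent_pad: float = 0.5) -> Grid:
    """One grid covering the pooled bounding box of several groups' points."""
    pooled = np.vstack([np.asarray(p, dtype=float).reshape(-1, 2) for p in point_sets])
    return make_grid(pooled, grid_cells=grid_cells, extent_pad=extent_pad)


def overlap_matrix(kuds: list[KUDResult], p: float) -> OverlapMatrix:
    """Pairwise overlap proportions HR[i][j] = A_ij / A_i at level p.

    All KUDs must share one grid so intersection areas are cell-exact.
    """
    if not kuds:
        raise ValueError("need at least one KUD")
    g0 = kuds[0].grid
    for k in kuds[1:]:
        if not g0.same_as(k.grid):
            raise ValueError("KUDs are not on a shared grid")
    masks = [isopleth(k, p)[0] for k in kuds]
    areas = np.array([isopleth(k, p)[2] for k in kuds])
    m = len(kuds)
    inter = np.zeros((m, m))
    for i in range(m):
        for j in range(i, m):
            a = float(np.count_nonzero(masks[i] & masks[j]) * g0.cell_area)
            inter[i, j] = inter[j, i] = a
    hr = inter / areas[:, None]
    return OverlapMatrix(
        labels=[k.label for k in kuds], hr=hr, intersection_areas=inter, level=p
    )
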