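"""Spatial primitives: cell→spot assignment, weights graphs, boundary distances."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .containers import CellTable, SpotGrid, WeightsGraph
from .errors import ParameterError, ValidationError

__all__ = [
    "assign_cells_to_spots",
    "build_spot_graph",
    "build_cell_graph",
    "distance_to_boundary",
]

_TIE_TOL = 1e-9  # µm: centre distances closer than this are treated as tied
# hex-lattice adjacency tolerance: absorbs floating-point jitter in spot
# coordinates without ever reaching the next-nearest lattice shell (√3·pitch)
_ADJACENCY_FACTOR = 1.05


def assign_cells_to_spots(cells: CellTable, grid: SpotGrid) -> CellTable:
    """Assign each cell to the spot whose disc contains its centroid.

    A cell belongs to spot *s* iff its centroid lies within
    ``spot_diameter_um / 2`` (inclusive) of the centre of *s*. Because spot
    discs do not overlap on a Visium lattice (55 µm diameter vs 100 µm
    pitch) at most one spot can qualify; exact ties at the radius are broken
    by the lexicographically smallest barcode. Cells inside no disc keep a
    null assignment — these are segmentable but not deconvolvable.

    Returns a new :class:`CellTable`; the input is not modified.
    """
    if grid.n_spots == 0:
        raise ValidationError("cannot assign cells against an empty spot grid")
    tree = cKDTree(grid.coords())
    radius = grid.radius_um
    k = min(4, grid.n_spots)
    dists, idxs = tree.query(cells.coords(), k=k)
    dists = np.atleast_2d(dists.reshape(cells.n_cells, -1))
    idxs = np.atleast_2d(idxs.reshape(cells.n_cells, -1))

    assigned = np.full(cells.n_cells, None, dtype=object)
    for i in range(cells.n_cells):
        d0 = dists[i, 0]
        if d0 > radius + _TIE_TOL or not np.isfinite(d0):
            continue
        tied = [
            int(idxs[i, j])
            for j in range(dists.shape[1])
            if np.isfinite(dists[i, j])
            and dists[i, j] <= radius + _TIE_TOL
            and dists[i, j] - d0 <= _TIE_TOL
        ]
        assigned[i] = min((grid.barcodes[s] for s in tied))
    return CellTable(
        cell_ids=list(cells.cell_ids),
        x_um=cells.x_um.copy(),
        y_um=cells.y_um.copy(),
        morphology=cells.morphology.copy(),
        feature_names=list(cells.feature_names),
        spot_barcode=assigned,
        type_label=cells.type_label.copy(),
    )


def build_spot_graph(grid: SpotGrid) -> WeightsGraph:
    """Binary adjacency between spot centres within 1.05 × pitch.

    On a hexagonal lattice this yields at most 6 neighbours per spot; the
    5% slack absorbs coordinate jitter while staying well below the
    next-nearest shell at √3 × pitch.
    """
    tree = cKDTree(grid.coords())
    pairs = tree.query_pairs(r=_ADJACENCY_FACTOR * grid.pitch_um, output_type="ndarray")
    return WeightsGraph(node_ids=list(grid.barcodes), edges=pairs)


def build_cell_graph(cells: CellTable, k: int = 6) -> WeightsGraph:
    """Symmetrized k-nearest-neighbour graph over cell centroids (binary)."""
    n = cells.n_cells
    if n < 2:
        raise ParameterError("cell graph needs at least 2 cells")
    if k >= n:
        raise ParameterError(f"k={k} must be smaller than the number of cells ({n})")
    tree = cKDTree(cells.coords())
    _, idxs = tree.query(cells.coords(), k=k + 1)
    idxs = np.atleast_2d(idxs)
    src = np.repeat(np.arange(n), k)
    dst = idxs[:, 1:].ravel()
    edges = np.column_stack([src, dst])
    return WeightsGraph(node_ids=list(cells.cell_ids), edges=edges)


def distance_to_boundary(points, region) -> np.ndarray:
    """Signed Euclidean distance (µm) from points to a polygon boundary.

    Negative inside the region, positive outside, zero on the boundary —
    so infiltration depth into a region reads as a negative coordinate.
    Holes count as boundary; a point inside a hole is outside the region.
    """
    import shapely
    from shapely.geometry import Polygon

    if not isinstance(region, Polygon):
        raise ValidationError("region must be a shapely Polygon")
    if len(region.exterior.coords) < 4:
        raise ValidationError("degenerate polygon: fewer than 3 distinct vertices")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2:
        raise ValidationError("points must be (n, 2) coordinates")
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    dist = shapely.distance(geoms, region.boundary)
    inside = shapely.covers(region, geoms)
    return np.where(inside, -dist, dist)
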