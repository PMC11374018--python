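"""Core in-memory containers for a Visium experiment.

All geometry lives in a single physical frame: micrometres, origin at the
top-left of the image, y increasing downward (image convention). File
readers convert into this frame at the I/O boundary; no other module
rescales coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ValidationError

__all__ = [
    "SpotGrid",
    "CountMatrix",
    "CellTable",
    "DeconvMatrix",
    "RegionSet",
    "WeightsGraph",
    "SpotTypeCounts",
]

_EPS_PITCH = 1e-6  # µm slack on the minimum-distance lattice check


def _as_unique_str_list(values, what: str) -> list[str]:
    out = [str(v) for v in values]
    if len(set(out)) != len(out):
        dupes = sorted({v for v in out if out.count(v) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")
    return out


@dataclass
class SpotGrid:
    """The capture-area lattice: barcoded spots with array and physical coordinates.

    A standard Visium capture area carries 4992 spots of 55 µm diameter on a
    hexagonal lattice with 100 µm centre-to-centre pitch.
    """

    barcodes: list[str]
    array_row: np.ndarray
    array_col: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    in_tissue: np.ndarray
    spot_diameter_um: float = 55.0
    pitch_um: float = 100.0

    def __post_init__(self) -> None:
        self.barcodes = _as_unique_str_list(self.barcodes, "spot barcodes")
        n = len(self.barcodes)
        self.array_row = np.asarray(self.array_row, dtype=np.int64)
        self.array_col = np.asarray(self.array_col, dtype=np.int64)
        self.x_um = np.asarray(self.x_um, dtype=np.float64)
        self.y_um = np.asarray(self.y_um, dtype=np.float64)
        self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
        for name in ("array_row", "array_col", "x_um", "y_um", "in_tissue"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"SpotGrid field {name!r} has wrong length")
        if not np.isfinite(self.spot_diameter_um) or self.spot_diameter_um <= 0:
            raise ValidationError("spot_diameter_um must be positive")
        if not np.isfinite(self.pitch_um) or self.pitch_um <= 0:
            raise ValidationError("pitch_um must be positive")
        rc = set(zip(self.array_row.tolist(), self.array_col.tolist()))
        if len(rc) != n:
            raise ValidationError("two spots share the same (array_row, array_col)")
        if n >= 2:
            tree = cKDTree(np.column_stack([self.x_um, self.y_um]))
            dmin = float(tree.query(tree.data, k=2)[0][:, 1].min())
            if dmin < self.pitch_um - _EPS_PITCH:
                raise ValidationError(
                    f"minimum centre distance {dmin:.6g} µm below pitch {self.pitch_um:.6g} µm"
                )

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)

    @property
    def radius_um(self) -> float:
        return self.spot_diameter_um / 2.0

    def coords(self) -> np.ndarray:
        """Spot centres as an (n, 2) array of (x, y) µm."""
        return np.column_stack([self.x_um, self.y_um])

    def barcode_index(self) -> dict[str, int]:
        return {b: i for i, b in enumerate(self.barcodes)}


@dataclass
class CountMatrix:
    """Spot × gene nonnegative integer transcript counts."""

    spot_barcodes: list[str]
    gene_ids: list[str]
    counts: np.ndarray  # (n_spots, n_genes) int64

    def __post_init__(self) -> None:
        self.spot_barcodes = _as_unique_str_list(self.spot_barcodes, "spot barcodes")
        self.gene_ids = _as_unique_str_list(self.gene_ids, "gene ids")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.spot_barcodes), len(self.gene_ids)):
            raise ValidationError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.spot_barcodes)} barcodes × {len(self.gene_ids)} genes"
            )
        if counts.size and counts.min() < 0:
            raise ValidationError("count matrix has negative entries")
        if not np.issubdtype(counts.dtype, np.integer):
            if counts.size and not np.allclose(counts, np.round(counts)):
                raise ValidationError("count matrix has non-integer entries")
            counts = np.round(counts).astype(np.int64)
        self.counts = counts.astype(np.int64, copy=False)

    @property
    def n_spots(self) -> int:
        return len(self.spot_barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class CellTable:
    """One row per segmented cell: centroid, morphology features, and
    (nullable) spot assignment / type label."""

    cell_ids: list[str]
    x_um: np.ndarray
    y_um: np.ndarray
    morphology: np.ndarray  # (n_cells, F), F >= 1
    feature_names: list[str]
    spot_barcode: np.ndarray | None = None  # object array, None = unassigned
    type_label: np.ndarray | None = None  # object array, None = unlabeled

    def __post_init__(self) -> None:
        self.cell_ids = _as_unique_str_list(self.cell_ids, "cell ids")
        n = len(self.cell_ids)
        self.x_um = np.asarray(self.x_um, dtype=np.float64)
        self.y_um = np.asarray(self.y_um, dtype=np.float64)
        self.morphology = np.atleast_2d(np.asarray(self.morphology, dtype=np.float64))
        if self.morphology.shape[0] != n and n > 0:
            raise ValidationError("morphology row count does not match cell count")
        if n > 0 and self.morphology.shape[1] < 1:
            raise ValidationError("morphology needs at least one feature column")
        if self.morphology.size and not np.isfinite(self.morphology).all():
            raise ValidationError("morphology contains non-finite values")
        if len(self.feature_names) != self.morphology.shape[1] and n > 0:
            raise ValidationError("feature_names length does not match morphology width")
        if self.spot_barcode is None:
            self.spot_barcode = np.full(n, None, dtype=object)
        else:
            self.spot_barcode = np.asarray(self.spot_barcode, dtype=object)
        if self.type_label is None:
            self.type_label = np.full(n, None, dtype=object)
        else:
            self.type_label = np.asarray(self.type_label, dtype=object)
        for name in ("x_um", "y_um", "spot_barcode", "type_label"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"CellTable field {name!r} has wrong length")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um])

    def assigned_mask(self) -> np.ndarray:
        return np.array([b is not None for b in self.spot_barcode], dtype=bool)

    def validate_against(self, grid: SpotGrid) -> None:
        """Every non-null spot assignment must exist in *grid*."""
        known = set(grid.barcodes)
        bad = sorted({b for b in self.spot_barcode if b is not None and b not in known})
        if bad:
            raise ValidationError(f"cells reference unknown spot barcodes: {bad[:5]}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "x_um": self.x_um,
                "y_um": self.y_um,
                "spot_barcode": [b if b is not None else "" for b in self.spot_barcode],
                "type_label": [t if t is not None else "" for t in self.type_label],
            }
        )
        for j, name in enumerate(self.feature_names):
            df[name] = self.morphology[:, j]
        return df


@dataclass
class DeconvMatrix:
    """Spot × cell-type proportions; every row lies on the probability simplex."""

    spot_barcodes: list[str]
    cell_types: list[str]
    proportions: np.ndarray  # (n_spots, K)
    renormalized: np.ndarray = field(default=None)  # rows fixed up on load

    # rows whose sum deviates by more than this are rejected outright
    ROW_SUM_TOL = 1e-3
    # rows within this of 1 are accepted as-is (numerically on the simplex)
    SIMPLEX_TOL = 1e-6

    def __post_init__(self) -> None:
        self.spot_barcodes = _as_unique_str_list(self.spot_barcodes, "spot barcodes")
        self.cell_types = _as_unique_str_list(self.cell_types, "cell types")
        if len(self.cell_types) < 1:
            raise ValidationError("deconvolution needs at least one cell type")
        p = np.asarray(self.proportions, dtype=np.float64)
        if p.shape != (len(self.spot_barcodes), len(self.cell_types)):
            raise ValidationError("proportion matrix shape mismatch")
        if p.size and (p.min() < -self.SIMPLEX_TOL or not np.isfinite(p).all()):
            raise ValidationError("proportions must be finite and nonnegative")
        p = np.clip(p, 0.0, None)
        sums = p.sum(axis=1)
        bad = np.abs(sums - 1.0) > self.ROW_SUM_TOL
        if bad.any():
            rows = [self.spot_barcodes[i] for i in np.flatnonzero(bad)[:5]]
            raise ValidationError(
                f"deconvolution row sums outside 1±{self.ROW_SUM_TOL:g} for spots {rows}"
            )
        flagged = np.abs(sums - 1.0) > self.SIMPLEX_TOL
        if flagged.any():
            p = p / sums[:, None]
        self.proportions = p
        self.renormalized = flagged

    @property
    def n_types(self) -> int:
        return len(self.cell_types)

    def barcode_index(self) -> dict[str, int]:
        return {b: i for i, b in enumerate(self.spot_barcodes)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions, index=self.spot_barcodes, columns=self.cell_types
        )


@dataclass
class RegionSet:
    """Named annotation polygons in the shared µm frame.

    ``polygons`` holds :class:`shapely.geometry.Polygon` objects (outer ring
    plus optional holes).
    """

    names: list[str]
    polygons: list

    def __post_init__(self) -> None:
        from shapely.geometry import Polygon

        self.names = _as_unique_str_list(self.names, "region names")
        if len(self.names) != len(self.polygons):
            raise ValidationError("names and polygons differ in length")
        for name, poly in zip(self.names, self.polygons):
            if not isinstance(poly, Polygon):
                raise ValidationError(f"region {name!r} is not a polygon")
            if len(poly.exterior.coords) < 4:  # closed ring: first == last
                raise ValidationError(f"region {name!r} has a degenerate outer ring")
            if not poly.is_valid:
                raise ValidationError(f"region {name!r} polygon is not simple/valid")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(zip(self.names, self.polygons))


@dataclass
class WeightsGraph:
    """Undirected spatial weights graph over spots or cells.

    Edges are stored once per unordered pair; weights default to binary.
    """

    node_ids: list[str]
    edges: np.ndarray  # (m, 2) int indices, i < j
    weights: np.ndarray = None  # (m,) nonnegative

    def __post_init__(self) -> None:
        self.node_ids = _as_unique_str_list(self.node_ids, "node ids")
        e = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if e.size:
            if (e[:, 0] == e[:, 1]).any():
                raise ValidationError("self-loops are not allowed")
            if e.min() < 0 or e.max() >= len(self.node_ids):
                raise ValidationError("edge endpoint out of range")
            lo = np.minimum(e[:, 0], e[:, 1])
            hi = np.maximum(e[:, 0], e[:, 1])
            e = np.column_stack([lo, hi])
            order = np.lexsort((e[:, 1], e[:, 0]))
            e = e[order]
            if len(np.unique(e, axis=0)) != len(e):
                e = np.unique(e, axis=0)
        self.edges = e
        if self.weights is None:
            self.weights = np.ones(len(e), dtype=np.float64)
        else:
            w = np.asarray(self.weights, dtype=np.float64)
            if len(w) != len(e):
                raise ValidationError("weights length does not match edge count")
            if w.size and w.min() < 0:
                raise ValidationError("weights must be nonnegative")
            self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if self.n_edges:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def total_weight(self) -> float:
        """W = Σ_ij w_ij with both directions of each edge counted."""
        return 2.0 * float(self.weights.sum())


@dataclass
class SpotTypeCounts:
    """Integer per-type cell counts per spot; rows conserve the segmented total."""

    spot_barcodes: list[str]
    cell_types: list[str]
    n_cells: np.ndarray  # (n_spots,) segmented cell count n_s
    counts: np.ndarray  # (n_spots, K) integer c_sk

    def __post_init__(self) -> None:
        self.spot_barcodes = _as_unique_str_list(self.spot_barcodes, "spot barcodes")
        self.n_cells = np.asarray(self.n_cells, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.spot_barcodes), len(self.cell_types)):
            raise ValidationError("type-count matrix shape mismatch")
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("negative type count")
        if not np.array_equal(self.counts.sum(axis=1), self.n_cells):
            raise ValidationError("per-type counts do not sum to the segmented total")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.spot_barcodes, columns=self.cell_types)
        df.insert(0, "n_cells", self.n_cells)
        return df
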