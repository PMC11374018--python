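"""Deconvolution–segmentation fusion: label individual cells per spot.

This is the package's core computation. Spot-level deconvolution yields a
cell-type composition p_sk for each spot; image segmentation yields the
individual cells (n_s per spot) with morphology features. Fusion converts
the two into per-cell type labels in three steps:

1. **Apportionment** — the fractional expected counts n_s · p_sk are turned
   into integers c_sk by largest-remainder (Hamilton) apportionment, so
   Σ_k c_sk = n_s exactly in every spot.
2. **Constrained assignment** — within each spot, cells are matched to type
   slots minimizing the summed squared distance of their morphology
   features to tissue-wide type centroids, subject to exactly c_sk cells of
   each type. Solved exactly as a transportation problem (unit supplies,
   demands c_sk) via linear assignment on an expanded cost matrix.
3. **Centroid refinement** — Lloyd-style alternation: type centroids are
   recomputed as the means of currently-labelled cells tissue-wide, and the
   per-spot assignment repeats until no label changes (or a configured
   fraction), capped at ``max_iter``. The assignment step is optimal per
   spot and the centroid step is the mean, so the global objective
   Σ‖f − μ_label‖² never increases.

Cells without a spot assignment cannot be deconvolved and keep a null label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import CellTable, DeconvMatrix, SpotTypeCounts
from .errors import ValidationError

__all__ = [
    "FusionConfig",
    "apportion_counts",
    "estimate_type_counts",
    "constrained_label_assignment",
    "fuse",
]

_SIMPLEX_TOL = 1e-6


@dataclass
class FusionConfig:
    max_iter: int = 50
    tol: float = 0.0  # fraction of labels allowed to change at convergence
    seed: int = 0
    feature_standardization: bool = True

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValidationError("max_iter must be ≥ 1")
        if not 0.0 <= self.tol < 1.0:
            raise ValidationError("tol must be in [0, 1)")


def apportion_counts(n: int, p: np.ndarray) -> np.ndarray:
    """Largest-remainder (Hamilton) apportionment of ``n`` units over types.

    Quotas q_k = n·p_k are floored; the leftover units go to the largest
    fractional remainders. Remainder ties are broken by larger p_k, then by
    lower type index. The result always sums to ``n``.
    """
    p = np.asarray(p, dtype=float)
    if n < 0:
        raise ValidationError("n must be ≥ 0")
    if p.ndim != 1 or p.size < 1:
        raise ValidationError("p must be a 1-D proportion vector")
    if (p < -_SIMPLEX_TOL).any() or abs(p.sum() - 1.0) > _SIMPLEX_TOL:
        raise ValidationError(f"p is off the simplex (sum={p.sum():.8g})")
    quotas = n * p
    floors = np.floor(quotas).astype(np.int64)
    leftover = int(n - floors.sum())
    if leftover > 0:
        remainders = quotas - floors
        # sort by (remainder desc, p desc, index asc); lexsort keys reversed
        order = np.lexsort((np.arange(p.size), -p, -remainders))
        floors[order[:leftover]] += 1
    return floors


def estimate_type_counts(cells: CellTable, deconv: DeconvMatrix) -> SpotTypeCounts:
    """Integer per-type cell counts for every spot in the deconvolution.

    n_s is the number of segmented cells assigned to spot s; the deconvolved
    row p_s· is apportioned into integers. Spots with no assigned cells get
    all-zero rows (flagged downstream by QC).
    """
    idx = deconv.barcode_index()
    missing = sorted(
        {b for b in cells.spot_barcode if b is not None and b not in idx}
    )
    if missing:
        raise ValidationError(
            f"assigned spot barcodes missing from deconvolution: {missing[:10]}"
        )
    n_s = np.zeros(len(deconv.spot_barcodes), dtype=np.int64)
    for b in cells.spot_barcode:
        if b is not None:
            n_s[idx[b]] += 1
    counts = np.zeros((len(n_s), deconv.n_types), dtype=np.int64)
    for s in range(len(n_s)):
        if n_s[s] > 0:
            counts[s] = apportion_counts(int(n_s[s]), deconv.proportions[s])
    return SpotTypeCounts(
        spot_barcodes=list(deconv.spot_barcodes),
        cell_types=list(deconv.cell_types),
        n_cells=n_s,
        counts=counts,
    )


def constrained_label_assignment(
    features: np.ndarray, counts: np.ndarray, centroids: np.ndarray
) -> np.ndarray:
    """Optimal type labels under exact per-type count constraints.

    Minimizes Σ_cells ‖feature − centroid(label)‖² subject to exactly
    ``counts[k]`` cells of type k. Solved exactly as unit-supply
    min-cost matching: each type contributes ``counts[k]`` identical demand
    columns and the Hungarian algorithm matches cells to columns. Among
    cost-equivalent optima the solution is deterministic for a fixed cell
    order (cells processed in index order).

    Returns integer type indices, one per cell.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    counts = np.asarray(counts, dtype=np.int64)
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    n = features.shape[0]
    if counts.sum() != n:
        raise ValidationError(
            f"count vector sums to {counts.sum()} but there are {n} cells"
        )
    if (counts < 0).any():
        raise ValidationError("negative type count")
    if n == 0:
        return np.empty(0, dtype=np.int64)
    # squared distances cells × types, then expand type k into counts[k] columns
    d2 = ((features[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    col_type = np.repeat(np.arange(len(counts)), counts)
    cost = d2[:, col_type]
    rows, cols = linear_sum_assignment(cost)
    labels = np.empty(n, dtype=np.int64)
    labels[rows] = col_type[cols]
    return labels


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def fuse(
    cells: CellTable, deconv: DeconvMatrix, config: FusionConfig | None = None
) -> tuple[CellTable, SpotTypeCounts]:
    """Label every assigned cell by morphology-constrained clustering.

    Returns ``(labelled cells, per-spot type counts)``. Per-spot label
    counts equal the apportioned c_sk at every iteration; the global
    objective is non-increasing; unassigned cells keep a null label.
    """
    if config is None:
        config = FusionConfig()
    type_counts = estimate_type_counts(cells, deconv)
    k = deconv.n_types
    feats = cells.morphology.astype(float)
    if config.feature_standardization and cells.n_cells:
        feats = _standardize(feats)

    assigned_mask = cells.assigned_mask()
    idx = deconv.barcode_index()
    spot_of_cell = np.array(
        [idx[b] if b is not None else -1 for b in cells.spot_barcode], dtype=np.int64
    )

    # deconvolution-weighted initial centroids:
    #   μ_k = Σ_s Σ_{c∈s} p_sk f_c / Σ_s n_s p_sk
    p = deconv.proportions
    centroids = np.zeros((k, feats.shape[1] if cells.n_cells else 1))
    denom = np.zeros(k)
    if assigned_mask.any():
        w = p[spot_of_cell[assigned_mask]]  # (n_assigned, K)
        fa = feats[assigned_mask]
        centroids = (w.T @ fa)
        denom = w.sum(axis=0)
        nz = denom > 0
        centroids[nz] /= denom[nz, None]
        # a type never expected anywhere keeps its (zero) initial centroid
        centroids[~nz] = 0.0

    cell_order = np.flatnonzero(assigned_mask)
    # group assigned cells by spot once, in stable cell-index order
    order = cell_order[np.argsort(spot_of_cell[cell_order], kind="stable")]
    sorted_spots = spot_of_cell[order]
    cuts = np.flatnonzero(np.diff(sorted_spots)) + 1
    groups = [
        (int(g[0]), m)
        for g, m in zip(np.split(sorted_spots, cuts), np.split(order, cuts))
        if len(m)
    ]
    labels = np.full(cells.n_cells, -1, dtype=np.int64)
    n_assigned = int(assigned_mask.sum())

    for _ in range(config.max_iter):
        new_labels = labels.copy()
        for s, members in groups:
            new_labels[members] = constrained_label_assignment(
                feats[members], type_counts.counts[s], centroids
            )
        changed = int((new_labels != labels)[assigned_mask].sum())
        labels = new_labels
        # recompute centroids as means of currently-labelled cells
        for j in range(k):
            sel = labels == j
            if sel.any():
                centroids[j] = feats[sel].mean(axis=0)
        if n_assigned == 0 or changed <= config.tol * n_assigned:
            break

    out_labels = np.array(
        [
            deconv.cell_types[labels[i]] if labels[i] >= 0 else None
            for i in range(cells.n_cells)
        ],
        dtype=object,
    )
    labelled = CellTable(
        cell_ids=list(cells.cell_ids),
        x_um=cells.x_um.copy(),
        y_um=cells.y_um.copy(),
        morphology=cells.morphology.copy(),
        feature_names=list(cells.feature_names),
        spot_barcode=cells.spot_barcode.copy(),
        type_label=out_labels,
    )
    return labelled, type_counts
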