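"""Synthetic Visium tissue generator with retained ground truth.

Emulates the full input bundle a real experiment provides — spot lattice,
segmented cells with morphology, spot × gene counts, deconvolution
proportions, optional enriched regions — while keeping the true per-cell
type labels, so every downstream stage can be validated by parameter
recovery rather than by eye.

The model, deliberately minimal:

* spots sit on the standard Visium hexagonal lattice (55 µm spots,
  100 µm pitch, 78 × 64 = 4992 spots at default scale);
* each spot receives ``Poisson(cells_per_spot_mean)`` cells, placed
  uniformly inside the 27.5 µm spot disc; a configurable fraction of cells
  is relocated into the inter-spot gaps and loses its spot association
  (these mimic segmented cells that no barcode captures);
* a cell's type is drawn from a spot-level categorical field (uniform,
  Gaussian blobs, or concentric rings), with optional polygonal regions in
  which one type's odds are multiplied by an enrichment factor;
* morphology features are independent normals per type;
* spot expression is Poisson with rate equal to the sum of the per-type
  gene signatures of the cells in the spot;
* observed deconvolution rows are Dirichlet perturbations of the true
  per-spot label composition, with concentration α₀ (large α₀ → near-exact
  deconvolution).

One seed drives a single generator stream consumed in a fixed order
(cell counts → placement → relocation → types → morphology), so a given
(grid, params) pair is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CellTable, CountMatrix, DeconvMatrix, SpotGrid
from .errors import ParameterError

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "generate_visium_grid",
    "simulate_tissue",
    "simulate_deconvolution",
    "simulate_counts",
    "simulate_experiment",
    "default_params",
]

_PATTERNS = ("uniform", "blobs", "ring")
_DIRICHLET_EPS = 0.01  # keeps every Dirichlet concentration strictly positive


@dataclass
class SimulationParams:
    """Study conditions for one synthetic experiment.

    ``morphology_means``/``morphology_sds`` are K × F; ``expression_signatures``
    is K × G (mean transcript rate contributed per cell of each type).
    ``deconv_noise`` is the Dirichlet concentration multiplier α₀: observed
    proportion rows are drawn Dirichlet(α₀ · truth + 0.01).
    ``region_specs`` entries are ``(polygon, enriched_type, factor)`` — inside
    the polygon, the enriched type's odds are multiplied by ``factor``.
    """

    n_types: int = 3
    type_names: list[str] = None
    morphology_means: np.ndarray = None
    morphology_sds: np.ndarray = None
    spatial_pattern: str = "uniform"
    cells_per_spot_mean: float = 5.0
    region_specs: list = None
    expression_signatures: np.ndarray = None
    deconv_noise: float = 50.0
    frac_outside_spots: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        k = int(self.n_types)
        if k < 1:
            raise ParameterError("n_types must be ≥ 1")
        if self.type_names is None:
            self.type_names = [f"type_{chr(ord('A') + i)}" for i in range(k)]
        if len(self.type_names) != k:
            raise ParameterError("type_names length must equal n_types")
        if self.morphology_means is None:
            self.morphology_means = _separated_means(k, n_features=max(3, k), separation=3.0)
        self.morphology_means = np.atleast_2d(np.asarray(self.morphology_means, float))
        if self.morphology_means.shape[0] != k:
            raise ParameterError("morphology_means must have n_types rows")
        if self.morphology_sds is None:
            self.morphology_sds = np.ones_like(self.morphology_means)
        self.morphology_sds = np.atleast_2d(np.asarray(self.morphology_sds, float))
        if self.morphology_sds.shape != self.morphology_means.shape:
            raise ParameterError("morphology_sds shape must match morphology_means")
        if (self.morphology_sds <= 0).any():
            raise ParameterError("morphology_sds must be strictly positive")
        if self.spatial_pattern not in _PATTERNS:
            raise ParameterError(f"spatial_pattern must be one of {_PATTERNS}")
        if self.cells_per_spot_mean < 0:
            raise ParameterError("cells_per_spot_mean must be ≥ 0")
        if self.expression_signatures is None:
            self.expression_signatures = _marker_signatures(k, markers_per_type=10)
        self.expression_signatures = np.atleast_2d(
            np.asarray(self.expression_signatures, float)
        )
        if self.expression_signatures.shape[0] != k:
            raise ParameterError("expression_signatures must have n_types rows")
        if (self.expression_signatures < 0).any():
            raise ParameterError("expression_signatures must be nonnegative")
        if not self.deconv_noise > 0:
            raise ParameterError("deconv_noise (α₀) must be > 0")
        if not 0 <= self.frac_outside_spots < 1:
            raise ParameterError("frac_outside_spots must be in [0, 1)")
        if self.region_specs is not None:
            for _, enriched, factor in self.region_specs:
                if enriched not in self.type_names:
                    raise ParameterError(f"unknown enriched type {enriched!r}")
                if factor < 1:
                    raise ParameterError("enrichment factor must be ≥ 1")


@dataclass
class GroundTruth:
    """Simulated cells with true labels, plus the exact per-spot composition."""

    cells: CellTable
    true_proportions: DeconvMatrix
    grid: SpotGrid = field(repr=False, default=None)
    params: SimulationParams = field(repr=False, default=None)


def _separated_means(k: int, n_features: int, separation: float) -> np.ndarray:
    """Type mean vectors with pairwise Euclidean distance = ``separation``.

    Uses scaled simplex vertices: e_i and e_j are √2 apart, so scaling by
    separation/√2 yields the requested spacing for every pair.
    """
    means = np.zeros((k, n_features))
    scale = separation / np.sqrt(2.0)
    for i in range(k):
        means[i, i % n_features] += scale
    return means


def _marker_signatures(
    k: int, markers_per_type: int = 10, marker_rate: float = 2.0, base_rate: float = 0.2
) -> np.ndarray:
    """Block-diagonal marker panel: each type elevates its own gene block."""
    g = k * markers_per_type
    sig = np.full((k, g), base_rate)
    for i in range(k):
        sig[i, i * markers_per_type : (i + 1) * markers_per_type] = marker_rate
    return sig


def default_params(seed: int = 0, **overrides) -> SimulationParams:
    """The default study conditions (3 well-separated types, 5 cells/spot)."""
    return SimulationParams(seed=seed, **overrides)


def generate_visium_grid(
    n_rows: int = 78,
    spots_per_row: int = 64,
    pitch_um: float = 100.0,
    spot_diameter_um: float = 55.0,
) -> SpotGrid:
    """Build a hexagonal capture-area lattice.

    Consecutive rows are offset by pitch/2 horizontally and pitch·√3/2
    vertically, so the minimum centre-to-centre distance equals the pitch.
    Defaults reproduce a full Visium capture area: 78 × 64 = 4992 spots,
    55 µm diameter, 100 µm pitch.
    """
    if n_rows < 1 or spots_per_row < 1:
        raise ParameterError("n_rows and spots_per_row must be ≥ 1")
    if pitch_um <= 0 or spot_diameter_um <= 0:
        raise ParameterError("pitch and diameter must be positive")
    rows = np.repeat(np.arange(n_rows), spots_per_row)
    cols = np.tile(np.arange(spots_per_row), n_rows)
    x = cols * pitch_um + (rows % 2) * (pitch_um / 2.0)
    y = rows * (pitch_um * np.sqrt(3.0) / 2.0)
    barcodes = [f"spot-{r:03d}x{c:03d}" for r, c in zip(rows, cols)]
    return SpotGrid(
        barcodes=barcodes,
        array_row=rows,
        array_col=cols,
        x_um=x,
        y_um=y,
        in_tissue=np.ones(len(rows), dtype=bool),
        spot_diameter_um=spot_diameter_um,
        pitch_um=pitch_um,
    )


def _type_field(grid: SpotGrid, params: SimulationParams, rng) -> np.ndarray:
    """Per-spot categorical type probabilities (n_spots × K)."""
    k = params.n_types
    xy = grid.coords()
    if params.spatial_pattern == "uniform":
        weights = np.ones((grid.n_spots, k))
    elif params.spatial_pattern == "blobs":
        lo, hi = xy.min(axis=0), xy.max(axis=0)
        extent = float(np.max(hi - lo)) or 1.0
        centers = rng.uniform(lo, hi, size=(k, 2))
        sigma = 0.25 * extent
        d2 = ((xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        weights = np.exp(-d2 / (2 * sigma**2)) + 0.05
    else:  # ring
        center = xy.mean(axis=0)
        r = np.hypot(*(xy - center).T)
        rmax = r.max() or 1.0
        band_radii = np.linspace(0, rmax, k)
        sigma = rmax / (2.0 * k)
        weights = np.exp(-((r[:, None] - band_radii[None, :]) ** 2) / (2 * sigma**2)) + 0.05
    if params.region_specs:
        from shapely import contains_xy

        for poly, enriched, factor in params.region_specs:
            inside = contains_xy(poly, xy[:, 0], xy[:, 1])
            j = params.type_names.index(enriched)
            weights[inside, j] *= factor
    return weights / weights.sum(axis=1, keepdims=True)


def simulate_tissue(grid: SpotGrid, params: SimulationParams, rng=None) -> GroundTruth:
    """Draw cells, positions, true types and morphology for one experiment.

    Deterministic for a fixed (grid, params.seed): the generator stream is
    consumed in the order counts → in-disc placement → gap relocation →
    types → morphology.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    k = params.n_types
    n_spots = grid.n_spots

    n_per_spot = rng.poisson(params.cells_per_spot_mean, size=n_spots)
    total = int(n_per_spot.sum())
    spot_of_cell = np.repeat(np.arange(n_spots), n_per_spot)

    # uniform placement inside each 55 µm disc
    radius = grid.radius_um
    rr = radius * np.sqrt(rng.uniform(size=total))
    th = rng.uniform(0, 2 * np.pi, size=total)
    x = grid.x_um[spot_of_cell] + rr * np.cos(th)
    y = grid.y_um[spot_of_cell] + rr * np.sin(th)

    # relocate a fraction into inter-spot gaps: they keep type & morphology
    # but lose their barcode (segmentable, not deconvolvable)
    outside = rng.uniform(size=total) < params.frac_outside_spots
    n_out = int(outside.sum())
    if n_out:
        gx, gy = _sample_gap_points(grid, n_out, rng)
        x[outside], y[outside] = gx, gy

    probs = _type_field(grid, params, rng)
    u = rng.uniform(size=total)
    cum = np.cumsum(probs[spot_of_cell], axis=1)
    type_idx = (u[:, None] > cum).sum(axis=1)

    morph = rng.normal(
        params.morphology_means[type_idx], params.morphology_sds[type_idx]
    )

    labels = np.array([params.type_names[t] for t in type_idx], dtype=object)
    spot_bc = np.array(
        [None if outside[i] else grid.barcodes[spot_of_cell[i]] for i in range(total)],
        dtype=object,
    )
    cells = CellTable(
        cell_ids=[f"cell_{i:06d}" for i in range(total)],
        x_um=x,
        y_um=y,
        morphology=morph,
        feature_names=[f"feat_{j}" for j in range(params.morphology_means.shape[1])],
        spot_barcode=spot_bc,
        type_label=labels,
    )

    hist = np.zeros((n_spots, k))
    kept = ~outside
    np.add.at(hist, (spot_of_cell[kept], type_idx[kept]), 1.0)
    row_n = hist.sum(axis=1)
    props = np.where(row_n[:, None] > 0, hist / np.maximum(row_n, 1)[:, None], 1.0 / k)
    truth = DeconvMatrix(
        spot_barcodes=list(grid.barcodes),
        cell_types=list(params.type_names),
        proportions=props,
    )
    return GroundTruth(cells=cells, true_proportions=truth, grid=grid, params=params)


def _sample_gap_points(grid: SpotGrid, n: int, rng, max_tries: int = 50):
    """Rejection-sample points in the grid bounding box outside every disc."""
    from scipy.spatial import cKDTree

    tree = cKDTree(grid.coords())
    pad = grid.pitch_um / 2.0
    lo = grid.coords().min(axis=0) - pad
    hi = grid.coords().max(axis=0) + pad
    xs = np.empty(n)
    ys = np.empty(n)
    need = np.arange(n)
    for _ in range(max_tries):
        cand = rng.uniform(lo, hi, size=(len(need), 2))
        d, _idx = tree.query(cand)
        ok = d > grid.radius_um
        take = need[ok]
        xs[take], ys[take] = cand[ok, 0], cand[ok, 1]
        need = need[~ok]
        if not len(need):
            break
    if len(need):  # dense grid corner case: drop them on disc boundaries
        cand = rng.uniform(lo, hi, size=(len(need), 2))
        xs[need], ys[need] = cand[:, 0], cand[:, 1]
    return xs, ys


def simulate_deconvolution(
    truth: GroundTruth, alpha0: float = None, rng=None, seed: int = None
) -> DeconvMatrix:
    """Observed deconvolution: Dirichlet(α₀ · truth + 0.01) per spot.

    Spots containing zero cells get the exact uniform row. As α₀ → ∞ the
    rows converge to the true composition.
    """
    params = truth.params
    if alpha0 is None:
        alpha0 = params.deconv_noise if params is not None else 50.0
    if not alpha0 > 0:
        raise ParameterError("α₀ must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else 0)
    p = truth.true_proportions.proportions
    k = p.shape[1]
    assigned = [b for b in truth.cells.spot_barcode if b is not None]
    idx = truth.true_proportions.barcode_index()
    n_per_spot = np.zeros(p.shape[0])
    for b in assigned:
        n_per_spot[idx[b]] += 1

    conc = alpha0 * p + _DIRICHLET_EPS
    gam = rng.gamma(shape=conc)
    rows = gam / np.maximum(gam.sum(axis=1, keepdims=True), 1e-300)
    rows[n_per_spot == 0] = 1.0 / k
    return DeconvMatrix(
        spot_barcodes=list(truth.true_proportions.spot_barcodes),
        cell_types=list(truth.true_proportions.cell_types),
        proportions=rows,
    )


def simulate_counts(truth: GroundTruth, params: SimulationParams = None, rng=None, seed=None) -> CountMatrix:
    """Spot × gene counts: Poisson with rate Σ_{cells in spot} signature[type]."""
    if params is None:
        params = truth.params
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else 0)
    sig = params.expression_signatures
    k, g = sig.shape
    idx = truth.true_proportions.barcode_index()
    tmap = {t: i for i, t in enumerate(params.type_names)}
    hist = np.zeros((len(idx), k))
    for bc, lab in zip(truth.cells.spot_barcode, truth.cells.type_label):
        if bc is not None:
            hist[idx[bc], tmap[lab]] += 1
    rates = hist @ sig
    counts = rng.poisson(rates)
    return CountMatrix(
        spot_barcodes=list(truth.true_proportions.spot_barcodes),
        gene_ids=[f"gene_{j:04d}" for j in range(g)],
        counts=counts,
    )


def simulate_experiment(grid: SpotGrid = None, params: SimulationParams = None):
    """Convenience: one seed → (grid, truth, deconv, counts) with the stream
    consumed in that fixed order."""
    if params is None:
        params = default_params()
    if grid is None:
        grid = generate_visium_grid()
    rng = np.random.default_rng(params.seed)
    truth = simulate_tissue(grid, params, rng=rng)
    deconv = simulate_deconvolution(truth, params.deconv_noise, rng=rng)
    counts = simulate_counts(truth, params, rng=rng)
    return grid, truth, deconv, counts
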