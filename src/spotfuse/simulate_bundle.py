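"""Persist a synthetic experiment in the exact on-disk input formats.

Bridges the simulator and the I/O layer: one call writes positions +
scalefactors, the Matrix Market count triplet, the segmented-cell CSV, the
deconvolution CSV, optionally a GeoJSON region, the retained ground-truth
labels, and a ready-to-run pipeline config.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from . import io
from .containers import CellTable, RegionSet
from .synthetic import (
    SimulationParams,
    generate_visium_grid,
    simulate_counts,
    simulate_deconvolution,
    simulate_tissue,
)

__all__ = ["write_synthetic_bundle"]


def _central_square(grid, frac: float = 0.25):
    from shapely.geometry import box

    xs, ys = grid.x_um, grid.y_um
    cx, cy = xs.mean(), ys.mean()
    half_w = (xs.max() - xs.min()) * frac / 2 + grid.pitch_um
    half_h = (ys.max() - ys.min()) * frac / 2 + grid.pitch_um
    return box(cx - half_w, cy - half_h, cx + half_w, cy + half_h)


def write_synthetic_bundle(
    out_dir,
    seed: int = 0,
    n_rows: int = 78,
    spots_per_row: int = 64,
    cells_per_spot: float = 5.0,
    n_types: int = 3,
    alpha0: float = 50.0,
    pattern: str = "uniform",
    with_region: bool = False,
    params: SimulationParams | None = None,
) -> dict:
    """Simulate one experiment and write every pipeline input file.

    Returns a dict of written paths. The true per-cell labels go to
    ``truth_labels.csv`` (not consumed by the pipeline; kept for
    validation).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = generate_visium_grid(n_rows=n_rows, spots_per_row=spots_per_row)
    region = _central_square(grid) if with_region else None
    if params is None:
        params = SimulationParams(
            n_types=n_types,
            cells_per_spot_mean=cells_per_spot,
            spatial_pattern=pattern,
            deconv_noise=alpha0,
            seed=seed,
            region_specs=[(region, "type_A", 5.0)] if region is not None else None,
        )
    rng = np.random.default_rng(params.seed)
    truth = simulate_tissue(grid, params, rng=rng)
    deconv = simulate_deconvolution(truth, params.deconv_noise, rng=rng)
    counts = simulate_counts(truth, params, rng=rng)

    paths = {
        "positions": out / "tissue_positions.csv",
        "scalefactors": out / "scalefactors_json.json",
        "matrix": out / "matrix.mtx",
        "barcodes": out / "barcodes.tsv",
        "features": out / "features.tsv",
        "cells": out / "cells.csv",
        "deconvolution": out / "deconvolution.csv",
    }
    io.write_spot_positions(grid, paths["positions"], paths["scalefactors"])
    io.write_count_matrix(counts, paths["matrix"], paths["barcodes"], paths["features"])
    # the pipeline's cell input is unlabeled & unassigned: strip the truth
    blank = CellTable(
        cell_ids=list(truth.cells.cell_ids),
        x_um=truth.cells.x_um.copy(),
        y_um=truth.cells.y_um.copy(),
        morphology=truth.cells.morphology.copy(),
        feature_names=list(truth.cells.feature_names),
    )
    io.write_cell_table(blank, paths["cells"])
    io.write_deconvolution(deconv, paths["deconvolution"])
    io.write_cell_table(truth.cells, out / "truth_labels.csv")
    paths["truth_labels"] = out / "truth_labels.csv"

    if region is not None:
        paths["regions"] = out / "regions.geojson"
        io.write_regions_geojson(
            RegionSet(names=["enriched_square"], polygons=[region]), paths["regions"]
        )

    cfg = {
        "inputs": {k: str(v) for k, v in paths.items() if k != "truth_labels"},
        "stages": {s: True for s in ("assign", "fuse", "qc", "spatial", "report")}
        | {"regional": region is not None},
        "params": {},
        "output_dir": str(out / "results"),
        "seed": int(seed),
    }
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    paths["config"] = cfg_path
    return {k: str(v) for k, v in paths.items()}
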