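"""YAML-configured orchestration of the analysis stages.

Stages run in dependency order (io → assign → fuse → qc → spatial →
regional → report); each persists plain CSV/JSON outputs with documented
names so any downstream stage can be re-run alone. A run manifest records
the config snapshot, software version, input checksums and per-stage
status; identical inputs + config + seed give byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import geometry, io, qc, regional, spatial
from .errors import ParameterError, ValidationError
from .fusion import FusionConfig, fuse

__all__ = ["PipelineConfig", "RunManifest", "load_config", "run_pipeline"]

STAGES = ("assign", "fuse", "qc", "spatial", "regional", "report")

_DEFAULT_PARAMS = {
    "fusion": {"max_iter": 50, "tol": 0.0, "feature_standardization": True},
    "spatial": {
        "top_n_genes": 500,
        "n_perm": 199,
        "cell_graph_k": 6,
        "enrichment_n_perm": 999,
        "level": "cells",  # enrichment graph: fused cells (or "spots")
    },
    "regional": {
        "bin_width_um": 50.0,
        "max_distance_um": 200.0,
        "reference": "outside_all_bins",
    },
    "qc": {"mito_pattern": "MT-", "top_n_genes": 5},
}

_INPUT_KEYS = (
    "positions",
    "scalefactors",
    "matrix",
    "barcodes",
    "features",
    "cells",
    "deconvolution",
    "regions",
)
_OPTIONAL_INPUTS = ("scalefactors", "regions")


@dataclass
class PipelineConfig:
    inputs: dict
    stages: dict
    params: dict
    output_dir: Path
    seed: int = 0

    def validate(self) -> None:
        for key in self.inputs:
            if key not in _INPUT_KEYS:
                raise ParameterError(f"unknown input key {key!r}")
        for key in self.stages:
            if key not in STAGES:
                raise ParameterError(f"unknown stage {key!r}")
        for key in self.params:
            if key not in _DEFAULT_PARAMS:
                raise ParameterError(f"unknown parameter block {key!r}")
        for block, vals in self.params.items():
            for k in vals:
                if k not in _DEFAULT_PARAMS[block]:
                    raise ParameterError(f"unknown key {k!r} in {block!r} block")
        required = [k for k in _INPUT_KEYS if k not in _OPTIONAL_INPUTS]
        for key in required:
            if key not in self.inputs:
                raise ParameterError(f"missing required input {key!r}")
            if not Path(self.inputs[key]).exists():
                raise ParameterError(f"input file not found: {self.inputs[key]}")
        for key in _OPTIONAL_INPUTS:
            if key in self.inputs and not Path(self.inputs[key]).exists():
                raise ParameterError(f"input file not found: {self.inputs[key]}")
        if self.stages.get("regional", False) and "regions" not in self.inputs:
            raise ParameterError("regional stage enabled but no regions file given")

    def param(self, block: str, key: str):
        return self.params.get(block, {}).get(key, _DEFAULT_PARAMS[block][key])


def load_config(path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config. Unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known_top = {"inputs", "stages", "params", "output_dir", "seed"}
    unknown = set(raw) - known_top
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(
        inputs=dict(raw.get("inputs", {})),
        stages={s: bool(raw.get("stages", {}).get(s, True)) for s in STAGES},
        params={k: dict(v) for k, v in (raw.get("params") or {}).items()},
        output_dir=Path(raw.get("output_dir", "spotfuse_out")),
        seed=int(raw.get("seed", 0)),
    )
    cfg.validate()
    return cfg


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    input_checksums: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)

    def start(self, stage: str) -> None:
        self.stages[stage] = {"status": "running", "started": time.time()}

    def finish(self, stage: str, status: str = "ok", **extra) -> None:
        entry = self.stages.setdefault(stage, {})
        entry.update(status=status, ended=time.time(), **extra)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "config": self.config,
                    "input_checksums": self.input_checksums,
                    "stages": self.stages,
                },
                fh,
                indent=2,
                sort_keys=True,
                default=str,
            )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, verbose: bool = False) -> RunManifest:
    """Execute enabled stages in dependency order; halt on the first failure.

    Outputs land in ``config.output_dir``:
    ``cells_labeled.csv``, ``type_counts.csv``, ``qc_per_spot.csv``,
    ``qc_summary.csv``, ``descriptive_*.csv``, ``moran_genes.csv``,
    ``enrichment_z.csv``, ``region_<name>_{infiltration,de}.csv``,
    ``bundle/spots.h5ad``, ``bundle/cells.csv``, ``view.tmap``,
    ``report.html`` (+ per-region HTML), ``run_manifest.json``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={
            "inputs": {k: str(v) for k, v in config.inputs.items()},
            "stages": config.stages,
            "params": config.params,
            "output_dir": str(config.output_dir),
            "seed": config.seed,
        }
    )
    for key, path in sorted(config.inputs.items()):
        manifest.input_checksums[key] = _sha256(path)
    manifest_path = out / "run_manifest.json"
    manifest.write(manifest_path)

    def log(msg: str) -> None:
        if verbose:
            print(f"[spotfuse] {msg}")

    try:
        # --- io (always) -------------------------------------------------
        manifest.start("io")
        t0 = time.time()
        grid = io.read_spot_positions(
            config.inputs["positions"], config.inputs.get("scalefactors")
        )
        counts = io.read_count_matrix(
            config.inputs["matrix"], config.inputs["barcodes"], config.inputs["features"]
        )
        cells = io.read_cell_table(config.inputs["cells"])
        deconv = io.read_deconvolution(config.inputs["deconvolution"])
        regions = (
            io.read_regions_geojson(config.inputs["regions"])
            if "regions" in config.inputs
            else None
        )
        manifest.finish(
            "io",
            n_spots=grid.n_spots,
            n_cells=cells.n_cells,
            n_genes=counts.n_genes,
            wall_s=round(time.time() - t0, 3),
        )
        log(f"io: {grid.n_spots} spots, {cells.n_cells} cells, {counts.n_genes} genes")

        labelled = cells
        type_counts = None
        qc_report = None

        if config.stages.get("assign", True):
            manifest.start("assign")
            t0 = time.time()
            cells = geometry.assign_cells_to_spots(cells, grid)
            io.write_cell_table(cells, out / "cells_assigned.csv")
            n_assigned = int(cells.assigned_mask().sum())
            manifest.finish("assign", n_assigned=n_assigned, wall_s=round(time.time() - t0, 3))
            log(f"assign: {n_assigned}/{cells.n_cells} cells in spots")
            labelled = cells

        if config.stages.get("fuse", True):
            manifest.start("fuse")
            t0 = time.time()
            fcfg = FusionConfig(
                max_iter=int(config.param("fusion", "max_iter")),
                tol=float(config.param("fusion", "tol")),
                seed=config.seed,
                feature_standardization=bool(
                    config.param("fusion", "feature_standardization")
                ),
            )
            labelled, type_counts = fuse(cells, deconv, fcfg)
            io.write_cell_table(labelled, out / "cells_labeled.csv")
            tc = type_counts.to_frame()
            tc.index.name = "barcode"
            tc.to_csv(out / "type_counts.csv")
            manifest.finish("fuse", wall_s=round(time.time() - t0, 3))
            log("fuse: done")

        if config.stages.get("qc", True):
            manifest.start("qc")
            t0 = time.time()
            qc_report = qc.compute_qc(
                counts, grid, labelled, mito_pattern=str(config.param("qc", "mito_pattern"))
            )
            qc_report.per_spot.to_csv(out / "qc_per_spot.csv")
            qc_report.summary_frame().to_csv(out / "qc_summary.csv", index=False)
            desc = qc.descriptive_stats(
                labelled, counts, top_n=int(config.param("qc", "top_n_genes"))
            )
            for name, df in desc.items():
                df.to_csv(out / f"descriptive_{name}.csv", index=False)
            manifest.finish("qc", wall_s=round(time.time() - t0, 3))
            log("qc: done")

        if config.stages.get("spatial", True):
            manifest.start("spatial")
            t0 = time.time()
            spot_graph = geometry.build_spot_graph(grid)
            moran = spatial.screen_genes(
                counts,
                spot_graph,
                top_n=int(config.param("spatial", "top_n_genes")),
                n_perm=int(config.param("spatial", "n_perm")),
                seed=config.seed,
            )
            moran.to_csv(out / "moran_genes.csv", index=False)
            level = str(config.param("spatial", "level"))
            if level == "cells" and labelled.n_cells >= 2:
                graph = geometry.build_cell_graph(
                    labelled, k=int(config.param("spatial", "cell_graph_k"))
                )
                labels = labelled.type_label
            else:  # spot-level fallback: dominant deconvolved type per spot
                graph = spot_graph
                dom = deconv.proportions.argmax(axis=1)
                labels = np.array(
                    [deconv.cell_types[j] for j in dom], dtype=object
                )
            enr = spatial.neighborhood_enrichment(
                labels,
                graph,
                n_perm=int(config.param("spatial", "enrichment_n_perm")),
                seed=config.seed,
            )
            enr.to_frame().to_csv(out / "enrichment_z.csv")
            manifest.finish("spatial", wall_s=round(time.time() - t0, 3))
            log("spatial: done")

        if config.stages.get("regional", False) and regions is not None:
            manifest.start("regional")
            t0 = time.time()
            width = float(config.param("regional", "bin_width_um"))
            dmax = float(config.param("regional", "max_distance_um"))
            edges = np.arange(-dmax, dmax + width / 2, width)
            from shapely import contains_xy

            for name, poly in regions:
                prof = regional.infiltration_profile(
                    labelled,
                    poly,
                    region_name=name,
                    bin_edges=edges,
                    reference=str(config.param("regional", "reference")),
                )
                prof.table.to_csv(out / f"region_{name}_infiltration.csv", index=False)
                inside = contains_xy(poly, grid.x_um, grid.y_um)
                grp_a = [b for b, s in zip(grid.barcodes, inside) if s]
                grp_b = [b for b, s in zip(grid.barcodes, inside) if not s]
                if grp_a and grp_b:
                    de = regional.compare_regions_de(counts, grp_a, grp_b)
                    de.to_csv(out / f"region_{name}_de.csv", index=False)
            manifest.finish("regional", wall_s=round(time.time() - t0, 3))
            log("regional: done")

        if config.stages.get("report", True):
            manifest.start("report")
            t0 = time.time()
            results = {}
            if qc_report is not None:
                results["qc"] = qc_report.per_spot
            if type_counts is not None:
                results["type_counts"] = type_counts
            bundle_dir = out / "bundle"
            io.write_anndata_bundle(grid, counts, deconv, labelled, results, bundle_dir)
            io.write_tmap_config(bundle_dir, None, out / "view.tmap")
            from .report import render_report

            region_names = list(regions.names) if regions is not None else []
            render_report(out, region_names=region_names)
            manifest.finish("report", wall_s=round(time.time() - t0, 3))
            log("report: done")
    except Exception as exc:
        running = [s for s, v in manifest.stages.items() if v.get("status") == "running"]
        for s in running:
            manifest.finish(s, status="failed", error=str(exc))
        manifest.write(manifest_path)
        raise
    manifest.write(manifest_path)
    return manifest
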