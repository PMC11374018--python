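"""Per-spot and per-sample quality control, plus descriptive statistics.

The per-spot panel is the conventional Visium QC set: total UMIs, detected
genes, mitochondrial fraction (configurable gene-name pattern) and segmented
cells per spot. Sample summaries (medians are over in-tissue spots only)
support inter-sample comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CellTable, CountMatrix, SpotGrid
from .errors import ValidationError

__all__ = ["QCReport", "compute_qc", "descriptive_stats"]


@dataclass
class QCReport:
    per_spot: pd.DataFrame  # indexed by barcode
    per_sample: dict

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"metric": list(self.per_sample), "value": list(self.per_sample.values())}
        )


def compute_qc(
    counts: CountMatrix,
    grid: SpotGrid,
    cells: CellTable | None = None,
    mito_pattern: str = "MT-",
    case_insensitive: bool = True,
) -> QCReport:
    """Compute the QC panel for one sample.

    ``mito_pattern`` is a gene-name prefix (default the human "MT-"
    convention); spots with zero UMIs get mitochondrial fraction 0.
    """
    if counts.spot_barcodes != grid.barcodes:
        raise ValidationError("count matrix barcodes do not match the spot grid")
    if not grid.in_tissue.any():
        raise ValidationError("no in-tissue spots: QC is undefined")

    mat = counts.counts
    total = mat.sum(axis=1)
    genes_detected = (mat > 0).sum(axis=1)
    names = counts.gene_ids
    if case_insensitive:
        mito_mask = np.array(
            [g.upper().startswith(mito_pattern.upper()) for g in names]
        )
    else:
        mito_mask = np.array([g.startswith(mito_pattern) for g in names])
    mito = mat[:, mito_mask].sum(axis=1) if mito_mask.any() else np.zeros(len(total))
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)

    n_cells = np.zeros(grid.n_spots, dtype=np.int64)
    n_unassigned = 0
    if cells is not None:
        idx = grid.barcode_index()
        for b in cells.spot_barcode:
            if b is None:
                n_unassigned += 1
            else:
                n_cells[idx[b]] += 1

    per_spot = pd.DataFrame(
        {
            "total_umis": total,
            "genes_detected": genes_detected,
            "mito_fraction": mito_frac,
            "cells_per_spot": n_cells,
        },
        index=pd.Index(grid.barcodes, name="barcode"),
    )
    tissue = grid.in_tissue
    ps = per_spot.loc[tissue]
    per_sample = {
        "n_in_tissue_spots": int(tissue.sum()),
        "median_umis_per_spot": float(ps["total_umis"].median()),
        "median_genes_per_spot": float(ps["genes_detected"].median()),
        "frac_spots_zero_cells": float((ps["cells_per_spot"] == 0).mean()),
        "n_unassigned_cells": int(n_unassigned),
    }
    return QCReport(per_spot=per_spot, per_sample=per_sample)


def descriptive_stats(
    cells: CellTable, counts: CountMatrix, top_n: int = 5
) -> dict[str, pd.DataFrame]:
    """Cell-type frequencies, top-N expressed genes, per-spot composition summary.

    Top-N ties are broken alphabetically by gene id.
    """
    labelled = [t for t in cells.type_label if t is not None]
    freq = pd.Series(labelled, dtype=object).value_counts()
    type_table = pd.DataFrame(
        {
            "cell_type": freq.index,
            "n_cells": freq.to_numpy(),
            "fraction": freq.to_numpy() / max(len(labelled), 1),
        }
    ).sort_values(["n_cells", "cell_type"], ascending=[False, True], ignore_index=True)

    totals = pd.DataFrame(
        {"gene_id": counts.gene_ids, "total_umis": counts.counts.sum(axis=0)}
    )
    top_genes = totals.sort_values(
        ["total_umis", "gene_id"], ascending=[False, True], ignore_index=True
    ).head(top_n)

    # per-spot distribution of cell counts by type
    rows = []
    assigned = [
        (b, t)
        for b, t in zip(cells.spot_barcode, cells.type_label)
        if b is not None and t is not None
    ]
    if assigned:
        df = pd.DataFrame(assigned, columns=["barcode", "cell_type"])
        pivot = df.pivot_table(
            index="barcode", columns="cell_type", aggfunc="size", fill_value=0
        )
        for ct in sorted(pivot.columns):
            col = pivot[ct]
            rows.append(
                {
                    "cell_type": ct,
                    "mean_per_spot": float(col.mean()),
                    "median_per_spot": float(col.median()),
                    "max_per_spot": int(col.max()),
                }
            )
    spot_summary = pd.DataFrame(
        rows, columns=["cell_type", "mean_per_spot", "median_per_spot", "max_per_spot"]
    )
    return {
        "type_frequencies": type_table,
        "top_genes": top_genes,
        "per_spot_type_summary": spot_summary,
    }
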