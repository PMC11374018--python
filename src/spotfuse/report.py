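"""Standalone HTML reports assembled from persisted stage outputs.

One main report (QC, descriptive statistics, top Moran genes, enrichment
heatmap) plus one sub-report per annotated region (infiltration profile and
regional DE). Figures are matplotlib PNGs embedded base64, so each file is
self-contained. Rendering reads only the stage CSVs — re-rendering without
recomputation reproduces identical figure data.
"""

from __future__ import annotations

import base64
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["render_report"]

_PAGE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; max-width: 70em; }}
h1 {{ border-bottom: 2px solid #444; }}
h2 {{ color: #333; margin-top: 1.6em; }}
table {{ border-collapse: collapse; font-size: 0.9em; }}
th, td {{ border: 1px solid #bbb; padding: 0.3em 0.7em; text-align: right; }}
th {{ background: #eee; }}
img {{ max-width: 100%; }}
.note {{ color: #666; font-size: 0.85em; }}
</style>
</head>
<body>
<h1>{title}</h1>
{body}
</body>
</html>
"""


def _fig_to_b64(fig) -> str:
    buf = _io.BytesIO()
    fig.savefig(buf, format="png", dpi=110, bbox_inches="tight")
    import matplotlib.pyplot as plt

    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def _img(fig, alt: str) -> str:
    return f'<img alt="{alt}" src="data:image/png;base64,{_fig_to_b64(fig)}">'


def _table(df: pd.DataFrame, max_rows: int = 25) -> str:
    return df.head(max_rows).to_html(index=False, float_format=lambda v: f"{v:.4g}")


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise ValidationError(f"missing result file {path.name} (produced by the {stage!r} stage)")
    return path


def _enrichment_heatmap(df: pd.DataFrame):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = df.to_numpy(dtype=float)
    lim = max(np.abs(mat).max(), 1e-9)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(mat, cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.set_xticks(range(len(df.columns)), df.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(df.index)), df.index)
    fig.colorbar(im, ax=ax, label="enrichment z")
    ax.set_title("Neighborhood enrichment")
    return fig


def _infiltration_figure(table: pd.DataFrame, region: str):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    mid = (table["bin_lo_um"] + table["bin_hi_um"]) / 2
    for ct, sub in table.assign(mid=mid).groupby("cell_type"):
        ax.plot(sub["mid"], sub["proportion"], marker="o", label=ct)
    ax.axvline(0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("signed distance to border (µm; negative = inside)")
    ax.set_ylabel("cell-type proportion")
    ax.set_title(f"Infiltration: {region}")
    ax.legend(fontsize=7)
    return fig


def render_report(out_dir, region_names=None) -> list[Path]:
    """Render the main report and one sub-report per region from stage CSVs.

    Raises a validation error naming the producing stage when a required
    result file is absent. Returns the written HTML paths.
    """
    out = Path(out_dir)
    region_names = list(region_names or [])
    parts = []

    qc_summary = pd.read_csv(_require(out / "qc_summary.csv", "qc"))
    parts.append("<h2>Sample QC</h2>" + _table(qc_summary))
    qc_spot = pd.read_csv(_require(out / "qc_per_spot.csv", "qc"))
    parts.append(
        '<p class="note">Per-spot metrics (first rows):</p>' + _table(qc_spot, 8)
    )

    freq = pd.read_csv(_require(out / "descriptive_type_frequencies.csv", "qc"))
    parts.append("<h2>Cell-type composition</h2>" + _table(freq))
    top = pd.read_csv(_require(out / "descriptive_top_genes.csv", "qc"))
    parts.append("<h2>Top expressed genes</h2>" + _table(top))

    moran = pd.read_csv(_require(out / "moran_genes.csv", "spatial"))
    moran_top = moran.sort_values(["q", "variable"]).head(15)
    parts.append("<h2>Spatially autocorrelated genes (Moran's I)</h2>" + _table(moran_top))

    enr = pd.read_csv(_require(out / "enrichment_z.csv", "spatial"), index_col=0)
    parts.append("<h2>Neighborhood enrichment</h2>" + _img(_enrichment_heatmap(enr), "enrichment"))

    if region_names:
        links = "".join(
            f'<li><a href="report_region_{n}.html">{n}</a></li>' for n in region_names
        )
        parts.append(f"<h2>Region reports</h2><ul>{links}</ul>")

    written = []
    main = out / "report.html"
    main.write_text(_PAGE.format(title="spotfuse sample report", body="\n".join(parts)))
    written.append(main)

    for name in region_names:
        sub_parts = []
        inf = pd.read_csv(_require(out / f"region_{name}_infiltration.csv", "regional"))
        sub_parts.append(
            "<h2>Infiltration profile</h2>"
            + _img(_infiltration_figure(inf, name), f"infiltration {name}")
            + _table(inf, 40)
        )
        de_path = out / f"region_{name}_de.csv"
        if de_path.exists():
            de = pd.read_csv(de_path)
            sub_parts.append("<h2>Differential expression vs rest</h2>" + _table(de, 20))
        sub = out / f"report_region_{name}.html"
        sub.write_text(
            _PAGE.format(title=f"spotfuse region report: {name}", body="\n".join(sub_parts))
        )
        written.append(sub)
    return written
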