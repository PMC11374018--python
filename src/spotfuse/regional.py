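"""Region-of-interest analytics: infiltration profiles and comparative DE.

Infiltration: cells are binned by signed distance to an annotated region's
boundary (negative = inside); per bin and cell type, a two-proportion
Z-test compares the bin's composition against a reference population, with
BH correction across all bin × type tests in the region. Comparative DE
ranks genes between two spot groups with a tie-corrected rank-sum test on
library-size-normalized log1p values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CellTable, CountMatrix
from .errors import ParameterError, ValidationError
from .geometry import distance_to_boundary
from .spatial import bh_fdr, normalize_log1p

__all__ = [
    "ZTestResult",
    "InfiltrationProfile",
    "two_prop_ztest",
    "infiltration_profile",
    "compare_regions_de",
]

DEFAULT_BIN_EDGES = np.arange(-200.0, 201.0, 50.0)


@dataclass
class ZTestResult:
    x1: int
    n1: int
    x2: int
    n2: int
    pooled: float
    z: float
    p: float


@dataclass
class InfiltrationProfile:
    region: str
    bin_edges: np.ndarray
    table: pd.DataFrame  # bin × type rows with counts, proportions, z, p, q
    reference_counts: dict
    reference_total: int


def two_prop_ztest(x1: int, n1: int, x2: int, n2: int) -> ZTestResult:
    """Pooled two-proportion Z-test, two-sided.

    z = (x1/n1 − x2/n2) / √(p̂(1−p̂)(1/n1 + 1/n2)) with p̂ the pooled
    proportion. Degenerate pools (p̂ of 0 or 1, where the null variance
    vanishes) return z = 0, p = 1 by convention.
    """
    if n1 < 1 or n2 < 1:
        raise ParameterError("both group sizes must be ≥ 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValidationError("successes must satisfy 0 ≤ x ≤ n")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ZTestResult(x1, n1, x2, n2, pooled, 0.0, 1.0)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return ZTestResult(x1, n1, x2, n2, pooled, float(z), float(min(p, 1.0)))


def infiltration_profile(
    cells: CellTable,
    region,
    region_name: str = "region",
    bin_edges=None,
    reference: str = "outside_all_bins",
) -> InfiltrationProfile:
    """Cell-type composition vs signed distance from a region border.

    Distances are negative inside the region; default bins span −200 to
    +200 µm in 50 µm steps (≈ spot radius, the resolution floor of
    spot-level positioning). ``reference`` is either ``outside_all_bins``
    (cells farther outside than the outermost bin edge) or ``tissue_wide``
    (all labelled cells). Each (bin, type) pair is Z-tested against the
    reference and BH-adjusted across all tests in the region.
    """
    if bin_edges is None:
        bin_edges = DEFAULT_BIN_EDGES
    bin_edges = np.asarray(bin_edges, dtype=float)
    if len(bin_edges) < 2 or (np.diff(bin_edges) <= 0).any():
        raise ParameterError("bin edges must be strictly increasing")
    if reference not in ("outside_all_bins", "tissue_wide"):
        raise ParameterError(f"unknown reference population {reference!r}")

    labelled = np.array([t is not None for t in cells.type_label], dtype=bool)
    if not labelled.any():
        raise ValidationError("no labelled cells")
    xy = cells.coords()[labelled]
    labs = np.array([str(t) for t in cells.type_label[labelled]], dtype=object)
    d = distance_to_boundary(xy, region)

    types = sorted(set(labs))
    in_range = (d >= bin_edges[0]) & (d < bin_edges[-1])
    if not in_range.any():
        raise ValidationError("all distance bins are empty")
    bin_idx = np.digitize(d, bin_edges) - 1  # valid only where in_range

    if reference == "outside_all_bins":
        ref_mask = d >= bin_edges[-1]
        if not ref_mask.any():
            ref_mask = ~in_range  # fall back to any out-of-range cell
        if not ref_mask.any():
            ref_mask = np.ones(len(d), dtype=bool)
    else:
        ref_mask = np.ones(len(d), dtype=bool)
    ref_total = int(ref_mask.sum())
    ref_counts = {t: int((labs[ref_mask] == t).sum()) for t in types}

    rows = []
    n_bins = len(bin_edges) - 1
    for b in range(n_bins):
        sel = in_range & (bin_idx == b)
        bin_total = int(sel.sum())
        for t in types:
            x = int((labs[sel] == t).sum())
            row = {
                "bin_lo_um": bin_edges[b],
                "bin_hi_um": bin_edges[b + 1],
                "cell_type": t,
                "count": x,
                "bin_total": bin_total,
                "proportion": x / bin_total if bin_total else np.nan,
                "ref_proportion": ref_counts[t] / ref_total if ref_total else np.nan,
            }
            if bin_total >= 1 and ref_total >= 1:
                zt = two_prop_ztest(x, bin_total, ref_counts[t], ref_total)
                row["z"] = zt.z
                row["p"] = zt.p
            else:
                row["z"] = np.nan
                row["p"] = np.nan
            rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    table["q"] = np.nan
    if ok.any():
        table.loc[ok, "q"] = bh_fdr(table.loc[ok, "p"].to_numpy())
    return InfiltrationProfile(
        region=region_name,
        bin_edges=bin_edges,
        table=table,
        reference_counts=ref_counts,
        reference_total=ref_total,
    )


def compare_regions_de(
    counts: CountMatrix, group_a, group_b, min_group_warn: int = 3
) -> pd.DataFrame:
    """Rank-sum differential expression between two disjoint spot groups.

    Values are counts-per-10k log1p; per gene: two-sided Wilcoxon rank-sum
    (normal approximation, tie-corrected), log2 fold change of group means
    (pseudocount 1), BH q. Sorted by q then |log2FC| descending. Groups
    smaller than ``min_group_warn`` are flagged ``low_power``.
    """
    idx = {b: i for i, b in enumerate(counts.spot_barcodes)}
    a = sorted({str(s) for s in group_a})
    b = sorted({str(s) for s in group_b})
    if not a or not b:
        raise ValidationError("both groups must be non-empty")
    if set(a) & set(b):
        raise ValidationError("groups must be disjoint")
    unknown = [s for s in a + b if s not in idx]
    if unknown:
        raise ValidationError(f"unknown spot barcodes: {unknown[:5]}")
    ia = np.array([idx[s] for s in a])
    ib = np.array([idx[s] for s in b])
    norm = normalize_log1p(counts)
    xa, xb = norm[ia], norm[ib]
    mean_a, mean_b = xa.mean(axis=0), xb.mean(axis=0)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    pvals = np.ones(counts.n_genes)
    for g in range(counts.n_genes):
        col_a, col_b = xa[:, g], xb[:, g]
        if np.ptp(np.concatenate([col_a, col_b])) == 0:
            pvals[g] = 1.0
            continue
        res = stats.mannwhitneyu(col_a, col_b, alternative="two-sided", method="asymptotic")
        pvals[g] = min(max(res.pvalue, np.finfo(float).tiny), 1.0)
    q = bh_fdr(pvals)
    low_power = min(len(a), len(b)) < min_group_warn
    df = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p": pvals,
            "q": q,
            "low_power": low_power,
        }
    )
    df["abs_fc"] = df["log2fc"].abs()
    df = df.sort_values(
        ["q", "abs_fc", "gene_id"], ascending=[True, False, True], ignore_index=True
    ).drop(columns="abs_fc")
    return df
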