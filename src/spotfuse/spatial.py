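"""Spatial-structure statistics: Moran's I and neighborhood enrichment.

Moran's I over a weights graph, with two-sided permutation inference and
BH correction across variables; neighborhood enrichment as a permutation
z-score for how often cell-type pairs are adjacent. Both operate on any
:class:`~spotfuse.containers.WeightsGraph` — the fused cell-level graph
(near single-cell resolution) or the spot lattice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, WeightsGraph
from .errors import ParameterError, ValidationError, ZeroVarianceError

__all__ = [
    "MoranResult",
    "EnrichmentMatrix",
    "morans_i",
    "morans_i_test",
    "morans_i_table",
    "bh_fdr",
    "neighborhood_enrichment",
    "normalize_log1p",
]


@dataclass
class MoranResult:
    variable: str
    I: float
    p_perm: float
    q: float | None
    n_perm: int


@dataclass
class EnrichmentMatrix:
    cell_types: list[str]
    z: np.ndarray  # (K, K) symmetric
    observed: np.ndarray  # (K, K) symmetric edge counts
    perm_mean: np.ndarray
    perm_sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.cell_types, columns=self.cell_types)


def _edge_coefficients(graph: WeightsGraph, row_standardize: bool):
    """Per-edge symmetric coefficients c_e such that
    Σ_ij w_ij z_i z_j = Σ_e c_e z_{i_e} z_{j_e}, and W = Σ_e c_e."""
    if graph.n_edges == 0:
        raise ValidationError("graph has no edges")
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    w = graph.weights
    if row_standardize:
        rs = np.zeros(graph.n_nodes)
        np.add.at(rs, i, w)
        np.add.at(rs, j, w)
        if (rs[np.unique(graph.edges)] == 0).any():
            raise ValidationError("zero row sum on a connected node")
        coef = w * (1.0 / rs[i] + 1.0 / rs[j])
    else:
        coef = 2.0 * w
    return i, j, coef


def morans_i(values, graph: WeightsGraph, row_standardize: bool = False) -> float:
    """Global Moran's I: I = (N/W) · Σ_ij w_ij z_i z_j / Σ_i z_i².

    z_i are deviations from the mean; W counts both directions of every
    undirected edge. Binary weights by default; with row standardization
    the statistic is confined to [−1, 1].
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) != graph.n_nodes:
        raise ValidationError("values must be a vector with one entry per node")
    if graph.n_nodes < 2:
        raise ValidationError("Moran's I needs at least 2 nodes")
    z = x - x.mean()
    ss = float(z @ z)
    if ss == 0.0:
        raise ZeroVarianceError("values have zero variance; Moran's I undefined")
    i, j, coef = _edge_coefficients(graph, row_standardize)
    num = float((coef * z[i] * z[j]).sum())
    w_total = float(coef.sum())
    return (graph.n_nodes / w_total) * num / ss


def morans_i_test(
    values,
    graph: WeightsGraph,
    n_perm: int = 999,
    seed: int = 0,
    row_standardize: bool = False,
    variable: str = "",
) -> MoranResult:
    """Two-sided permutation test for Moran's I.

    p = (1 + #{|I_perm| ≥ |I_obs|}) / (n_perm + 1) over uniform random
    relabelings of the values across nodes; exact under exchangeability.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be ≥ 1")
    x = np.asarray(values, dtype=float)
    i_obs = morans_i(x, graph, row_standardize)
    rng = np.random.default_rng(seed)
    z = x - x.mean()
    i, j, coef = _edge_coefficients(graph, row_standardize)
    # I_perm differs from I_obs only through the cross-product term
    perms = np.argsort(rng.random((n_perm, len(z))), axis=1)
    zp = z[perms]  # (n_perm, N)
    nums = (coef[None, :] * zp[:, i] * zp[:, j]).sum(axis=1)
    scale = (graph.n_nodes / float(coef.sum())) / float(z @ z)
    i_perm = scale * nums
    p = (1.0 + np.count_nonzero(np.abs(i_perm) >= abs(i_obs) - 1e-15)) / (n_perm + 1.0)
    return MoranResult(variable=variable, I=i_obs, p_perm=float(p), q=None, n_perm=n_perm)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def normalize_log1p(counts: CountMatrix, target_sum: float = 1e4) -> np.ndarray:
    """Library-size normalization to ``target_sum`` per spot, then log1p.

    All-zero spots stay all-zero.
    """
    mat = counts.counts.astype(float)
    lib = mat.sum(axis=1, keepdims=True)
    scaled = np.divide(mat * target_sum, lib, out=np.zeros_like(mat), where=lib > 0)
    return np.log1p(scaled)


def morans_i_table(
    values: np.ndarray,
    variable_names: list[str],
    graph: WeightsGraph,
    n_perm: int = 999,
    seed: int = 0,
    row_standardize: bool = False,
) -> pd.DataFrame:
    """Moran's I + permutation p per column, BH-adjusted across columns.

    Zero-variance columns are reported with null statistics rather than
    failing the whole screen. Each column gets its own independent
    permutation stream derived from ``seed``.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != len(variable_names):
        raise ValidationError("one name per value column required")
    root = np.random.default_rng(seed)
    col_seeds = root.integers(0, 2**31 - 1, size=len(variable_names))
    rows = []
    for c, name in enumerate(variable_names):
        col = values[:, c]
        if np.ptp(col) == 0:
            rows.append({"variable": name, "I": np.nan, "p_perm": np.nan})
            continue
        res = morans_i_test(
            col, graph, n_perm=n_perm, seed=int(col_seeds[c]),
            row_standardize=row_standardize, variable=name,
        )
        rows.append({"variable": name, "I": res.I, "p_perm": res.p_perm})
    df = pd.DataFrame(rows)
    ok = df["p_perm"].notna()
    df["q"] = np.nan
    if ok.any():
        df.loc[ok, "q"] = bh_fdr(df.loc[ok, "p_perm"].to_numpy())
    df["n_perm"] = n_perm
    return df


def screen_genes(
    counts: CountMatrix, graph: WeightsGraph, top_n: int = 500, n_perm: int = 199,
    seed: int = 0, raw: bool = False,
) -> pd.DataFrame:
    """Per-gene Moran screen on the ``top_n`` genes by total counts.

    Values are library-size-normalized and log1p-transformed unless
    ``raw=True``. The spot graph's node order must match the count matrix.
    """
    if counts.spot_barcodes != graph.node_ids:
        raise ValidationError("count matrix and graph node order differ")
    totals = counts.counts.sum(axis=0)
    order = np.lexsort((np.array(counts.gene_ids), -totals))[:top_n]
    mat = counts.counts.astype(float) if raw else normalize_log1p(counts)
    return morans_i_table(
        mat[:, order], [counts.gene_ids[g] for g in order], graph,
        n_perm=n_perm, seed=seed,
    )


def neighborhood_enrichment(
    labels,
    graph: WeightsGraph,
    n_perm: int = 999,
    seed: int = 0,
) -> EnrichmentMatrix:
    """Permutation z-scores for cell-type adjacency.

    o[k,l] counts edges joining a type-k and a type-l node; the null
    permutes labels uniformly over labelled nodes. Pairs whose permutation
    null is degenerate (sd 0) get z = 0 by convention. Edges touching an
    unlabelled node are ignored.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != graph.n_nodes:
        raise ValidationError("one label per node required")
    labelled = np.array([lab is not None for lab in labels], dtype=bool)
    if not labelled.any():
        raise ValidationError("all nodes are unlabelled")
    if graph.n_edges == 0:
        raise ValidationError("graph has no edges")
    types = sorted({str(lab) for lab in labels[labelled]})
    k = len(types)
    tmap = {t: i for i, t in enumerate(types)}
    code = np.full(graph.n_nodes, -1, dtype=np.int64)
    for n_i in np.flatnonzero(labelled):
        code[n_i] = tmap[str(labels[n_i])]

    e = graph.edges
    keep = (code[e[:, 0]] >= 0) & (code[e[:, 1]] >= 0)
    ei, ej = e[keep, 0], e[keep, 1]

    def pair_counts(c: np.ndarray) -> np.ndarray:
        a, b = c[ei], c[ej]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        flat = np.bincount(lo * k + hi, minlength=k * k).reshape(k, k)
        full = flat + flat.T
        np.fill_diagonal(full, np.diag(flat))
        return full

    observed = pair_counts(code)
    rng = np.random.default_rng(seed)
    lab_nodes = np.flatnonzero(labelled)
    base = code[lab_nodes]
    mean = np.zeros((k, k))
    m2 = np.zeros((k, k))
    for t in range(n_perm):
        c = code.copy()
        c[lab_nodes] = base[rng.permutation(len(base))]
        o = pair_counts(c).astype(float)
        delta = o - mean
        mean += delta / (t + 1)
        m2 += delta * (o - mean)
    sd = np.sqrt(m2 / n_perm) if n_perm > 0 else np.zeros((k, k))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (observed - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return EnrichmentMatrix(
        cell_types=types, z=z, observed=observed, perm_mean=mean, perm_sd=sd
    )
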