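# spotfuse

Near single-cell analysis of 10x Visium spatial transcriptomics.

A Visium capture area carries 4992 barcoded spots, each 55 µm in diameter on
a hexagonal lattice with 100 µm pitch — and each spot usually contains
several cells. Spot-level deconvolution tells you *what mixture* of cell
types produced a spot's transcripts; H&E image segmentation tells you *which
individual cells* sit where. `spotfuse` fuses the two into per-cell type
labels, then quantifies the spatial structure of the labelled tissue. It is
aimed at computational biologists who already have SpaceRanger outputs, a
segmented-cell table and a deconvolution matrix, and want labelled cells and
spatial statistics without stitching five tools together.

## The method

For each spot *s* with `n_s` segmented cells and deconvolved proportions
`p_sk` over *K* types:

1. **Integer apportionment.** Expected counts `n_s·p_sk` become integers
   `c_sk` by largest-remainder (Hamilton) apportionment — floors first, the
   leftover units go to the largest fractional remainders — so
   `Σ_k c_sk = n_s` holds exactly in every spot.
2. **Morphology-constrained labelling.** Within each spot, cells are matched
   to type slots minimizing `Σ_cells ‖f_c − μ_label‖²` over standardized
   morphology features, subject to exactly `c_sk` cells per type. The match
   is solved exactly as a unit-supply transportation problem. Tissue-wide
   type centroids `μ_k` (initialized as deconvolution-weighted feature
   means) are refined by Lloyd-style alternation; the objective never
   increases and the per-spot counts are respected at every iteration.
3. **Spatial statistics** on the result:
   * global **Moran's I**, `I = (N/W)·Σ_ij w_ij z_i z_j / Σ_i z_i²`, with
     two-sided permutation p-values and BH correction across genes;
   * **neighborhood enrichment**: permutation z-scores for how often
     cell-type pairs are adjacent in the k-NN cell graph;
   * **infiltration profiles**: cell-type proportions in 50 µm bins of
     signed distance from an annotated region border (negative = inside),
     each bin tested against a reference population with a pooled
     two-proportion Z-test, `z = (p̂₁−p̂₂)/√(p̂(1−p̂)(1/n₁+1/n₂))`;
   * rank-sum differential expression between regions on counts-per-10k
     log1p values.

A built-in synthetic Visium simulator generates the full input bundle —
lattice, cells with morphology, counts, Dirichlet-noised deconvolution,
enriched regions — with ground-truth labels retained, so every stage is
testable by parameter recovery.

## Worked example

```python
import numpy as np
import spotfuse as sf

grid = sf.generate_visium_grid(10, 20)          # 200-spot mini capture area
params = sf.default_params(seed=1)              # 3 types, 5 cells/spot
grid, truth, deconv, counts = sf.simulate_experiment(grid, params)

cells = sf.assign_cells_to_spots(truth.cells, grid)
labelled, type_counts = sf.fuse(cells, deconv, sf.FusionConfig(seed=1))

mask = cells.assigned_mask()
acc = np.mean([a == b for a, b, m in
               zip(labelled.type_label, truth.cells.type_label, mask) if m])
print(f"cells simulated: {truth.cells.n_cells}, assigned to spots: {int(mask.sum())}")
print(f"per-spot count conservation: "
      f"{bool((type_counts.counts.sum(1) == type_counts.n_cells).all())}")
print(f"label recovery vs ground truth: {acc:.3f}")

g = sf.build_spot_graph(grid)
res = sf.morans_i_test(grid.x_um + grid.y_um, g, n_perm=999, seed=1)
print(f"Moran's I of a smooth gradient: I={res.I:.3f}, p={res.p_perm:.4f}")
```

prints

```
cells simulated: 1044, assigned to spots: 940
per-spot count conservation: True
label recovery vs ground truth: 0.916
Moran's I of a smooth gradient: I=0.915, p=0.0010
```

940 of 1044 simulated cells fall inside spot discs (the rest sit in
inter-spot gaps and cannot be deconvolved); with the default moderate
deconvolution noise 91.6% of assigned cells recover their true type, and a
coordinate gradient is, as it must be, strongly spatially autocorrelated.

## Command line

```sh
spotfuse simulate --out sim/ --seed 1 --with-region   # write a synthetic input bundle
spotfuse run      --config sim/config.yaml            # full pipeline → CSVs, h5ad, .tmap, HTML report
spotfuse fuse     --config sim/config.yaml            # assignment + fusion only
spotfuse analyze  --config sim/config.yaml            # everything except the HTML report
spotfuse report   --out sim/results                   # re-render reports from persisted CSVs
```

The YAML config declares input paths, stage toggles, per-stage parameters,
an output directory and one global seed; unknown keys are rejected. Every
run writes a `run_manifest.json` with input checksums and per-stage status —
identical inputs, config and seed give byte-identical CSV outputs.

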