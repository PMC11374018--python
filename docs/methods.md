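# Methods

This note documents the models, parameter choices and numerical
conventions behind `spotfuse`, and what the synthetic-data validation does
and does not demonstrate.

## Coordinate frame and geometry

All internal geometry is in micrometres, origin at the top-left of the
image frame with y increasing downward (image convention). File readers
convert at the I/O boundary only: pixel coordinates from a positions table
are scaled by microns-per-pixel, taken directly from the scalefactors JSON
when present or derived as 55 µm divided by the spot diameter in full-res
pixels (the Visium spot's physical diameter is fixed by the assay). Both
positions dialects — headerless six-column and headered — are auto-detected
from the first line.

The simulated capture area is a hexagonal lattice: consecutive rows are
offset by pitch/2 horizontally and pitch·√3/2 vertically, which makes the
minimum centre-to-centre distance exactly the pitch (100 µm by default;
78 rows × 64 spots = 4992 spots, 55 µm spot diameter).

A cell belongs to the spot whose disc (radius = diameter/2, boundary
inclusive) contains its centroid. On a Visium lattice discs never overlap,
so the assignment is unambiguous up to exact radius ties, which are broken
toward the lexicographically smallest barcode with a 1e-9 µm tolerance.
Centroid-in-disc was chosen over mask-overlap because the pipeline consumes
centroids and features only, not segmentation masks.

Spot adjacency uses a 1.05 × pitch cut-off — enough slack for
floating-point jitter, far below the next lattice shell at √3 × pitch. The
cell graph is a symmetrized k-nearest-neighbour graph (k = 6 by default,
matching the hexagonal coordination number); weights are binary.

Signed boundary distances are negative inside a region, positive outside,
zero on the border, so infiltration depth reads as a negative coordinate.
Polygon holes count as boundary and their interiors as outside.

## Fusion

Fractional expected counts `n_s·p_sk` are converted to integers by
largest-remainder (Hamilton) apportionment. Remainder ties go to the larger
proportion, then to the lower type index. Hamilton was picked over
divisor methods because it satisfies the quota property (every `c_sk` is
the floor or ceiling of its quota), conserves totals exactly, and has no
systematic bias toward abundant types.

The per-spot labelling is solved exactly: each type contributes `c_sk`
unit-demand columns and the Hungarian algorithm matches cells to columns
under squared-Euclidean cost in standardized feature space. Spots are small
(typically < 20 cells), so exactness costs essentially nothing and removes
any greedy-ordering artefact. Constraints are per spot; centroids are
tissue-wide, so morphologically similar cells receive the same label across
the whole section.

Morphology features are standardized tissue-wide to zero mean and unit
variance by default, because raw features (area vs. eccentricity, say) live
on wildly different scales; a zero-variance feature is left unscaled.
Centroids are initialized as deconvolution-weighted feature means
`μ_k = Σ_s Σ_{c∈s} p_sk f_c / Σ_s n_s p_sk`; a type with zero total
expected weight keeps its initial centroid rather than dividing by zero.
Alternation stops when no label changes (an optional tolerance allows a
small changed fraction) with a 50-iteration cap; the assignment step is
optimal per spot and the centroid step is a mean, so the global objective
is non-increasing and termination is guaranteed in practice by the cap.
Cells outside every spot disc cannot be deconvolved and keep a null label;
spots where segmentation finds no cells produce all-zero count rows and
surface in QC as `frac_spots_zero_cells`.

## Spatial statistics

Moran's I is computed as `(N/W)·Σ_ij w_ij z_i z_j / Σ z_i²` with both
directions of each undirected edge counted in `W`. Binary weights are the
default; row-standardized weights are available (and confine I to [−1, 1]).
Constant input raises an explicit zero-variance error instead of returning
NaN. Inference is a two-sided permutation test,
`p = (1 + #{|I_perm| ≥ |I_obs|}) / (n_perm + 1)`, exact under
exchangeability; each variable in a multi-variable screen gets an
independent permutation stream derived from the global seed, and BH
correction is applied across variables. The per-gene screen runs on
counts-per-10k log1p values (raw-count option retained) and tests the top
500 genes by total counts by default to bound runtime; both are
configurable.

Neighborhood enrichment counts edges joining each type pair, permutes
labels over labelled nodes (unlabelled nodes and their edges are ignored),
and reports `z = (o − mean_perm)/sd_perm`, with z = 0 when the permutation
null is degenerate. The permutation mean/SD accumulate via Welford's
algorithm, so memory does not grow with `n_perm`. Enrichment runs on the
fused cell-level graph by default — that near single-cell resolution is the
point of fusion — with a spot-level mode (dominant deconvolved type per
spot) as a fallback.

## Regional analysis

Infiltration bins span ±200 µm from the border in 50 µm steps by default:
50 µm is roughly the spot radius, and finer bins would be spurious given
that cell positions are only known to within a spot (±55 µm). Each
(bin, type) pair is compared against a reference population with the pooled
two-proportion Z-test; a pooled proportion of exactly 0 or 1 has zero null
variance and returns z = 0, p = 1 by convention. The default reference is
the cells beyond the outermost outside bin — i.e. tissue far from the
border — with a tissue-wide option; the choice is declared in the output
rather than inferred. BH correction is applied across all bin × type tests
within a region. Empty bins are reported with null statistics.

Comparative DE between spot groups uses the two-sided Wilcoxon rank-sum
test (normal approximation with tie correction) on counts-per-10k log1p
values, log2 fold change of group means with pseudocount 1, and BH
correction; groups smaller than 3 spots are flagged low-power rather than
refused.

## Synthetic tissue

The simulator emulates the five input artefacts with ground truth retained.
Per spot, the cell count is Poisson (default mean 5 cells/spot, a typical
Visium occupancy); cells are placed uniformly in the spot disc, and a
configurable fraction (default 0.10) is relocated into inter-spot gaps to
mimic segmented cells no barcode captures. Types follow a spot-level
categorical field — uniform, Gaussian blobs, or concentric rings — with
optional polygonal regions multiplying one type's odds by an enrichment
factor. Morphology features are independent normals per type; the default
type means sit at pairwise distance 3 SD, a separation at which morphology
is informative but not trivially so. Expression is Poisson with rate equal
to the summed per-type gene signatures of a spot's cells (default: 10
marker genes per type at rate 2 against a 0.2 baseline). Observed
deconvolution rows are Dirichlet(α₀·truth + 0.01) — α₀ defaults to 50,
i.e. visibly noisy but informative; α₀ → ∞ recovers the truth, and
zero-cell spots get the exact uniform row (also the convention for the
ground-truth proportions of empty spots, where a normalized histogram is
undefined). One seed drives a single generator stream consumed in a fixed
order (counts → placement → relocation → types → morphology), so every
simulation is exactly reproducible. A full default-scale simulation
(4992 spots, ≈25 000 cells) takes well under a second.

What the simulator does **not** model: transcript capture efficiency and
dropout, segmentation errors and doublets, correlated morphology features,
nucleus overlap, and H&E pixels. Passing recovery tests therefore shows the
fusion machinery is correct and well-calibrated under its own assumptions —
not that real deconvolution output is this well-behaved. On real tissue,
types that morphology cannot separate will be apportioned correctly in
aggregate but labelled near-randomly among themselves within a spot.

## Validation sizes and determinism

The validation suite runs at deliberately modest scales chosen to exercise
every code path with tight Monte-Carlo bounds: recovery experiments on
200-spot tissues (~1000 cells), count-conservation sweeps across 100
simulation seeds, Moran calibration with 200 variables × 199 permutations,
enrichment nulls over 20 replicate labelings. The ground-truth recovery
threshold of 95% (3-SD morphology separation, α₀ = 10⁶, seed fixed) was
pinned from the package's own first oracle run at those conditions, which
measured 95.4%; recovery is monotone non-decreasing in both separation and
α₀ across the tested 3 × 3 grid. The whole pipeline is a pure function of
(inputs, config, seed) at the level of emitted CSV content; HTML reports
embed matplotlib figures and are deterministic given identical upstream
CSVs.

## Known limitations

* Fusion accuracy is bounded by deconvolution quality; the apportionment
  inherits any bias in `p_sk` untouched.
* The transportation solve is exact per spot, but the alternating loop is
  a local optimizer over centroids — a poor initialization can settle in a
  suboptimal labelling (mitigated by the deconvolution-weighted start).
* Permutation tests assume exchangeability across nodes; strong library-
  size gradients can violate it for raw counts (hence the normalized
  default).
* The two-proportion Z-test treats cells as independent; cells in the same
  spot are not, so infiltration p-values on real data are mildly
  anti-conservative at high per-spot counts.
* Only Visium-style geometry is supported; no HD/Xenium-style layouts.
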