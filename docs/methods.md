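# Methods

`nichetda` predicts whether a simulated tumour will form a *perivascular
niche* — a blood vessel with at least 10 tumour cells within 5 distance
units — from the spatial arrangement of tumour cells and macrophages well
before the niche exists. The prediction target is binary: label 1 if at
least one niche exists at the final (500 h) snapshot, 0 otherwise. Features
are persistence images computed from four filtrations of the cell point
clouds; classifiers are L2-regularised logistic regressions whose
coefficient maps are interpretable in image coordinates.

All lengths are in simulation units (cell radius 0.5, so one cell diameter
= 1 unit); times are in hours.

## Filtrations

**Vietoris–Rips (VR).** For a static point cloud, vertices enter at 0, an
edge `{x, y}` at `d(x, y)` (closed-ball convention), and a triangle at the
largest of its edge values. Complexes are capped at dimension 2 (only H0
and H1 are used). Filtration order breaks value ties by dimension and then
lexicographic vertex tuple, making every output deterministic. VR
filtrations are truncated at a maximum radius matched to the image window
(5 for tumour, 10 for macrophage clouds); features still alive at the cap
are dropped from images and their count logged, since the dominant
essential component carries no discriminative information.

**Radial.** A fixed-radius complex (linkage ε = 0.7 for tumour cells,
from a coarse accuracy sweep) filtered by `w = R − ‖x − μ‖` with basepoint
μ = (25, 25) — the initial tumour location — and R = 35. Outermost cells
enter first; a tumour outgrowth appears as an H0 feature born at
`w = R − r_tip` and dying when it merges into the main body, so its
persistence is the protrusion length in radius units. Components of the
full complex never die; they are vectorised separately (below). For
non-centred data the tumour centre of mass can be passed as `mu`.

**Vineyard.** Dimension-0 VR diagrams of the macrophage cloud at the 10
snapshots `t−100, t−90, …, t−10` are stacked with the time slot as the
birth axis: each finite death ε_d contributes a kernel at (slot, ε_d).
Because every dimension-0 VR birth is 0, death equals persistence. The one
essential component per slot is discarded. For this construction the full
(untruncated) dimension-0 diagram is needed; it is computed exactly on a
Euclidean-MST-reduced edge set, since single-linkage merge heights are
exactly the finite dimension-0 VR deaths.

**Zigzag.** Fixed-radius macrophage complexes (ε = 2, from a coarse sweep;
macrophages cluster at larger radii than tumour cells) at the same 10
snapshots, connected through intersection complexes — the simplices present
in both neighbouring snapshots under the stable cell numbering — giving an
alternating sequence of length 19. The dimension-0 interval decomposition
of this zigzag distinguishes clusters that genuinely persist (by cell
identity) from look-alike clusters that are born and die between snapshots.
For unlabelled data, `match_cells_by_transport` estimates identities by
minimum total squared displacement with vessels acting as sources and sinks
of unlimited capacity (solved as a balanced assignment problem).

## Persistence computation

Everything is computed over GF(2), in-package.

* **H0**: union-find over the filtration order with the elder rule; ties in
  birth are broken so the component containing the smallest vertex index
  survives. One record per point; components alive at the end are reported
  with infinite death. On VR filtrations finite deaths coincide with
  single-linkage dendrogram merge heights (the oracle used in tests).
* **H1**: reduction of the triangle boundary matrix with columns stored as
  Python integers used as bitsets over edge indices (sparse XOR columns,
  pivot-by-latest-edge). Zero-persistence pairs are not reported; 1-cycles
  never filled by a triangle are reported infinite.
* **Zigzag H0**: the structure maps of a dimension-0 zigzag are induced by
  maps of connected components, so the generalized rank of the module over
  a segment `[i, j]` equals the number of connected components of the
  segment's *component telescope* (one node per component per index, glued
  along the maps) that meet every index of the segment. Interval
  multiplicities follow by the four-term inclusion–exclusion on segment
  ranks. A left-to-right sweep with a fixed assignment of births to
  components was rejected: at a component split, which fragment should
  inherit the older birth depends on the future of the sequence, so no
  online rule is correct (worked counterexamples in the test suite). The
  rank identity is validated against explicit GF(2) limit→colimit linear
  algebra on randomised sequences.

## Persistence images

A record (b, d) contributes an isotropic Gaussian at (b, d−b) weighted by
its persistence d−b, summed at pixel centres (no integration over pixel
area; the midpoint error is quantified against quadrature in the tests and
is below 1% at the default σ). Defaults, configurable via
`PipelineConfig`: VR images 20×20 with windows [0, 5]² (tumour) and
[0, 10]² (macrophage), σ = half a pixel; radial images 35×8 over birth
distance [0, 35] × persistence [0, 8] with a length-35 profile and σ = 0.5;
vineyard 10×20 with pixel centres on slots 1…10; zigzag 19×19 over start
index × interval length. Radial infinite features become a 1-D profile of
unit-weight Gaussians over radial birth distance `R − w_birth`, appended to
the flattened image. Images are comparable only under identical specs,
enforced before classification.

## Synthetic data generator

The generator is a deliberate caricature of an off-lattice tumour–immune
agent-based model: no diffusible-species PDEs, no mechanics, no stromal or
necrotic agents. Its purpose is to produce identity-tracked point clouds
with the statistical structure the classifiers exploit — compact
proliferating tumours, chemotactic macrophages with a continuous phenotype
p ∈ [0, 1] (M1 anti-tumour below 0.5, M2 pro-tumour at or above),
extravasation at 8 fixed vessels on a ring of radius 18 about the initial
tumour at (25, 25), M2-led co-migration of tumour cells toward vessels, and
contact killing by M1 macrophages. Update rules run on a 1-hour tick with
snapshots every 10 h over 0–500 h; hourly steps are capped at 1 unit and
overlap relaxation pushes cells to ≥ 1.8 cell radii, which yields the
documented per-snapshot displacement bound used by the identity-continuity
test. The initial tumour is a 19-cell hexagonal patch; vessel count and
initial tumour size are package choices, as is the ring placement, which
puts vessels at large radius consistent with the radial-filtration logic.

Three presets drive the classic immunoediting outcomes, with ±15% per-seed
jitter for cohort heterogeneity (all tuned by pilot cohorts of 20 seeds):

| regime      | extravasation | chemotaxis | switch (h) | kill (h) | proliferation |
|-------------|---------------|------------|------------|----------|---------------|
| equilibrium | 0.03          | 0.6        | 600        | 80       | 0.0035–0.004  |
| elimination | 0.30          | 0.9        | 10⁶        | 2        | 0.003         |
| escape      | 0.10          | 0.7        | 6          | 10⁶      | 0.005         |

Under these conditions elimination clears the tumour, equilibrium holds a
compact mass (median ≈ 100 cells at 500 h) with essentially no niches, and
escape converts macrophages to M2 early enough that niches form in ≥ 80% of
runs. What passing tests show is therefore that the topological features
separate these caricatured regimes; they do not show performance on
Chaste-grade simulations or real imaging data, whose macrophage dynamics,
density profiles and noise characteristics are richer.

A second, purely geometric generator (`planted_spacing_clouds`) plants the
macrophage spacing signature directly: class-1 clouds are jittered grids at
nearest-neighbour spacing 1.2–1.8 (closely spaced but not packed), class-0
clouds at spacing < 1 or > 2. It exists to verify that the dimension-0
macrophage classifier recovers a known multi-scale clustering signal and
that its coefficient map is positive exactly on the persistence-1–2 band.

## Classification

Stratified 5-fold cross-validation repeated 10 times with seeded splits;
within each training fold the regularisation strength C is selected by
inner 3-fold cross-validation on the grid 10⁻²…10² (5 points). Features
are not standardised so that coefficient maps stay in image units;
coefficient maps come from one full-data refit at the inner-selected C
(fold-wise coefficient pooling is not defined by the protocol, so the
single refit is the package's choice). Benchmarks use the snapshot at t
itself. The M1/M2 phenotype ratio uses thresholded counts with +1
pseudocounts, `(1 + #{p<0.5}) / (1 + #{p≥0.5})`; a continuous variant
`(1 + Σ(1−p)) / (1 + Σp)` is available since the thresholding convention is
a modelling choice.

## Numerical and fixture choices

* Ties everywhere are resolved by (value, dimension, lexicographic vertex
  tuple); diagrams, images and writers are deterministic byte-for-byte.
* Degenerate inputs: empty point clouds give empty complexes, empty
  diagrams and zero images; coincident points give zero-persistence H0
  records, which carry zero image mass.
* The annulus/disk discrimination fixtures are built at cell resolution:
  the thresholds (persistence 1 = one cell diameter, dominance factor 3)
  are meaningful for cell-density clouds, and a sparse uniform cloud at
  radius 10 would instead carry sampling-noise loops of persistence > 1.
  The disk is therefore a jittered hexagonal colony of 100 cells at spacing
  0.95 (radius ≈ 5); the annulus is sampled uniformly on radii 8–10.
* Cohort sizes: test and acceptance cohorts use 15–20 runs per regime and
  three evaluation times (250, 350, 500 h), which keeps the full pipeline
  reproducible on a single CPU while leaving every classifier with ≥ 2
  examples per class per fold.

## Known limitations

* The generator's equilibrium regime is a rough birth–death balance, not a
  homeostatic control loop; very long horizons would drift.
* Zigzag persistence is computed for dimension 0 only (the pipeline's
  scope); dimension-1 zigzags would need a genuine zigzag reduction.
* The H1 reduction is exact but quadratic-ish in fill-in; clouds beyond a
  few hundred points at large connection radii get slow.
* Persistence images use pixel-centre evaluation; with σ below half a
  pixel width, mass aliasing between records offset by sub-pixel shifts
  becomes visible.
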