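# nichetda

Topological classification of tumour–immune spatial dynamics: predicting
perivascular-niche formation from the shapes of cell point clouds.

## The problem

In tumour–immune systems, pro-tumour (M2) macrophages can lead tumour cells
to blood vessels, forming a *perivascular niche* — a vessel with at least
10 tumour cells within 5 distance units — a staging ground for
intravasation and metastasis. Simple markers (tumour cell count, M1/M2
phenotype ratio, minimum tumour–vessel distance) only detect this late.
The spatial *arrangement* of cells carries earlier signals: multi-scale
clustering of macrophages, holes in the tumour mass, boundary tortuosity
and outgrowths, and the temporal stability of macrophage clusters.

`nichetda` quantifies these signals with persistent homology and feeds
them to interpretable classifiers. It is aimed at researchers analysing
spatio-temporal cell-location data — time series of typed, identity-tracked
2-D coordinates — from agent-based simulations or tracked imaging.

## The method

From each run (cell tables over 0–500 h, sampled every 10 h) four
vectorisations are computed, all as persistence images PI (Gaussian kernels
weighted by persistence, summed on a pixel grid):

* **PI^VR_0, PI^VR_1** — Vietoris–Rips filtrations of the tumour (T) or
  macrophage (M) cloud at a single time: an edge {x, y} enters at d(x, y),
  H0 tracks multi-scale clusters, H1 tracks holes in the cell arrangement.
* **PI^rad_0(T)** — the fixed-radius complex (ε = 0.7) filtered by
  w = R − ‖x − μ‖ from the tumour's initial centre μ = (25, 25), R = 35:
  outgrowths of the tumour boundary appear as features whose persistence is
  their protrusion length; disconnected components become a 1-D profile
  over radial distance appended to the image.
* **PI^vin_0(M)** — a vineyard: dimension-0 VR diagrams of the macrophage
  cloud at 10 snapshots t−100 … t−10 stacked with time as the birth axis.
* **PI^zz_0(M)** — zigzag persistence of fixed-radius (ε = 2) macrophage
  complexes over the same window, linked by intersection complexes under
  the stable cell numbering, so a cluster is tracked by *cell identity*
  rather than diagram similarity.

Each feature set trains an L2-regularised logistic regression evaluated by
stratified 5-fold cross-validation repeated 10 times; its coefficients
reshape back onto the image, showing which (birth, persistence) regions
indicate niche formation. Four scalar benchmarks (tumour count, macrophage
count, M1/M2 ratio, tumour–vessel distance) provide the comparison line.

A self-contained caricature agent-based generator produces identity-tracked
tumour/macrophage/vessel time series in three regimes — equilibrium,
elimination, escape — controlled by three macrophage parameters
(extravasation rate, chemotaxis sensitivity, phenotype-switch threshold).
All persistence computation (union-find H0, bitset mod-2 boundary-matrix
reduction for H1, and a zigzag-H0 interval decomposition via generalized
ranks of component telescopes) is implemented in-package and validated
against independent oracles in the test suite. See `docs/methods.md`.

## Worked example

```python
import numpy as np
import nichetda as nt

cohort = nt.generate_cohort(5, base_seed=0)          # 5 runs per regime
runs = [r for r, _ in cohort]
labels = [nt.label_run(r) for r in runs]             # niche at t=500?
print(f"{len(runs)} runs, niche prevalence {100*np.mean(labels):.1f}%")

table, reports = nt.accuracy_vs_time(
    runs, ("rad0_T", "vr0_M", "bench_tumour_count"), times=(250, 500),
    seed=0, labels=labels,
)
print(table[["feature_tag", "time", "mean_accuracy", "accuracy_sd"]].to_string(index=False))

grid, profile = nt.coefficient_map(reports[("rad0_T", 250)])
print(f"radial coefficient map {grid.shape}, profile length {len(profile)}")
```

prints

```
15 runs, niche prevalence 33.3%
       feature_tag  time  mean_accuracy  accuracy_sd
            rad0_T   250       1.000000     0.000000
            rad0_T   500       1.000000     0.000000
             vr0_M   250       1.000000     0.000000
             vr0_M   500       1.000000     0.000000
bench_tumour_count   250       0.880000     0.175093
bench_tumour_count   500       0.913333     0.162324
radial coefficient map (8, 35), profile length 35
```

On this small caricature cohort the topological features separate the
classes perfectly 250 hours before the label is decided, while the tumour
cell count still misclassifies runs; the 8×35 coefficient grid localises
which outgrowth radii and protrusion lengths drive the prediction, and the
length-35 profile weights the radii of disconnected tumour components.

A thin CLI mirrors the pipeline: `nichetda simulate --regime escape --n 10
--seed 0 --out runs/`, then `nichetda featurise`, `nichetda classify`,
`nichetda report` (see `nichetda --help`).

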