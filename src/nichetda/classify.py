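"""Featurisation over timesteps/windows and cross-validated logistic regression.

Feature tags
------------
Static tags use the snapshot at time t; dynamic tags use the 10-snapshot
window t-100, t-90, ..., t-10 ending just before t.

=================  ==========================================================
``vr0_T``/``vr1_T``  VR persistence images of the tumour cloud, dims 0 / 1
``vr0_M``/``vr1_M``  VR persistence images of the macrophage cloud
``rad0_T``           two-part radial image of the tumour cloud (dim 0)
``vin0_M``           vineyard image: stacked dim-0 VR diagrams of macrophages
``zz0_M``            zigzag image: dim-0 intervals of the macrophage zigzag
``bench_*``          scalar benchmarks (tumour/macrophage count, M1/M2
                     phenotype ratio, minimum tumour-vessel distance)
=================  ==========================================================

Classification is L2-regularised logistic regression, evaluated by 10
independent seeded repeats of stratified 5-fold cross-validation, with the
regularisation strength selected by inner cross-validation on a logarithmic
grid.  Features are not standardised, so coefficient maps remain in image
units and can be reshaped onto the persistence-image geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

from .config import DEFAULT_CONFIG, PipelineConfig
from .filtrations import (
    build_radial_filtration,
    build_single_linkage_filtration,
    build_vr_filtration,
    build_zigzag_sequence,
)
from .labels_benchmarks import benchmark_features
from .persistence import PersistenceDiagram, ph0, ph1, zigzag_ph0
from .vectorisation import (
    PersistenceImage,
    PersistenceImageSpec,
    diagram_to_image,
    radial_to_image,
    vineyard_image,
    zigzag_image,
)

logger = logging.getLogger(__name__)

TOPOLOGICAL_TAGS = ("vr0_T", "vr1_T", "vr0_M", "vr1_M", "rad0_T", "vin0_M", "zz0_M")
BENCHMARK_TAGS = ("bench_tumour_count", "bench_mac_count", "bench_ratio", "bench_distance")
ALL_TAGS = TOPOLOGICAL_TAGS + BENCHMARK_TAGS
DYNAMIC_TAGS = ("vin0_M", "zz0_M")


@dataclass
class FeatureMatrix:
    X: np.ndarray
    labels: np.ndarray
    feature_tag: str
    time: int
    image_spec: PersistenceImageSpec | None = None
    dropped_infinite: int = 0

    def __post_init__(self) -> None:
        if len(self.X) != len(self.labels):
            raise ValueError("feature rows and labels length mismatch")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be 0/1")


@dataclass
class ClassifierReport:
    feature_tag: str
    time: int
    mean_accuracy: float
    accuracy_sd: float
    coefficients: np.ndarray
    folds: int = 5
    repeats: int = 10
    image_spec: PersistenceImageSpec | None = None
    fold_accuracies: np.ndarray = field(default_factory=lambda: np.empty(0))


def window_times(t: int, config: PipelineConfig = DEFAULT_CONFIG) -> list[int]:
    """The dynamic-window snapshot hours for end time t: t-100, ..., t-10."""
    k = config.window_snapshots
    dt = config.snapshot_interval
    return [t - dt * (k - i) for i in range(k)]


def _drop_infinite(diagram: PersistenceDiagram) -> tuple[PersistenceDiagram, int]:
    fin = diagram.finite()
    return PersistenceDiagram(fin, diagram.filtration_kind, diagram.axis_units), len(
        diagram.records
    ) - len(fin)


def _image_for_tag(series, tag: str, t: int, config: PipelineConfig) -> PersistenceImage:
    if tag in DYNAMIC_TAGS:
        times = window_times(t, config)
    else:
        snap = series.snapshot_at(t)
        if snap is None:
            raise ValueError(f"missing snapshot at t={t}")
    if tag in ("vr0_T", "vr1_T", "vr0_M", "vr1_M"):
        cell_type = "tumour" if tag.endswith("_T") else "macrophage"
        max_eps = (
            config.vr_max_eps_tumour if cell_type == "tumour" else config.vr_max_eps_macrophage
        )
        spec_cfg = (
            config.vr_image_tumour if cell_type == "tumour" else config.vr_image_macrophage
        )
        spec = PersistenceImageSpec.from_config(spec_cfg)
        _, xy = snap.points_of_type(cell_type)
        dim = 0 if tag.startswith("vr0") else 1
        filtration = build_vr_filtration(xy, max_dim=dim + 1, max_eps=max_eps)
        diagram = ph0(filtration) if dim == 0 else ph1(filtration)
        finite, dropped = _drop_infinite(diagram)
        if dropped:
            logger.debug("%s t=%d: dropped %d truncated/essential features", tag, t, dropped)
        img = diagram_to_image(finite, spec)
        img.dropped_infinite = dropped
        return img
    if tag == "rad0_T":
        spec = PersistenceImageSpec.from_config(config.radial_image)
        _, xy = snap.points_of_type("tumour")
        filtration = build_radial_filtration(
            xy, eps=config.eps_tumour, mu=config.basepoint, R=config.radial_R
        )
        return radial_to_image(ph0(filtration, "radial"), spec, R=config.radial_R)
    if tag == "vin0_M":
        spec = PersistenceImageSpec.from_config(config.vineyard_image)
        diagrams = []
        for ti in times:
            snap_i = series.snapshot_at(ti)
            if snap_i is None:
                raise ValueError(f"missing snapshot at t={ti}")
            _, xy = snap_i.points_of_type("macrophage")
            diagrams.append(ph0(build_single_linkage_filtration(xy)))
        return vineyard_image(diagrams, spec)
    if tag == "zz0_M":
        spec = PersistenceImageSpec.from_config(config.zigzag_image)
        seq = build_zigzag_sequence(series, "macrophage", config.eps_macrophage_zigzag, times)
        return zigzag_image(zigzag_ph0(seq), spec)
    raise ValueError(f"unknown feature tag {tag!r}")


def featurise(
    series_list,
    feature_tag: str,
    t: int,
    config: PipelineConfig = DEFAULT_CONFIG,
    labels=None,
) -> FeatureMatrix:
    """One feature row per run at end time ``t`` for the requested tag.

    ``labels`` defaults to the perivascular-niche label of each run's final
    snapshot.
    """
    from .labels_benchmarks import label_run

    if labels is None:
        labels = [label_run(s) for s in series_list]
    labels = np.asarray(labels, dtype=int)
    if feature_tag in BENCHMARK_TAGS:
        rows = []
        for s in series_list:
            snap = s.snapshot_at(t)
            if snap is None:
                raise ValueError(f"missing snapshot at t={t}")
            feats = benchmark_features(snap)
            value = {
                "bench_tumour_count": feats.tumour_count,
                "bench_mac_count": feats.macrophage_count,
                "bench_ratio": feats.phenotype_ratio,
                "bench_distance": feats.min_tumour_vessel_distance,
            }[feature_tag]
            rows.append([float(value)])
        return FeatureMatrix(np.asarray(rows), labels, feature_tag, t)
    spec = None
    rows = []
    dropped = 0
    for s in series_list:
        img = _image_for_tag(s, feature_tag, t, config)
        if spec is None:
            spec = img.spec
        elif img.spec != spec:
            raise ValueError("image spec mismatch across runs")
        dropped += img.dropped_infinite
        rows.append(img.flatten())
    return FeatureMatrix(
        np.vstack(rows), labels, feature_tag, t, image_spec=spec, dropped_infinite=dropped
    )


_CS_GRID = np.logspace(-2.0, 2.0, 5)


def _make_clf(seed: int) -> LogisticRegressionCV:
    return LogisticRegressionCV(
        Cs=_CS_GRID,
        cv=StratifiedKFold(3, shuffle=True, random_state=seed),
        scoring="accuracy",
        solver="lbfgs",
        max_iter=2000,
        n_jobs=None,
    )


def _fit(clf, X, y):
    import warnings

    with warnings.catch_warnings():
        # sklearn 1.9 emits FutureWarnings about upcoming LogisticRegressionCV
        # API changes; the explicit arguments above pin the current behaviour
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(X, y)
    return clf


def fit_logreg_cv(features: FeatureMatrix, seed: int = 0) -> ClassifierReport:
    """Repeated stratified 5-fold CV accuracy plus full-data coefficients.

    Accuracy is the mean held-out accuracy over 10 seeded repeats of
    stratified 5-fold CV; within each training fold the regularisation
    strength is chosen by inner 3-fold CV on a logarithmic grid.  The
    coefficient vector comes from a final fit on all data.
    """
    y = features.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; cannot fit a classifier")
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")
    X = features.X
    rskf = RepeatedStratifiedKFold(n_splits=5, n_repeats=10, random_state=seed)
    accs = []
    for fold_idx, (tr, te) in enumerate(rskf.split(X, y)):
        clf = _fit(_make_clf(seed + fold_idx), X[tr], y[tr])
        accs.append(float(clf.score(X[te], y[te])))
    accs = np.array(accs)
    final = _fit(_make_clf(seed), X, y)
    return ClassifierReport(
        feature_tag=features.feature_tag,
        time=features.time,
        mean_accuracy=float(accs.mean()),
        accuracy_sd=float(accs.std(ddof=1)),
        coefficients=final.coef_.ravel().copy(),
        folds=5,
        repeats=10,
        image_spec=features.image_spec,
        fold_accuracies=accs,
    )


def accuracy_vs_time(
    series_list,
    feature_tags=ALL_TAGS,
    times=None,
    config: PipelineConfig = DEFAULT_CONFIG,
    seed: int = 0,
    labels=None,
) -> tuple[pd.DataFrame, dict]:
    """Long-format accuracy table (one row per tag x time) plus the reports."""
    from .labels_benchmarks import label_run

    if times is None:
        times = config.times
    if labels is None:
        labels = [label_run(s) for s in series_list]
    rows = []
    reports = {}
    for tag in feature_tags:
        for t in times:
            fm = featurise(series_list, tag, int(t), config, labels=labels)
            rep = fit_logreg_cv(fm, seed=seed)
            reports[(tag, int(t))] = rep
            rows.append(
                {
                    "feature_tag": tag,
                    "time": int(t),
                    "mean_accuracy": rep.mean_accuracy,
                    "accuracy_sd": rep.accuracy_sd,
                    "n_runs": len(fm.labels),
                    "dropped_infinite": fm.dropped_infinite,
                }
            )
            logger.info(
                "%s t=%d: accuracy %.3f +/- %.3f", tag, t, rep.mean_accuracy, rep.accuracy_sd
            )
    return pd.DataFrame(rows), reports


def coefficient_map(
    report: ClassifierReport, image_spec: PersistenceImageSpec | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Reshape a report's coefficients onto the persistence-image geometry.

    Returns (signed grid of shape (ny, nx), optional signed profile) — the
    profile part is present for radial features, whose flattened vector
    appends the length-nx infinite-feature profile to the grid.
    """
    spec = image_spec or report.image_spec
    if spec is None:
        raise ValueError("coefficient_map requires an image-based feature tag")
    nx, ny = spec.resolution
    coefs = np.asarray(report.coefficients, dtype=float)
    if len(coefs) == nx * ny:
        return coefs.reshape(ny, nx), None
    if len(coefs) == nx * ny + nx:
        return coefs[: nx * ny].reshape(ny, nx), coefs[nx * ny :]
    raise ValueError(
        f"coefficient length {len(coefs)} matches neither {nx * ny} nor {nx * ny + nx}"
    )


def plot_accuracy(table: pd.DataFrame, path=None):
    """Accuracy-vs-time curves, one line per feature tag (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    for tag, grp in table.groupby("feature_tag"):
        style = "--" if tag.startswith("bench") else "-"
        ax.errorbar(
            grp["time"], grp["mean_accuracy"], yerr=grp["accuracy_sd"], label=tag, ls=style
        )
    ax.set_xlabel("time (h)")
    ax.set_ylabel("CV accuracy")
    ax.set_ylim(0.0, 1.05)
    ax.legend(fontsize=8, ncol=2)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
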