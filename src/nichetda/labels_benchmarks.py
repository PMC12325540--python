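"""Perivascular-niche labelling and the four benchmark statistics.

A perivascular niche is a blood vessel with at least 10 tumour cells within
5 distance units; runs are labelled 1 when at least one niche exists at the
final (500 h) snapshot.  The benchmarks — tumour count, macrophage count,
macrophage M1/M2 phenotype ratio and minimum tumour-vessel distance — are
the simple spatial statistics the topological classifiers are compared
against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .synthetic_abm import CellTimeSeries, Snapshot

NICHE_MIN_CELLS = 10
NICHE_RADIUS = 5.0
M2_THRESHOLD = 0.5


@dataclass
class RunFeatures:
    run_id: str | None
    time: int
    tumour_count: int
    macrophage_count: int
    phenotype_ratio: float
    min_tumour_vessel_distance: float
    niche_count: int


def detect_niches(
    snapshot: Snapshot, min_cells: int = NICHE_MIN_CELLS, radius: float = NICHE_RADIUS
) -> int:
    """Number of vessels with at least ``min_cells`` tumour cells within ``radius``.

    The rule is per vessel: a tumour cell may count towards several vessels.
    """
    if len(snapshot.vessel_xy) == 0:
        raise ValueError("snapshot contains no vessel records")
    if len(snapshot.tumour_xy) == 0:
        return 0
    d = cdist(snapshot.vessel_xy, snapshot.tumour_xy)
    return int(((d <= radius).sum(axis=1) >= min_cells).sum())


def label_run(series: CellTimeSeries, final_time: int | None = None) -> int:
    """1 iff the run exhibits at least one perivascular niche at the final time."""
    if final_time is None:
        final_time = series.params.horizon if series.params is not None else 500
    snap = series.snapshot_at(final_time)
    if snap is None:
        raise ValueError(f"series is missing the final snapshot at t={final_time}")
    return int(detect_niches(snap) >= 1)


def phenotype_ratio(phenotypes: np.ndarray, continuous: bool = False) -> float:
    """M1/M2 polarisation ratio.

    Default: thresholded counts with +1 pseudocounts,
    (1 + #{p < 0.5}) / (1 + #{p >= 0.5}).  The continuous variant uses
    (1 + sum(1 - p)) / (1 + sum(p)).
    """
    p = np.asarray(phenotypes, dtype=float)
    if continuous:
        return float((1.0 + np.sum(1.0 - p)) / (1.0 + np.sum(p)))
    m1 = int((p < M2_THRESHOLD).sum())
    m2 = int((p >= M2_THRESHOLD).sum())
    return (1.0 + m1) / (1.0 + m2)


def benchmark_features(
    snapshot: Snapshot, run_id: str | None = None, domain_size: float = 50.0
) -> RunFeatures:
    """The four benchmark statistics plus the niche count for one snapshot.

    When there are no tumour cells (or no vessels) the minimum tumour-vessel
    distance takes the domain-diagonal sentinel value.
    """
    sentinel = float(np.sqrt(2.0) * domain_size)
    if len(snapshot.tumour_xy) and len(snapshot.vessel_xy):
        min_dist = float(cdist(snapshot.tumour_xy, snapshot.vessel_xy).min())
    else:
        min_dist = sentinel
    niche = detect_niches(snapshot) if len(snapshot.vessel_xy) else 0
    return RunFeatures(
        run_id=run_id,
        time=snapshot.time,
        tumour_count=len(snapshot.tumour_xy),
        macrophage_count=len(snapshot.mac_xy),
        phenotype_ratio=phenotype_ratio(snapshot.mac_phenotype),
        min_tumour_vessel_distance=min_dist,
        niche_count=niche,
    )
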