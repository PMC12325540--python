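"""Text serialisation of cell tables, diagrams, zigzag intervals and images.

Cell tables are CSV with header ``cell_id,cell_type,x,y,phenotype,time``
(phenotype empty for non-macrophages); diagrams, intervals and images are
JSON.  Floats are serialised with ``repr`` round-trip precision (17
significant digits), so every writer is deterministic byte-for-byte and every
read/write cycle is an identity, including infinite deaths (the literal
string ``"inf"``).
"""

from __future__ import annotations

import csv
import json
from math import inf
from pathlib import Path

import numpy as np
import pandas as pd

from .persistence import DiagramRecord, PersistenceDiagram, ZigzagIntervals
from .vectorisation import PersistenceImage, PersistenceImageSpec

CELL_TABLE_COLUMNS = ["cell_id", "cell_type", "x", "y", "phenotype", "time"]
CELL_TYPES = {"tumour", "macrophage", "vessel"}


class CellTableError(ValueError):
    """Raised for malformed cell tables, naming the offending row."""


def write_cell_table(series, path: str | Path, run_id: str | None = None) -> None:
    """Write a :class:`~nichetda.synthetic_abm.CellTimeSeries` as a cell-table CSV."""
    rows = []
    for snap in series.snapshots:
        for rec in snap.records():
            rows.append(
                {
                    "cell_id": rec.cell_id,
                    "cell_type": rec.cell_type,
                    "x": repr(float(rec.x)),
                    "y": repr(float(rec.y)),
                    "phenotype": "" if rec.phenotype is None else repr(float(rec.phenotype)),
                    "time": rec.time,
                }
            )
    path = Path(path)
    with path.open("w", newline="") as fh:
        cols = CELL_TABLE_COLUMNS + (["run_id"] if run_id is not None else [])
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for row in rows:
            if run_id is not None:
                row["run_id"] = run_id
            writer.writerow(row)


def write_run_metadata(series, path: str | Path, regime: str | None = None) -> None:
    from dataclasses import asdict

    meta = {"params": asdict(series.params)}
    if regime is not None:
        meta["regime"] = regime
    Path(path).write_text(json.dumps(meta, indent=2, default=float) + "\n")


def read_cell_table(path: str | Path):
    """Read a cell-table CSV into a :class:`~nichetda.synthetic_abm.CellTimeSeries`.

    Validation errors (missing columns, non-numeric coordinates, duplicate
    ``(cell_id, time)``, phenotype on a non-macrophage) name the failing row.
    """
    from .synthetic_abm import CellTimeSeries, Snapshot

    df = pd.read_csv(path, dtype={"phenotype": float}, float_precision="round_trip")
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise CellTableError(f"missing column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise CellTableError("no records in cell table")
    for col in ("x", "y"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise CellTableError(f"non-numeric {col!r} at row {int(bad[0]) + 2}")
    bad_type = df.index[~df["cell_type"].isin(CELL_TYPES)]
    if len(bad_type):
        raise CellTableError(
            f"unknown cell_type {df.loc[bad_type[0], 'cell_type']!r} at row {int(bad_type[0]) + 2}"
        )
    dup = df.duplicated(subset=["cell_id", "time"])
    if dup.any():
        raise CellTableError(f"duplicate (cell_id, time) at row {int(df.index[dup][0]) + 2}")
    has_phen = df["phenotype"].notna()
    bad_phen = df.index[has_phen & (df["cell_type"] != "macrophage")]
    if len(bad_phen):
        raise CellTableError(f"phenotype on non-macrophage cell at row {int(bad_phen[0]) + 2}")
    missing_phen = df.index[~has_phen & (df["cell_type"] == "macrophage")]
    if len(missing_phen):
        raise CellTableError(f"macrophage without phenotype at row {int(missing_phen[0]) + 2}")

    snapshots = []
    for t, grp in df.groupby("time", sort=True):
        tum = grp[grp.cell_type == "tumour"]
        mac = grp[grp.cell_type == "macrophage"]
        ves = grp[grp.cell_type == "vessel"]
        snapshots.append(
            Snapshot(
                time=int(t),
                tumour_ids=tum.cell_id.to_numpy(dtype=np.intp),
                tumour_xy=tum[["x", "y"]].to_numpy(dtype=float),
                mac_ids=mac.cell_id.to_numpy(dtype=np.intp),
                mac_xy=mac[["x", "y"]].to_numpy(dtype=float),
                mac_phenotype=mac.phenotype.to_numpy(dtype=float),
                vessel_ids=ves.cell_id.to_numpy(dtype=np.intp),
                vessel_xy=ves[["x", "y"]].to_numpy(dtype=float),
            )
        )
    return CellTimeSeries(snapshots=snapshots, params=None)


def _death_to_json(d: float):
    return "inf" if d == inf else d


def _death_from_json(d):
    return inf if d == "inf" else float(d)


def write_diagram(diagram: PersistenceDiagram, path: str | Path) -> None:
    payload = {
        "filtration_kind": diagram.filtration_kind,
        "axis_units": diagram.axis_units,
        "records": [
            [r.dimension, r.birth, _death_to_json(r.death), r.multiplicity]
            for r in diagram.records
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_diagram(path: str | Path) -> PersistenceDiagram:
    raw = json.loads(Path(path).read_text())
    records = []
    for i, rec in enumerate(raw["records"]):
        try:
            dim, birth, death, mult = rec
            records.append(DiagramRecord(int(dim), float(birth), _death_from_json(death), int(mult)))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed diagram record at line {i + 1}: {rec!r}") from exc
    return PersistenceDiagram(
        records, filtration_kind=raw.get("filtration_kind", "vr"), axis_units=raw.get("axis_units", "length")
    )


def write_intervals(intervals: ZigzagIntervals, path: str | Path) -> None:
    payload = {"length": intervals.length, "intervals": [list(iv) for iv in intervals.intervals]}
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_intervals(path: str | Path) -> ZigzagIntervals:
    raw = json.loads(Path(path).read_text())
    return ZigzagIntervals([tuple(int(x) for x in iv) for iv in raw["intervals"]], int(raw["length"]))


def write_image(image: PersistenceImage, path: str | Path) -> None:
    payload = {
        "birth_range": list(image.spec.birth_range),
        "pers_range": list(image.spec.pers_range),
        "resolution": list(image.spec.resolution),
        "sigma": image.spec.sigma,
        "weight": image.spec.weight,
        "grid": [[float(v) for v in row] for row in image.grid],
    }
    if image.infinite_profile is not None:
        payload["infinite_profile"] = [float(v) for v in image.infinite_profile]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_image(path: str | Path) -> PersistenceImage:
    raw = json.loads(Path(path).read_text())
    spec = PersistenceImageSpec(
        tuple(raw["birth_range"]),
        tuple(raw["pers_range"]),
        tuple(raw["resolution"]),
        float(raw["sigma"]),
        raw.get("weight", "linear_persistence"),
    )
    grid = np.array(raw["grid"], dtype=float)
    if grid.size == 0:
        grid = grid.reshape(0, 0)
    nx, ny = spec.resolution
    if grid.shape != (ny, nx):
        raise ValueError(f"grid shape {grid.shape} does not match metadata resolution {(ny, nx)}")
    profile = raw.get("infinite_profile")
    if profile is not None:
        profile = np.array(profile, dtype=float)
        if len(profile) != nx:
            raise ValueError(f"infinite_profile length {len(profile)} does not match nx={nx}")
    return PersistenceImage(grid, spec, infinite_profile=profile)
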