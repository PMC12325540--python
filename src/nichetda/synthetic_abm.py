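"""Caricature agent-based generator of tumour / macrophage / vessel time series.

This module emulates the statistical structure of an off-lattice
tumour-immune agent-based model at the level needed by the topological
pipeline: identity-tracked 2-D cell coordinates in a [0, 50] x [0, 50]
domain, cell radius 0.5, hourly internal dynamics sampled every 10 hours
from 0 to 500 hours, with fixed blood-vessel points and a continuous
macrophage phenotype p in [0, 1] (anti-tumour "M1" for p < 0.5, pro-tumour
"M2" for p >= 0.5).

The dynamics are deliberately minimal.  Per 1-hour tick:

i)    macrophages extravasate at each vessel with probability
      ``extravasation_rate`` while any tumour cell exists;
ii)   M1 macrophages step towards the nearest tumour cell with bias
      ``chemotaxis_sensitivity`` plus isotropic noise;
iii)  a macrophage within one cell diameter of a tumour cell accrues
      proximity hours; beyond ``phenotype_switch_threshold`` hours its
      phenotype increases at 0.05/hour;
iv)   M2 macrophages step towards the nearest vessel, and tumour cells
      within 2 units of an M2 macrophage follow its displacement (paracrine
      co-migration); an M2 macrophage reaching a vessel re-enters it and is
      removed;
v)    tumour cells divide with probability ``proliferation_rate`` into an
      adjacent position;
vi)   a tumour cell in contact with an M1 macrophage for
      ``kill_contact_hours`` consecutive hours is removed;
vii)  overlapping cells are pushed apart to at least 1.8 cell radii.

Three parameter presets drive the generator towards the classic outcomes of
tumour immunoediting — equilibrium (compact persistent tumour, M1
dominated), elimination (tumour cleared), escape (M2 conversion, perivascular
niche formation) — with per-seed jitter so that cohorts are heterogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf

import numpy as np
from scipy.spatial.distance import cdist

TUMOUR = "tumour"
MACROPHAGE = "macrophage"
VESSEL = "vessel"

REGIMES = ("equilibrium", "elimination", "escape")

_STEP_SCALE = 0.5  # base directed step length, units/hour
_NOISE_SCALE = 0.25  # isotropic motility noise, units/hour
_MAX_STEP = 1.0  # hard cap on hourly displacement
_PHENOTYPE_RATE = 0.05  # phenotype increase per hour once switched
_FOLLOW_RADIUS = 2.0  # tumour cells within this of an M2 follow it
_SEPARATION = 0.9  # 1.8 * cell_radius minimum separation
_VESSEL_RING_RADIUS = 18.0


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the caricature generator.

    ``extravasation_rate`` and ``proliferation_rate`` are per-hour
    probabilities; ``chemotaxis_sensitivity`` is a dimensionless step-bias
    weight; ``phenotype_switch_threshold`` and ``kill_contact_hours`` are in
    hours (``math.inf`` disables the behaviour).
    """

    extravasation_rate: float
    chemotaxis_sensitivity: float
    phenotype_switch_threshold: float
    kill_contact_hours: float
    proliferation_rate: float
    domain_size: float = 50.0
    cell_radius: float = 0.5
    n_vessels: int = 8
    horizon: int = 500
    snapshot_interval: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("extravasation_rate", "proliferation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.chemotaxis_sensitivity < 0:
            raise ValueError("chemotaxis_sensitivity must be nonnegative")
        if self.phenotype_switch_threshold < 0 or self.kill_contact_hours < 0:
            raise ValueError("thresholds must be nonnegative")
        if self.domain_size <= 0:
            raise ValueError("domain_size must be positive")
        if self.n_vessels < 1:
            raise ValueError("n_vessels must be at least 1")
        if self.horizon % self.snapshot_interval != 0:
            raise ValueError("horizon must be divisible by snapshot_interval")

    @property
    def max_snapshot_displacement(self) -> float:
        """Bound on the displacement of a surviving cell between snapshots
        (directed step plus worst-case overlap resolution per tick)."""
        return self.snapshot_interval * (_MAX_STEP + _SEPARATION)


@dataclass(frozen=True)
class CellRecord:
    cell_id: int
    cell_type: str
    x: float
    y: float
    phenotype: float | None
    time: int


@dataclass
class Snapshot:
    """Typed cell coordinates at one timestep, stored as arrays per type."""

    time: int
    tumour_ids: np.ndarray
    tumour_xy: np.ndarray
    mac_ids: np.ndarray
    mac_xy: np.ndarray
    mac_phenotype: np.ndarray
    vessel_ids: np.ndarray
    vessel_xy: np.ndarray

    def points_of_type(self, cell_type: str) -> tuple[np.ndarray, np.ndarray]:
        if cell_type == TUMOUR:
            return self.tumour_ids, self.tumour_xy
        if cell_type == MACROPHAGE:
            return self.mac_ids, self.mac_xy
        if cell_type == VESSEL:
            return self.vessel_ids, self.vessel_xy
        raise ValueError(f"unknown cell type {cell_type!r}")

    def records(self) -> list[CellRecord]:
        out = []
        for cid, (x, y) in zip(self.vessel_ids, self.vessel_xy):
            out.append(CellRecord(int(cid), VESSEL, float(x), float(y), None, self.time))
        for cid, (x, y) in zip(self.tumour_ids, self.tumour_xy):
            out.append(CellRecord(int(cid), TUMOUR, float(x), float(y), None, self.time))
        for cid, (x, y), p in zip(self.mac_ids, self.mac_xy, self.mac_phenotype):
            out.append(CellRecord(int(cid), MACROPHAGE, float(x), float(y), float(p), self.time))
        return out


@dataclass
class CellTimeSeries:
    snapshots: list[Snapshot]
    params: SimulationParams | None = None

    @property
    def times(self) -> list[int]:
        return [s.time for s in self.snapshots]

    def snapshot_at(self, time: int) -> Snapshot | None:
        for s in self.snapshots:
            if s.time == time:
                return s
        return None

    @property
    def final(self) -> Snapshot:
        return self.snapshots[-1]


_PRESETS = {
    # tuned by pilot runs; see docs/methods.md for the tuning rationale
    "equilibrium": dict(
        extravasation_rate=0.03,
        chemotaxis_sensitivity=0.6,
        phenotype_switch_threshold=600.0,
        kill_contact_hours=80.0,
        proliferation_rate=0.004,
    ),
    "elimination": dict(
        extravasation_rate=0.30,
        chemotaxis_sensitivity=0.9,
        phenotype_switch_threshold=1e6,
        kill_contact_hours=2.0,
        proliferation_rate=0.003,
    ),
    "escape": dict(
        extravasation_rate=0.10,
        chemotaxis_sensitivity=0.7,
        phenotype_switch_threshold=6.0,
        kill_contact_hours=1e6,
        proliferation_rate=0.005,
    ),
}


def preset_params(regime: str, seed: int) -> SimulationParams:
    """Parameter set documented to drive the generator towards ``regime``.

    Deterministic in (regime, seed): the per-hour rates are jittered by up to
    +/-15% from the regime's base values so that cohorts are heterogeneous,
    and ``seed`` also seeds the simulation stream.
    """
    if regime not in _PRESETS:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    base = _PRESETS[regime]
    rng = np.random.default_rng([int(seed), REGIMES.index(regime)])
    jit = lambda v: float(np.clip(v * rng.uniform(0.85, 1.15), 0.0, 1.0))
    return SimulationParams(
        extravasation_rate=jit(base["extravasation_rate"]),
        chemotaxis_sensitivity=float(base["chemotaxis_sensitivity"] * rng.uniform(0.85, 1.15)),
        phenotype_switch_threshold=float(
            base["phenotype_switch_threshold"] * rng.uniform(0.85, 1.15)
        ),
        kill_contact_hours=float(base["kill_contact_hours"] * rng.uniform(0.85, 1.15)),
        proliferation_rate=jit(base["proliferation_rate"]),
        seed=int(seed),
    )


def _vessel_ring(params: SimulationParams) -> np.ndarray:
    centre = params.domain_size / 2.0
    angles = 2.0 * np.pi * np.arange(params.n_vessels) / params.n_vessels
    return np.column_stack(
        [centre + _VESSEL_RING_RADIUS * np.cos(angles), centre + _VESSEL_RING_RADIUS * np.sin(angles)]
    )


def _initial_tumour(params: SimulationParams) -> np.ndarray:
    """A 19-cell hexagonal patch (two rings) centred in the domain."""
    centre = params.domain_size / 2.0
    spacing = 0.95
    pts = [(0.0, 0.0)]
    for ring, count in ((1, 6), (2, 12)):
        ang = 2.0 * np.pi * np.arange(count) / count + (0.26 if ring == 2 else 0.0)
        pts.extend(zip(ring * spacing * np.cos(ang), ring * spacing * np.sin(ang)))
    return np.asarray(pts) + centre


def _unit_towards(src: np.ndarray, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-source unit vector towards the nearest target, plus that target's index."""
    d = cdist(src, targets)
    nearest = d.argmin(axis=1)
    vec = targets[nearest] - src
    norm = np.linalg.norm(vec, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return vec / norm, nearest


def _resolve_overlaps(xy: np.ndarray, rng: np.random.Generator, iterations: int = 2) -> np.ndarray:
    """Push cell centres apart to >= 1.8 cell radii (a cheap relaxation)."""
    n = len(xy)
    if n < 2:
        return xy
    for _ in range(iterations):
        d = cdist(xy, xy)
        np.fill_diagonal(d, np.inf)
        ii, jj = np.where(np.triu(d < _SEPARATION))
        if len(ii) == 0:
            break
        shift = np.zeros_like(xy)
        for i, j in zip(ii, jj):
            delta = xy[j] - xy[i]
            dist = np.linalg.norm(delta)
            if dist < 1e-9:
                ang = rng.uniform(0.0, 2.0 * np.pi)
                delta = np.array([np.cos(ang), np.sin(ang)])
                dist = 1.0
            push = 0.5 * (_SEPARATION - dist) * delta / dist
            shift[i] -= push
            shift[j] += push
        # keep per-tick relaxation bounded so snapshot displacements stay
        # within max_snapshot_displacement
        norms = np.linalg.norm(shift, axis=1, keepdims=True)
        over = norms[:, 0] > _SEPARATION / 2.0
        if over.any():
            shift[over] *= (_SEPARATION / 2.0) / norms[over]
        xy = xy + shift
    return xy


def simulate_run(params: SimulationParams) -> CellTimeSeries:
    """Run the generator and return identity-tracked snapshots every
    ``snapshot_interval`` hours from 0 to ``horizon``."""
    rng = np.random.default_rng([int(params.seed), 982451653])
    vessels = _vessel_ring(params)
    vessel_ids = np.arange(params.n_vessels, dtype=np.intp)
    next_id = params.n_vessels

    tum_xy = _initial_tumour(params)
    tum_ids = np.arange(next_id, next_id + len(tum_xy), dtype=np.intp)
    next_id += len(tum_xy)
    tum_contact = np.zeros(len(tum_xy))  # consecutive M1-contact hours

    mac_xy = np.empty((0, 2))
    mac_ids = np.empty(0, dtype=np.intp)
    mac_p = np.empty(0)
    mac_prox = np.empty(0)  # cumulative tumour-proximity hours

    snapshots: list[Snapshot] = []

    def emit(t: int) -> None:
        snapshots.append(
            Snapshot(
                time=t,
                tumour_ids=tum_ids.copy(),
                tumour_xy=tum_xy.copy(),
                mac_ids=mac_ids.copy(),
                mac_xy=mac_xy.copy(),
                mac_phenotype=mac_p.copy(),
                vessel_ids=vessel_ids.copy(),
                vessel_xy=vessels.copy(),
            )
        )

    emit(0)
    contact_radius = 2.0 * params.cell_radius
    for t in range(1, params.horizon + 1):
        # i) extravasation
        if len(tum_xy) > 0 and params.extravasation_rate > 0:
            spawn = rng.random(params.n_vessels) < params.extravasation_rate
            k = int(spawn.sum())
            if k:
                ang = rng.uniform(0.0, 2.0 * np.pi, k)
                offs = np.column_stack([np.cos(ang), np.sin(ang)])
                mac_xy = np.vstack([mac_xy, vessels[spawn] + 1.2 * offs])
                mac_ids = np.concatenate(
                    [mac_ids, np.arange(next_id, next_id + k, dtype=np.intp)]
                )
                next_id += k
                mac_p = np.concatenate([mac_p, np.zeros(k)])
                mac_prox = np.concatenate([mac_prox, np.zeros(k)])

        # ii, iv) macrophage movement
        mac_step = np.zeros_like(mac_xy)
        if len(mac_xy):
            noise = rng.normal(0.0, _NOISE_SCALE, mac_xy.shape)
            mac_step += noise
            m1 = mac_p < 0.5
            if m1.any() and len(tum_xy):
                dirs, _ = _unit_towards(mac_xy[m1], tum_xy)
                mac_step[m1] += params.chemotaxis_sensitivity * _STEP_SCALE * dirs
            m2 = ~m1
            if m2.any():
                dirs, _ = _unit_towards(mac_xy[m2], vessels)
                mac_step[m2] += params.chemotaxis_sensitivity * _STEP_SCALE * dirs
            norms = np.linalg.norm(mac_step, axis=1, keepdims=True)
            over = norms[:, 0] > _MAX_STEP
            if over.any():
                mac_step[over] *= _MAX_STEP / norms[over]
            mac_xy = mac_xy + mac_step

        # iv) tumour cells follow nearby M2 macrophages
        if len(tum_xy) and len(mac_xy):
            m2_idx = np.where(mac_p >= 0.5)[0]
            if len(m2_idx):
                d = cdist(tum_xy, mac_xy[m2_idx])
                nearest = d.argmin(axis=1)
                follows = d[np.arange(len(tum_xy)), nearest] <= _FOLLOW_RADIUS
                if follows.any():
                    tum_xy = tum_xy.copy()
                    tum_xy[follows] += mac_step[m2_idx[nearest[follows]]]

        # iii) phenotype switching
        if len(mac_xy) and len(tum_xy):
            near_tum = cdist(mac_xy, tum_xy).min(axis=1) <= contact_radius
            mac_prox = mac_prox + near_tum
            switched = mac_prox >= params.phenotype_switch_threshold
            mac_p = np.minimum(1.0, mac_p + _PHENOTYPE_RATE * switched)

        # vi) M1 contact killing
        if len(tum_xy):
            m1_idx = np.where(mac_p < 0.5)[0]
            if len(m1_idx) and len(mac_xy):
                in_contact = cdist(tum_xy, mac_xy[m1_idx]).min(axis=1) <= contact_radius
                tum_contact = np.where(in_contact, tum_contact + 1.0, 0.0)
            else:
                tum_contact = np.zeros(len(tum_xy))
            if params.kill_contact_hours != inf:
                alive = tum_contact < params.kill_contact_hours
                tum_xy, tum_ids, tum_contact = tum_xy[alive], tum_ids[alive], tum_contact[alive]

        # v) proliferation
        if len(tum_xy) and params.proliferation_rate > 0:
            divide = rng.random(len(tum_xy)) < params.proliferation_rate
            k = int(divide.sum())
            if k:
                ang = rng.uniform(0.0, 2.0 * np.pi, k)
                child = tum_xy[divide] + 0.95 * np.column_stack([np.cos(ang), np.sin(ang)])
                tum_xy = np.vstack([tum_xy, child])
                tum_ids = np.concatenate(
                    [tum_ids, np.arange(next_id, next_id + k, dtype=np.intp)]
                )
                next_id += k
                tum_contact = np.concatenate([tum_contact, np.zeros(k)])

        # iv) M2 macrophages re-entering a vessel despawn
        if len(mac_xy):
            m2 = mac_p >= 0.5
            if m2.any():
                at_vessel = cdist(mac_xy, vessels).min(axis=1) <= contact_radius
                gone = m2 & at_vessel
                if gone.any():
                    keep = ~gone
                    mac_xy, mac_ids = mac_xy[keep], mac_ids[keep]
                    mac_p, mac_prox = mac_p[keep], mac_prox[keep]

        # vii) overlap resolution over all mobile cells, then clamp to domain
        n_t = len(tum_xy)
        allxy = np.vstack([tum_xy, mac_xy]) if len(mac_xy) else tum_xy
        if len(allxy):
            allxy = _resolve_overlaps(allxy, rng)
            allxy = np.clip(allxy, 0.0, params.domain_size)
            tum_xy, mac_xy = allxy[:n_t], allxy[n_t:]

        if t % params.snapshot_interval == 0:
            emit(t)

    return CellTimeSeries(snapshots=snapshots, params=params)


def generate_cohort(
    n_per_regime: int, base_seed: int, regimes: tuple[str, ...] = REGIMES
) -> list[tuple[CellTimeSeries, str]]:
    """3 * n_per_regime runs with seeds derived deterministically from ``base_seed``."""
    if n_per_regime < 1:
        raise ValueError("n_per_regime must be at least 1")
    out = []
    for ridx, regime in enumerate(regimes):
        for i in range(n_per_regime):
            seed = int(
                np.random.SeedSequence([int(base_seed), ridx, i]).generate_state(1)[0] % (2**31)
            )
            params = preset_params(regime, seed)
            out.append((simulate_run(params), regime))
    return out


def planted_spacing_clouds(
    n_runs: int, seed: int, n_points: int = 45, domain: float = 50.0
) -> list[tuple[np.ndarray, int]]:
    """Balanced synthetic macrophage clouds with planted spacing signatures.

    Class 1 clouds place points with nearest-neighbour spacing ~ U(1.2, 1.8)
    (closely spaced but not packed, the multi-scale cluster signature of the
    perivascular-niche class); class 0 clouds use spacing either below 1 or
    above 2.  Returns (points, label) pairs, alternating labels.
    """
    rng = np.random.default_rng([int(seed), 77])
    out = []
    for i in range(n_runs):
        label = i % 2
        if label == 1:
            spacing = rng.uniform(1.2, 1.8)
        elif i % 4 == 0:
            spacing = rng.uniform(0.4, 0.8)
        else:
            spacing = rng.uniform(2.5, 4.0)
        side = int(np.ceil(np.sqrt(n_points)))
        gx, gy = np.meshgrid(np.arange(side), np.arange(side))
        pts = np.column_stack([gx.ravel(), gy.ravel()])[:n_points] * spacing
        pts = pts + rng.normal(0.0, 0.05 * spacing, pts.shape)
        offset = rng.uniform(2.0, 6.0, 2)
        pts = np.clip(pts + offset, 0.0, domain)
        out.append((pts, label))
    return out
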