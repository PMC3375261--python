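"""Exact stochastic (Gillespie) simulation of the go-or-grow lattice model.

Each site of a d-dimensional cubic lattice is empty or holds one cell in the
proliferative (P) or migratory (M) state — size exclusion.  The whole system
is a continuous-time Markov chain over the 3^(L^d) lattice configurations;
per cell the event set is

    P-cell:  apoptosis (mu), switch to M (k_m), division (alpha)
    M-cell:  apoptosis (mu), switch to P (k_p), jump (nu)

Division places the daughter (a P-cell) uniformly in one of the *empty* von
Neumann neighbour sites and fails if the cell is fully enclosed.  A jump
picks one of the 2d directions uniformly and is wasted if the target site is
occupied or outside the lattice.  Both conventions are configurable
(``division_rule``/``move_rule`` in {"empty_only", "attempt"}) because the
master-equation derivation counts per-direction attempts while the event
description places daughters among empty sites; the default follows the
event description for division and the attempt convention for movement.

Rates are per-cell constants, so failed events consume the sampled Gillespie
event without side effects, and the total propensity is always

    n_P (mu + k_m + alpha) + n_M (mu + k_p + nu).

Boundaries are closed (no-flux): off-lattice moves and daughter placements
are simply not available.  Because the model is meant to describe a front
that never feels the edge, a trajectory is flagged as truncated from the
first moment any cell occupies the outermost shell of sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .params import LatticeGeometry, ModelRates, validate

__all__ = [
    "SiteState",
    "LatticeState",
    "SimTrajectory",
    "EnsembleField",
    "seed_single_cell",
    "run",
    "ensemble_occupancy",
    "interface_velocity",
    "trajectory_to_csv",
    "NoFrontError",
]

EVENT_NAMES = (
    "p_apoptosis",
    "p_switch",
    "division",
    "m_apoptosis",
    "m_switch",
    "jump",
)


class SiteState(IntEnum):
    EMPTY = 0
    P = 1
    M = 2


class NoFrontError(ValueError):
    """Occupancy field never crosses the requested threshold."""


@dataclass
class LatticeState:
    """Occupancy grid plus simulation clock."""

    geometry: LatticeGeometry
    grid: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.shape != self.geometry.shape:
            raise ValueError(
                f"grid shape {self.grid.shape} does not match geometry "
                f"{self.geometry.shape}"
            )

    @property
    def n_p(self) -> int:
        return int(np.count_nonzero(self.grid == SiteState.P))

    @property
    def n_m(self) -> int:
        return int(np.count_nonzero(self.grid == SiteState.M))

    @property
    def mass(self) -> int:
        return int(np.count_nonzero(self.grid))


@dataclass
class SimTrajectory:
    """Cell counts at checkpoint times plus bookkeeping."""

    times: np.ndarray
    n_p: np.ndarray
    n_m: np.ndarray
    event_counts: dict[str, int]
    truncated_at: float | None = None
    snapshots: dict[float, np.ndarray] = field(default_factory=dict)
    final_state: LatticeState | None = None

    @property
    def mass(self) -> np.ndarray:
        return self.n_p + self.n_m

    @property
    def valid(self) -> np.ndarray:
        """Mask of checkpoints unaffected by boundary contact."""
        if self.truncated_at is None:
            return np.ones_like(self.times, dtype=bool)
        return self.times < self.truncated_at


@dataclass
class EnsembleField:
    """Per-site occupancy frequency at a fixed time over replicates."""

    geometry: LatticeGeometry
    t: float
    frequency: np.ndarray
    n_reps: int
    flagged: bool = False


def seed_single_cell(geom: LatticeGeometry) -> LatticeState:
    """A single P-cell at the central site — the clonal origin of the tumour."""
    grid = np.zeros(geom.shape, dtype=np.int8)
    grid[geom.center] = SiteState.P
    return LatticeState(geometry=geom, grid=grid, t=0.0)


def _neighbour_offsets(shape: tuple[int, ...]) -> np.ndarray:
    """Flat-index offsets of the 2d von Neumann directions."""
    strides = np.ones(len(shape), dtype=np.int64)
    for axis in range(len(shape) - 2, -1, -1):
        strides[axis] = strides[axis + 1] * shape[axis + 1]
    offsets = []
    for axis in range(len(shape)):
        offsets.extend([int(strides[axis]), -int(strides[axis])])
    return np.array(offsets, dtype=np.int64)


def run(
    initial: LatticeState,
    rates: ModelRates,
    t_end: float,
    checkpoints: np.ndarray | list[float] | None = None,
    seed: int | np.random.Generator = 0,
    move_rule: str = "attempt",
    division_rule: str = "empty_only",
    snapshot_times: list[float] | None = None,
    keep_final_state: bool = False,
) -> SimTrajectory:
    """Exact SSA trajectory from ``initial`` to ``t_end``.

    Identical seeds and inputs reproduce bit-identical event sequences.
    ``checkpoints`` default to every cell cycle; ``snapshot_times`` request
    grid copies at the first checkpoint >= each requested time.
    """
    validate(rates, initial.geometry)
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if move_rule not in ("attempt", "empty_only"):
        raise ValueError(f"unknown move_rule {move_rule!r}")
    if division_rule not in ("attempt", "empty_only"):
        raise ValueError(f"unknown division_rule {division_rule!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    geom = initial.geometry
    shape = geom.shape
    d = geom.d
    L = geom.L
    grid = initial.grid.ravel().copy()
    offsets = _neighbour_offsets(shape)
    n_dirs = 2 * d
    # Per-axis coordinate extraction for boundary checks on flat indices.
    strides = np.empty(d, dtype=np.int64)
    strides[-1] = 1
    for axis in range(d - 2, -1, -1):
        strides[axis] = strides[axis + 1] * shape[axis + 1]

    def on_boundary(idx: int) -> bool:
        for axis in range(d):
            coord = (idx // strides[axis]) % L
            if coord == 0 or coord == L - 1:
                return True
        return False

    def neighbour(idx: int, direction: int) -> int:
        axis = direction // 2
        sign = 1 if direction % 2 == 0 else -1
        coord = (idx // strides[axis]) % L
        new = coord + sign
        if new < 0 or new >= L:
            return -1
        return idx + sign * int(strides[axis])

    p_sites = list(np.flatnonzero(grid == SiteState.P))
    m_sites = list(np.flatnonzero(grid == SiteState.M))
    p_sites = [int(i) for i in p_sites]
    m_sites = [int(i) for i in m_sites]

    if checkpoints is None:
        checkpoints = np.arange(1.0, t_end + 0.5)
    ck = np.asarray(checkpoints, dtype=float)
    if ck.size and (np.any(ck <= 0) or np.any(np.diff(ck) <= 0)):
        raise ValueError("checkpoints must be positive and strictly increasing")
    snap_req = sorted(snapshot_times) if snapshot_times else []

    times_out: list[float] = []
    np_out: list[int] = []
    nm_out: list[int] = []
    snapshots: dict[float, np.ndarray] = {}
    counts = dict.fromkeys(EVENT_NAMES, 0)
    truncated_at: float | None = None
    if any(on_boundary(i) for i in p_sites + m_sites):
        truncated_at = initial.t

    t = initial.t
    ck_idx = 0
    alpha, nu, mu, k_p, k_m = rates.alpha, rates.nu, rates.mu, rates.k_p, rates.k_m
    p_event_rate = mu + k_m + alpha
    m_event_rate = mu + k_p + nu

    def record_through(t_new: float) -> None:
        nonlocal ck_idx
        while ck_idx < ck.size and ck[ck_idx] <= min(t_new, t_end) + 1e-12:
            times_out.append(float(ck[ck_idx]))
            np_out.append(len(p_sites))
            nm_out.append(len(m_sites))
            while snap_req and snap_req[0] <= ck[ck_idx] + 1e-12:
                snapshots[float(ck[ck_idx])] = grid.reshape(shape).copy()
                snap_req.pop(0)
            ck_idx += 1

    def note_placement(idx: int) -> None:
        nonlocal truncated_at
        if truncated_at is None and on_boundary(idx):
            truncated_at = t

    while True:
        n_pc = len(p_sites)
        n_mc = len(m_sites)
        total = n_pc * p_event_rate + n_mc * m_event_rate
        if total <= 0.0:
            record_through(t_end)
            t = t_end
            break
        dt = rng.exponential(1.0 / total)
        t_next = t + dt
        if t_next > t_end:
            record_through(t_end)
            t = t_end
            break
        record_through(t_next)
        t = t_next
        x = rng.random() * total
        if x < n_pc * p_event_rate:
            i = int(rng.integers(n_pc))
            site = p_sites[i]
            y = x % p_event_rate  # uniform in [0, p_event_rate)
            if y < mu:
                counts["p_apoptosis"] += 1
                grid[site] = SiteState.EMPTY
                p_sites[i] = p_sites[-1]
                p_sites.pop()
            elif y < mu + k_m:
                counts["p_switch"] += 1
                grid[site] = SiteState.M
                p_sites[i] = p_sites[-1]
                p_sites.pop()
                m_sites.append(site)
            else:
                counts["division"] += 1
                if division_rule == "empty_only":
                    empties = [
                        n
                        for direction in range(n_dirs)
                        if (n := neighbour(site, direction)) >= 0
                        and grid[n] == SiteState.EMPTY
                    ]
                    if empties:
                        target = empties[int(rng.integers(len(empties)))]
                        grid[target] = SiteState.P
                        p_sites.append(target)
                        note_placement(target)
                else:  # attempt: one direction, wasted if blocked
                    target = neighbour(site, int(rng.integers(n_dirs)))
                    if target >= 0 and grid[target] == SiteState.EMPTY:
                        grid[target] = SiteState.P
                        p_sites.append(target)
                        note_placement(target)
        else:
            x -= n_pc * p_event_rate
            i = int(rng.integers(n_mc))
            site = m_sites[i]
            y = x % m_event_rate
            if y < mu:
                counts["m_apoptosis"] += 1
                grid[site] = SiteState.EMPTY
                m_sites[i] = m_sites[-1]
                m_sites.pop()
            elif y < mu + k_p:
                counts["m_switch"] += 1
                grid[site] = SiteState.P
                m_sites[i] = m_sites[-1]
                m_sites.pop()
                p_sites.append(site)
            else:
                counts["jump"] += 1
                if move_rule == "attempt":
                    target = neighbour(site, int(rng.integers(n_dirs)))
                    if target >= 0 and grid[target] == SiteState.EMPTY:
                        grid[site] = SiteState.EMPTY
                        grid[target] = SiteState.M
                        m_sites[i] = target
                        note_placement(target)
                else:
                    empties = [
                        n
                        for direction in range(n_dirs)
                        if (n := neighbour(site, direction)) >= 0
                        and grid[n] == SiteState.EMPTY
                    ]
                    if empties:
                        target = empties[int(rng.integers(len(empties)))]
                        grid[site] = SiteState.EMPTY
                        grid[target] = SiteState.M
                        m_sites[i] = target
                        note_placement(target)

    final = LatticeState(geometry=geom, grid=grid.reshape(shape).copy(), t=t)
    return SimTrajectory(
        times=np.array(times_out),
        n_p=np.array(np_out, dtype=np.int64),
        n_m=np.array(nm_out, dtype=np.int64),
        event_counts=counts,
        truncated_at=truncated_at,
        snapshots=snapshots,
        final_state=final if keep_final_state else None,
    )


def ensemble_occupancy(
    initial: LatticeState,
    rates: ModelRates,
    t: float,
    n_reps: int,
    seed: int = 0,
    **run_kwargs,
) -> EnsembleField:
    """Per-site occupancy frequency at time t across independent replicates.

    Replicate streams are spawned deterministically from the root seed via
    ``numpy.random.SeedSequence.spawn``, so the field is reproducible and
    replicates are statistically independent.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    fields = ensemble_occupancy_series(
        initial, rates, [t], n_reps, seed=seed, **run_kwargs
    )
    return fields[0]


def ensemble_occupancy_series(
    initial: LatticeState,
    rates: ModelRates,
    times: list[float],
    n_reps: int,
    seed: int = 0,
    **run_kwargs,
) -> list[EnsembleField]:
    """Occupancy frequency fields at several times from the same replicates."""
    times = sorted(float(t) for t in times)
    if not times or times[0] <= 0:
        raise ValueError("snapshot times must be positive")
    geom = initial.geometry
    acc = {t: np.zeros(geom.shape, dtype=np.int64) for t in times}
    flagged = False
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    for ss in streams:
        rng = np.random.default_rng(ss)
        traj = run(
            initial,
            rates,
            t_end=times[-1],
            checkpoints=times,
            seed=rng,
            snapshot_times=list(times),
            **run_kwargs,
        )
        if traj.truncated_at is not None:
            flagged = True
        for t in times:
            acc[t] += traj.snapshots[t] != SiteState.EMPTY
    return [
        EnsembleField(
            geometry=geom,
            t=t,
            frequency=acc[t] / n_reps,
            n_reps=n_reps,
            flagged=flagged,
        )
        for t in times
    ]


def _axis_front_radii(field: EnsembleField, threshold: float) -> list[float]:
    """Outermost threshold-crossing distance from the centre, per direction.

    The occupancy is read along the axis lines through the lattice centre
    (the natural choice for a radially symmetric tumour seeded centrally)."""
    geom = field.geometry
    center = geom.center
    radii: list[float] = []
    for axis in range(geom.d):
        index: list = list(center)
        index[axis] = slice(None)
        line = np.asarray(field.frequency[tuple(index)], dtype=float)
        c = center[axis]
        for segment in (line[c:], line[c::-1]):
            above = np.flatnonzero(segment >= threshold)
            if above.size == 0:
                raise NoFrontError(
                    f"occupancy never reaches {threshold} at t={field.t}"
                )
            i = int(above[-1])
            if i == segment.size - 1:
                radii.append(float(i))
            else:
                frac = (segment[i] - threshold) / (segment[i] - segment[i + 1])
                radii.append(float(i) + float(frac))
    return radii


def interface_velocity(
    fields: list[EnsembleField], threshold: float = 0.5
) -> tuple[float, np.ndarray, np.ndarray]:
    """Front speed from ensemble occupancy fields at successive times.

    For every axis and direction the outermost crossing of ``threshold``
    (linearly interpolated between sites) is located, the 2d radii are
    averaged into one front radius per time, and the speed is the
    least-squares slope of radius versus time.  Returns (speed, times,
    radii)."""
    if len(fields) < 3:
        raise ValueError("need at least 3 time points")
    if any(f.flagged for f in fields):
        raise ValueError("ensemble fields flagged by boundary contact")
    times = np.array([f.t for f in fields])
    radii = np.array(
        [float(np.mean(_axis_front_radii(f, threshold))) for f in fields]
    )
    slope = float(np.polyfit(times, radii, 1)[0])
    return slope, times, radii


def trajectory_to_csv(traj: SimTrajectory, path) -> None:
    """Write checkpoint counts as CSV with header ``t,n_P,n_M,mass``."""
    arr = np.column_stack([traj.times, traj.n_p, traj.n_m, traj.mass])
    np.savetxt(
        path, arr, delimiter=",", header="t,n_P,n_M,mass", comments="",
        fmt=["%.6f", "%d", "%d", "%d"],
    )
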