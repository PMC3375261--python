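"""Two-species master equations on a 1-D lattice and front tracking.

Writing ``p_i(t)`` and ``m_i(t)`` for the probabilities of finding a
proliferating resp. migrating cell at site ``i``, and assuming occupancies of
neighbouring sites independent, the per-site balance of division, jumping,
switching and apoptosis gives

    dp_i/dt = (alpha/2) (1 - p_i - m_i)(p_{i-1} + p_{i+1})
              - (mu + k_m) p_i + k_p m_i
    dm_i/dt = (nu/2) [ (1 - p_i - m_i)(m_{i-1} + m_{i+1})
                       - m_i ((1 - p_{i-1} - m_{i-1}) + (1 - p_{i+1} - m_{i+1})) ]
              - (mu + k_p) m_i + k_m p_i

Via the discrete Laplacian these are the lattice discretisation of a
reaction-diffusion system: density-modulated diffusion plus logistic growth
for p, and the cross-diffusion typical of a two-species exclusion process for
m.  The system is integrated *as the lattice equations* (method of lines on
the unit grid) rather than as a re-discretised PDE — this is the object the
stochastic model actually coarse-grains to, and the PDE form lives in
:mod:`gogrow.waves` where the wave-speed analysis uses it.

Boundary conditions are no-flux, implemented with ghost sites mirrored
across the boundary face (zero-gradient copies), which conserves total mass
exactly up to the reaction terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .params import ModelRates, validate

__all__ = [
    "OccupancyProfiles",
    "FrontSeries",
    "FrontSpeedResult",
    "NoFrontError",
    "TruncationWarning",
    "master_rhs",
    "integrate",
    "step_profile",
    "front_position",
    "front_series",
    "front_speed",
    "propagation_speed",
    "profiles_to_csv",
]

#: Occupancy violations smaller than this are clipped silently; larger ones
#: indicate an integrator failure and raise.
BOUNDS_TOL = 1e-9


class NoFrontError(ValueError):
    """The occupancy profile never crosses the front threshold."""


class TruncationWarning(UserWarning):
    """The front reached the far end of the domain; later times are unreliable."""


@dataclass
class OccupancyProfiles:
    """Per-site occupancy probabilities (p, m) on a uniform 1-D grid."""

    x: np.ndarray
    p: np.ndarray
    m: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        if not (self.x.shape == self.p.shape == self.m.shape):
            raise ValueError("x, p and m must have identical shapes")

    @property
    def total(self) -> np.ndarray:
        return self.p + self.m

    def check_bounds(self, tol: float = BOUNDS_TOL) -> None:
        worst = max(
            float(np.max(-self.p, initial=0.0)),
            float(np.max(-self.m, initial=0.0)),
            float(np.max(self.total - 1.0, initial=0.0)),
        )
        if worst > tol:
            raise ValueError(
                f"occupancy bounds violated by {worst:.3e} (> {tol:.1e}) at t={self.t}"
            )


@dataclass
class FrontSeries:
    """Positions of the front reference point as a function of time."""

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)


@dataclass
class FrontSpeedResult:
    speed: float
    intercept: float
    residual: float
    window: tuple[float, float]


def _ghosted(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Left/right neighbour arrays under zero-gradient (mirrored-face) ghosts."""
    left = np.concatenate((f[:1], f[:-1]))
    right = np.concatenate((f[1:], f[-1:]))
    return left, right


def master_rhs(
    profiles: OccupancyProfiles, rates: ModelRates
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivative (dp/dt, dm/dt) of the coupled master equations."""
    profiles.check_bounds(tol=1e-6)
    p, m = profiles.p, profiles.m
    return _rhs_arrays(p, m, rates)


def _rhs_arrays(
    p: np.ndarray, m: np.ndarray, rates: ModelRates
) -> tuple[np.ndarray, np.ndarray]:
    e = 1.0 - p - m
    pl, pr = _ghosted(p)
    ml, mr = _ghosted(m)
    el, er = _ghosted(e)
    dp = 0.5 * rates.alpha * e * (pl + pr) - (rates.mu + rates.k_m) * p + rates.k_p * m
    dm = (
        0.5 * rates.nu * (e * (ml + mr) - m * (el + er))
        - (rates.mu + rates.k_p) * m
        + rates.k_m * p
    )
    return dp, dm


def step_profile(
    n_sites: int = 600, extent: int = 10, height: float = 1.0
) -> OccupancyProfiles:
    """Canonical initial condition: P-occupancy ``height`` on the ``extent``
    leftmost sites, no migratory cells — a tumour seeded by a few
    proliferating cells at one end of the domain."""
    x = np.arange(n_sites, dtype=float)
    p = np.zeros(n_sites)
    p[:extent] = height
    m = np.zeros(n_sites)
    return OccupancyProfiles(x=x, p=p, m=m, t=0.0)


def integrate(
    initial: OccupancyProfiles,
    rates: ModelRates,
    t_end: float,
    checkpoints: np.ndarray | list[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    truncation_fraction: float = 0.9,
) -> list[OccupancyProfiles]:
    """Integrate the master equations, returning profiles at each checkpoint.

    The state is interleaved (p_0, m_0, p_1, m_1, ...) so the Jacobian is
    banded with bandwidth 3, which LSODA exploits.  A ``TruncationWarning``
    is emitted if the total density at the start of the last 10% of the
    domain exceeds the front threshold at the final checkpoint, i.e. if the
    front ran out of room.
    """
    validate(rates)
    initial.check_bounds()
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if checkpoints is None:
        checkpoints = np.arange(1.0, t_end + 0.5)
    checkpoints = np.asarray(checkpoints, dtype=float)
    if np.any(checkpoints <= 0) or np.any(np.diff(checkpoints) <= 0):
        raise ValueError("checkpoints must be positive and strictly increasing")
    n = initial.p.size
    y0 = np.empty(2 * n)
    y0[0::2] = initial.p
    y0[1::2] = initial.m

    def fun(t: float, y: np.ndarray) -> np.ndarray:
        dp, dm = _rhs_arrays(y[0::2], y[1::2], rates)
        out = np.empty_like(y)
        out[0::2] = dp
        out[1::2] = dm
        return out

    options = {}
    if method == "LSODA":
        options = {"lband": 3, "uband": 3}
    sol = solve_ivp(
        fun,
        (0.0, float(t_end)),
        y0,
        t_eval=checkpoints,
        method=method,
        rtol=rtol,
        atol=atol,
        **options,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    out: list[OccupancyProfiles] = []
    for j, t in enumerate(sol.t):
        p = sol.y[0::2, j]
        m = sol.y[1::2, j]
        prof = OccupancyProfiles(x=initial.x.copy(), p=p, m=m, t=float(t))
        prof.check_bounds()
        prof.p = np.clip(prof.p, 0.0, 1.0)
        prof.m = np.clip(prof.m, 0.0, 1.0)
        out.append(prof)
    tail_start = int(truncation_fraction * n)
    if out and float(np.max(out[-1].total[tail_start:])) > 0.5:
        warnings.warn(
            "front entered the last 10% of the domain; increase the domain "
            "length or shorten the run",
            TruncationWarning,
            stacklevel=2,
        )
    return out


def front_position(profiles: OccupancyProfiles, threshold: float = 0.5) -> float:
    """Outermost downward crossing of ``threshold`` by the total density p+m.

    Linear interpolation between the bracketing sites.  Raises
    :class:`NoFrontError` if the profile never reaches the threshold; if the
    density crosses several times the outermost crossing is used and a
    warning attached.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    total = profiles.total
    above = np.flatnonzero(total >= threshold)
    if above.size == 0:
        raise NoFrontError(f"total density never reaches {threshold} at t={profiles.t}")
    i = int(above[-1])
    # count only downward (above -> below) crossings: a single front has one
    crossings = np.count_nonzero(np.diff((total >= threshold).astype(int)) == -1)
    if crossings > 1:
        warnings.warn(
            f"{crossings} threshold crossings at t={profiles.t}; using the outermost",
            UserWarning,
            stacklevel=2,
        )
    if i == total.size - 1:
        return float(profiles.x[i])
    frac = (total[i] - threshold) / (total[i] - total[i + 1])
    return float(profiles.x[i] + frac * (profiles.x[i + 1] - profiles.x[i]))


def front_series(
    profile_list: list[OccupancyProfiles], threshold: float = 0.5
) -> FrontSeries:
    times = np.array([prof.t for prof in profile_list])
    positions = np.array([front_position(prof, threshold) for prof in profile_list])
    return FrontSeries(times=times, positions=positions)


def front_speed(
    series: FrontSeries, window: tuple[float, float] = (25.0, 50.0)
) -> FrontSpeedResult:
    """Least-squares slope of the reference-point position over a time window.

    The default window starts at t=25 cell cycles to exclude the initial
    transient during which the profile relaxes towards the travelling wave.
    """
    lo, hi = window
    mask = (series.times >= lo) & (series.times <= hi)
    if np.count_nonzero(mask) < 5:
        raise ValueError("need at least 5 checkpoints inside the fit window")
    t = series.times[mask]
    x = series.positions[mask]
    if not np.all(np.isfinite(x)):
        raise NoFrontError("front position undefined inside the fit window")
    (slope, intercept), res, *_ = np.polyfit(t, x, 1, full=True)
    residual = float(res[0]) if res.size else 0.0
    return FrontSpeedResult(
        speed=float(slope), intercept=float(intercept), residual=residual, window=window
    )


def propagation_speed(
    rates: ModelRates,
    n_sites: int = 600,
    extent: int = 10,
    window: tuple[float, float] = (25.0, 50.0),
    threshold: float = 0.5,
    checkpoint_step: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> FrontSpeedResult:
    """Convenience pipeline: step initial condition -> integrate -> fit speed."""
    t_end = window[1]
    checkpoints = np.arange(checkpoint_step, t_end + 0.5 * checkpoint_step,
                            checkpoint_step)
    profs = integrate(
        step_profile(n_sites=n_sites, extent=extent),
        rates,
        t_end=t_end,
        checkpoints=checkpoints,
        rtol=rtol,
        atol=atol,
    )
    series = front_series(profs, threshold=threshold)
    return front_speed(series, window=window)


def profiles_to_csv(profiles: OccupancyProfiles, path) -> None:
    """Write one checkpoint profile as CSV with header ``x,p,m``."""
    arr = np.column_stack([profiles.x, profiles.p, profiles.m])
    np.savetxt(path, arr, delimiter=",", header="x,p,m", comments="")
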