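"""Travelling-wave speed analysis of the go-or-grow reaction-diffusion system.

The PDE approximation of the master equations,

    p_t = D_a [(1-p-m) p]_xx-ish transport + alpha (1-p-m) p - (mu+k_m) p + k_p m
    m_t = D_n [(1-p-m) m_xx - m (1-p-m)_xx] - (mu+k_p) m + k_m p,

admits front solutions p(x - c t), m(x - c t) invading the empty (healthy)
state.  Substituting the travelling-wave ansatz and linearising about the
origin (p, m, p', m') = 0 yields a 4-D autonomous system whose Jacobian
eigenvalues are the roots of the quartic

    F(lambda) = (D_a lambda^2 + c lambda + (alpha - mu - k_m))
              * (D_n lambda^2 + c lambda - (mu + k_p))  -  k_p k_m.

For c below the minimal wave speed the origin is a spiral — the front would
oscillate into negative occupancies — and some roots are complex.  The
minimal (linear, pulled) speed c* is the smallest c at which all roots are
real, located here by a coarse ascending scan followed by bisection.

D_a and D_nu are *per-axis* diffusion constants alpha/(2d) and nu/(2d): to
compare the 1-D analysis with a d-dimensional simulation only the motion
component normal to the front counts, which rescales the diffusion
coefficients but none of the reaction rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .params import DiffusionConstants, ModelRates, diffusion_constants, validate

__all__ = [
    "WaveSpeedQuery",
    "SpectralResult",
    "FixedPoints",
    "CriticalityResult",
    "OptimalSwitching",
    "characteristic_roots",
    "minimal_wave_speed",
    "fixed_points",
    "critical_apoptosis",
    "critical_exponent",
    "optimal_switching",
    "dimension_rescale",
]


@dataclass(frozen=True)
class WaveSpeedQuery:
    """Inputs of a minimal-wave-speed computation.

    ``effective_dimension`` rescales the diffusion constants to their
    per-axis values for comparison with a d-dimensional simulation;
    ``resolution`` is the bisection width at which the scan for c* stops and
    ``realness_tol`` the |Im lambda| below which a root counts as real.
    """

    rates: ModelRates
    effective_dimension: int = 1
    coarse_step: float = 0.01
    resolution: float = 1e-6
    realness_tol: float = 1e-9
    ceiling: float = 100.0

    def __post_init__(self) -> None:
        if self.resolution <= 0 or self.realness_tol <= 0 or self.coarse_step <= 0:
            raise ValueError("scan resolution and tolerance must be positive")
        if self.effective_dimension not in (1, 2, 3):
            raise ValueError("effective_dimension must be 1, 2 or 3")


@dataclass
class SpectralResult:
    """Roots of the origin-Jacobian characteristic polynomial at speed c."""

    c: float
    roots: np.ndarray
    max_imag: float
    converged: bool


@dataclass
class FixedPoints:
    """Spatially homogeneous steady states (p, m) of the kinetics."""

    healthy: tuple[float, float]
    invaded: tuple[float, float] | None


@dataclass
class CriticalityResult:
    mu_c: float
    beta: float
    residual: float
    eps_range: tuple[float, float]


@dataclass
class OptimalSwitching:
    k_p: float
    k_m: float
    c: float
    ratio: float
    on_boundary: bool


def _quartic_coeffs(
    c: float, rates: ModelRates, D: DiffusionConstants
) -> np.ndarray:
    """Coefficients (highest power first) of the characteristic polynomial."""
    A = rates.alpha - rates.mu - rates.k_m
    B = -(rates.mu + rates.k_p)
    return np.array(
        [
            D.D_alpha * D.D_nu,
            c * (D.D_alpha + D.D_nu),
            D.D_alpha * B + D.D_nu * A + c * c,
            c * (A + B),
            A * B - rates.k_p * rates.k_m,
        ]
    )


def _polish(roots: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """One Newton step per root on the polynomial itself."""
    deriv = np.polyder(coeffs)
    fp = np.polyval(deriv, roots)
    f = np.polyval(coeffs, roots)
    safe = np.abs(fp) > 1e-12
    roots = roots.astype(complex)
    roots[safe] = roots[safe] - f[safe] / fp[safe]
    return roots


def characteristic_roots(
    c: float,
    rates: ModelRates,
    effective_dimension: int = 1,
    realness_tol: float = 1e-9,
) -> SpectralResult:
    """Roots of F(lambda) for candidate speed c.

    With ``k_p * k_m == 0`` the quartic factors exactly into the two
    quadratic brackets; with ``nu == 0`` the leading coefficient vanishes and
    only the finite roots (degree < 4) are reported.
    """
    if c < 0:
        raise ValueError("candidate speed c must be >= 0")
    D = diffusion_constants(rates, effective_dimension)
    coeffs = _quartic_coeffs(c, rates, D)
    nz = np.flatnonzero(np.abs(coeffs) > 0)
    if nz.size == 0:
        return SpectralResult(c=c, roots=np.array([]), max_imag=0.0, converged=True)
    trimmed = coeffs[nz[0]:]
    roots = np.roots(trimmed)
    roots = _polish(roots, trimmed)
    max_imag = float(np.max(np.abs(roots.imag))) if roots.size else 0.0
    return SpectralResult(
        c=c, roots=roots, max_imag=max_imag, converged=max_imag <= realness_tol
    )


def _all_real(c: float, query: WaveSpeedQuery) -> bool:
    return characteristic_roots(
        c,
        query.rates,
        query.effective_dimension,
        query.realness_tol,
    ).converged


def minimal_wave_speed(query: WaveSpeedQuery | ModelRates, **kwargs) -> float:
    """Smallest c >= 0 with an all-real origin spectrum (the pulled-front speed).

    Returns 0 when the healthy state is not invadable (mu >= mu_c), since no
    front exists there.  Accepts either a :class:`WaveSpeedQuery` or a bare
    :class:`ModelRates` plus query fields as keyword arguments.
    """
    if isinstance(query, ModelRates):
        query = WaveSpeedQuery(rates=query, **kwargs)
    rates = query.rates
    validate(rates)
    if rates.alpha <= 0:
        return 0.0
    # Origin invadable iff the homogeneous linearisation
    # [[A, k_p], [k_m, B]] (A = alpha-mu-k_m, B = -(mu+k_p)) has a positive
    # leading eigenvalue.  Equivalent to AB - k_p k_m < 0 except in the
    # degenerate mu = k_p = 0 case, so use the eigenvalue directly.
    A = rates.alpha - rates.mu - rates.k_m
    B = -(rates.mu + rates.k_p)
    leading = 0.5 * (A + B) + math.sqrt(0.25 * (A - B) ** 2 + rates.k_p * rates.k_m)
    if leading <= 0:
        return 0.0
    step = query.coarse_step
    c_lo = 0.0
    c_hi = step
    while not _all_real(c_hi, query):
        c_lo = c_hi
        c_hi += step
        if c_hi > query.ceiling:
            raise RuntimeError(
                f"no all-real spectrum found below the scan ceiling {query.ceiling}"
            )
    while c_hi - c_lo > query.resolution:
        mid = 0.5 * (c_lo + c_hi)
        if _all_real(mid, query):
            c_hi = mid
        else:
            c_lo = mid
    return c_hi


def fixed_points(rates: ModelRates) -> FixedPoints:
    """Homogeneous steady states of the kinetics: healthy (0,0) and invaded.

    Setting the reaction terms to zero gives M* = k_m P* / (mu + k_p) and

        P* = [alpha - mu - k_m + k_p k_m/(mu + k_p)]
             / [alpha (1 + k_m/(mu + k_p))].

    In the mu -> 0 limit this reduces to (P*, M*) = (k_p, k_m)/(k_p + k_m):
    only the relative magnitude of the switching rates sets the equilibrium
    occupancies.  If P* <= 0 no invaded state exists (tumour extinction).
    """
    validate(rates)
    if rates.alpha <= 0:
        return FixedPoints(healthy=(0.0, 0.0), invaded=None)
    denom_switch = rates.mu + rates.k_p
    if denom_switch == 0.0:
        # mu = k_p = 0: M-cells are absorbing; invaded state exists only if
        # they are never produced.
        if rates.k_m == 0.0:
            return FixedPoints(healthy=(0.0, 0.0), invaded=(1.0, 0.0))
        return FixedPoints(healthy=(0.0, 0.0), invaded=None)
    r = rates.k_m / denom_switch
    p_star = (rates.alpha - rates.mu - rates.k_m + rates.k_p * r) / (
        rates.alpha * (1.0 + r)
    )
    if p_star <= 0:
        return FixedPoints(healthy=(0.0, 0.0), invaded=None)
    m_star = r * p_star
    return FixedPoints(healthy=(0.0, 0.0), invaded=(float(p_star), float(m_star)))


def critical_apoptosis(alpha: float, k_p: float, k_m: float) -> float:
    """Critical apoptosis rate mu_c above which the tumour cannot invade.

    mu_c is the positive root of (alpha - mu - k_m)(mu + k_p) + k_p k_m = 0,
    i.e. where the leading eigenvalue of the homogeneous linearisation
    [[alpha - mu - k_m, k_p], [k_m, -(mu + k_p)]] crosses zero.  For k_m = 0
    this collapses to mu_c = alpha (plain logistic growth)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if k_p < 0 or k_m < 0:
        raise ValueError("switching rates must be >= 0")
    b = alpha - k_m - k_p
    return 0.5 * (b + math.sqrt(b * b + 4.0 * alpha * k_p))


def critical_exponent(
    rates: ModelRates,
    effective_dimension: int = 1,
    decades: tuple[float, float] = (1.0, 4.0),
    points_per_decade: int = 4,
    resolution: float = 1e-9,
) -> CriticalityResult:
    """Fit the exponent beta in c*(mu) ~ (mu_c - mu)^beta near criticality.

    The apoptosis field of ``rates`` is ignored; mu is swept over
    mu_c (1 - eps) with eps log-spaced across ``decades``.  The vanishing of
    the front speed behaves like a second-order phase transition; the model
    prediction is beta = 1/2 regardless of the other rates.
    """
    mu_c = critical_apoptosis(rates.alpha, rates.k_p, rates.k_m)
    n = int(round((decades[1] - decades[0]) * points_per_decade)) + 1
    eps = np.logspace(-decades[0], -decades[1], n)
    speeds = np.empty(n)
    for i, e in enumerate(eps):
        mu = mu_c * (1.0 - e)
        q = WaveSpeedQuery(
            rates=rates.replace(mu=mu),
            effective_dimension=effective_dimension,
            resolution=resolution,
        )
        speeds[i] = minimal_wave_speed(q)
        if speeds[i] <= 0:
            raise RuntimeError(f"wave speed vanished below mu_c at eps={e:g}")
    logd = np.log(mu_c * eps)
    logc = np.log(speeds)
    (beta, _), res, *_ = np.polyfit(logd, logc, 1, full=True)
    residual = float(res[0]) if res.size else 0.0
    return CriticalityResult(
        mu_c=float(mu_c),
        beta=float(beta),
        residual=residual,
        eps_range=(float(eps.min()), float(eps.max())),
    )


def optimal_switching(
    alpha: float = 1.0,
    nu: float = 5.0,
    mu: float = 0.01,
    bounds: tuple[float, float] = (0.05, 24.0),
    grid: int = 40,
    effective_dimension: int = 1,
    refine: bool = True,
    resolution: float = 1e-6,
) -> OptimalSwitching:
    """Switching rates (k_p, k_m) maximising the invasion speed.

    Coarse log-spaced grid search over ``bounds``^2 followed by a
    derivative-free (Nelder-Mead) refinement in log coordinates.  The
    orientation of the optimum ratio (which rate is larger) depends on the
    diffusion contrast, so the reported ``ratio`` is min/max of the two
    rates.  ``on_boundary`` flags maximisers pinned to the search bounds —
    with the hourly switching cap the speed can still be increasing in the
    overall switching scale at the cap."""
    lo, hi = bounds
    if not 0 < lo < hi <= 24.0:
        raise ValueError("bounds must satisfy 0 < lo < hi <= 24")

    def speed(k_p: float, k_m: float) -> float:
        q = WaveSpeedQuery(
            rates=ModelRates(alpha=alpha, nu=nu, mu=mu, k_p=k_p, k_m=k_m),
            effective_dimension=effective_dimension,
            resolution=resolution,
        )
        return minimal_wave_speed(q)

    ks = np.logspace(math.log10(lo), math.log10(hi), grid)
    best = (-np.inf, lo, lo)
    for k_p in ks:
        for k_m in ks:
            c = speed(k_p, k_m)
            if c > best[0]:
                best = (c, float(k_p), float(k_m))
    c_best, kp_best, km_best = best
    if refine:
        def neg(logk: np.ndarray) -> float:
            k_p, k_m = np.exp(logk)
            k_p = min(max(k_p, lo), hi)
            k_m = min(max(k_m, lo), hi)
            return -speed(k_p, k_m)

        res = minimize(
            neg,
            np.log([kp_best, km_best]),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 200},
        )
        k_p, k_m = np.exp(res.x)
        k_p = float(min(max(k_p, lo), hi))
        k_m = float(min(max(k_m, lo), hi))
        c_ref = speed(k_p, k_m)
        if c_ref >= c_best:
            c_best, kp_best, km_best = c_ref, k_p, k_m
    edge = 1e-3
    on_boundary = any(
        abs(math.log(k / b)) < edge
        for k in (kp_best, km_best)
        for b in (lo, hi)
    )
    ratio = min(kp_best, km_best) / max(kp_best, km_best)
    return OptimalSwitching(
        k_p=kp_best, k_m=km_best, c=c_best, ratio=ratio, on_boundary=on_boundary
    )


def dimension_rescale(rates: ModelRates, d: int) -> WaveSpeedQuery:
    """Query for a 1-D analysis comparable to a d-dimensional simulation.

    Only the per-axis diffusion constants change (alpha/(2d), nu/(2d));
    reaction rates are untouched, since switching, division and death are
    local events with no directional component."""
    if d not in (1, 2, 3):
        raise ValueError("d must be 1, 2 or 3")
    return WaveSpeedQuery(rates=rates, effective_dimension=d)
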