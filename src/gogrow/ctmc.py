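"""Exact continuous-time Markov chain treatment of small lattices.

The whole lattice model is a CTMC over the 3^(L^d) configurations (each site
empty, P or M).  For tiny lattices the generator can be built explicitly and
the distribution at time t computed with a matrix exponential — an exact
reference against which the Gillespie simulator can be validated, with no
Monte-Carlo error on this side.

States are encoded base-3 over flattened site order: configuration index
``sum_i s_i 3^i`` with s_i in {0 empty, 1 P, 2 M}.  Only 1-D lattices are
supported (3^L states grows too fast for anything else to be useful).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .params import LatticeGeometry, ModelRates, validate
from .ib import SiteState

__all__ = [
    "enumerate_states",
    "build_generator",
    "state_distribution",
    "occupancy_marginals",
    "encode_state",
]


def enumerate_states(L: int) -> np.ndarray:
    """All 3^L configurations of a 1-D lattice, shape (3^L, L)."""
    n = 3**L
    states = np.empty((n, L), dtype=np.int8)
    for i in range(n):
        v = i
        for j in range(L):
            states[i, j] = v % 3
            v //= 3
    return states


def encode_state(sites: np.ndarray) -> int:
    return int(sum(int(s) * 3**j for j, s in enumerate(sites)))


def build_generator(
    rates: ModelRates,
    L: int,
    move_rule: str = "attempt",
    division_rule: str = "empty_only",
) -> np.ndarray:
    """Dense generator Q with Q[i, j] the rate of configuration i -> j.

    Event rules mirror the simulator exactly: per-cell rates, closed
    boundaries, failed events cause no transition (they leave the
    configuration unchanged and therefore contribute nothing to Q).
    Division rate ``alpha`` is split uniformly over the empty neighbours
    ("empty_only") or over all 2 directions with blocked attempts dropped
    ("attempt"); jumps are per-direction at rate nu/2 with blocked attempts
    dropped ("attempt") or nu split over the empty neighbours ("empty_only").
    """
    validate(rates, LatticeGeometry(d=1, L=L))
    states = enumerate_states(L)
    n = states.shape[0]
    Q = np.zeros((n, n))
    pow3 = 3 ** np.arange(L)

    def add(i: int, sites: np.ndarray, rate: float) -> None:
        j = int(np.dot(sites, pow3))
        Q[i, j] += rate

    for i in range(n):
        s = states[i]
        for site in range(L):
            state = s[site]
            if state == SiteState.EMPTY:
                continue
            neighbours = [k for k in (site - 1, site + 1) if 0 <= k < L]
            empties = [k for k in neighbours if s[k] == SiteState.EMPTY]
            if state == SiteState.P:
                if rates.mu > 0:
                    s2 = s.copy(); s2[site] = SiteState.EMPTY
                    add(i, s2, rates.mu)
                if rates.k_m > 0:
                    s2 = s.copy(); s2[site] = SiteState.M
                    add(i, s2, rates.k_m)
                if rates.alpha > 0 and empties:
                    if division_rule == "empty_only":
                        per_target = rates.alpha / len(empties)
                    else:
                        per_target = rates.alpha / 2.0
                    for k in empties:
                        s2 = s.copy(); s2[k] = SiteState.P
                        add(i, s2, per_target)
            else:  # M-cell
                if rates.mu > 0:
                    s2 = s.copy(); s2[site] = SiteState.EMPTY
                    add(i, s2, rates.mu)
                if rates.k_p > 0:
                    s2 = s.copy(); s2[site] = SiteState.P
                    add(i, s2, rates.k_p)
                if rates.nu > 0 and empties:
                    if move_rule == "attempt":
                        per_target = rates.nu / 2.0
                    else:
                        per_target = rates.nu / len(empties)
                    for k in empties:
                        s2 = s.copy()
                        s2[site] = SiteState.EMPTY
                        s2[k] = SiteState.M
                        add(i, s2, per_target)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def state_distribution(
    rates: ModelRates,
    L: int,
    t: float,
    initial: np.ndarray | int,
    move_rule: str = "attempt",
    division_rule: str = "empty_only",
) -> np.ndarray:
    """Exact distribution over the 3^L configurations at time t.

    ``initial`` is either a configuration index or a length-L site-state
    array (the distribution then starts as a point mass there)."""
    Q = build_generator(rates, L, move_rule=move_rule, division_rule=division_rule)
    n = Q.shape[0]
    p0 = np.zeros(n)
    if isinstance(initial, (int, np.integer)):
        p0[int(initial)] = 1.0
    else:
        p0[encode_state(np.asarray(initial))] = 1.0
    return p0 @ expm(Q * t)


def occupancy_marginals(distribution: np.ndarray, L: int) -> np.ndarray:
    """Per-site probability of being occupied (P or M), from a configuration
    distribution."""
    states = enumerate_states(L)
    occupied = states != SiteState.EMPTY
    return occupied.astype(float).T @ distribution
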