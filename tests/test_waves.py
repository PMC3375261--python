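"""Spectral travelling-wave analysis: roots, minimal speed, criticality."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import fsolve

from gogrow import (
    ModelRates,
    WaveSpeedQuery,
    characteristic_roots,
    critical_apoptosis,
    critical_exponent,
    dimension_rescale,
    fixed_points,
    minimal_wave_speed,
)


def test_quartic_factorises_when_one_switch_rate_vanishes():
    """With k_p * k_m = 0 the characteristic polynomial is the product of
    the two quadratic brackets; its roots are the union of theirs."""
    rates = ModelRates(alpha=1, nu=5, mu=0.05, k_p=2, k_m=0)
    c = 2.0
    res = characteristic_roots(c, rates)
    D_a, D_n = 0.5, 2.5
    A = rates.alpha - rates.mu - rates.k_m
    B = -(rates.mu + rates.k_p)
    expected = np.concatenate([
        np.roots([D_a, c, A]), np.roots([D_n, c, B]),
    ])
    assert np.allclose(
        np.sort_complex(res.roots), np.sort_complex(expected), atol=1e-12
    )


def test_fisher_boundary_case_has_double_root_at_sqrt2():
    """Proliferation only, no death: at c = sqrt(2) the p-bracket
    (lambda^2/2 + c lambda + 1) has the double real root -sqrt(2)."""
    rates = ModelRates(alpha=1, nu=1, mu=0, k_p=0, k_m=0)
    res = characteristic_roots(math.sqrt(2), rates)
    p_roots = sorted(r.real for r in res.roots if abs(r + math.sqrt(2)) < 1e-4)
    assert len(p_roots) == 2
    assert res.max_imag < 1e-4  # double root: limited numerical resolution


def test_zero_speed_spectrum_spirals_when_origin_unstable(baseline_rates):
    res = characteristic_roots(0.0, baseline_rates)
    assert res.max_imag > 0.1
    assert not res.converged


def test_large_speed_spectrum_is_real(baseline_rates):
    res = characteristic_roots(10.0, baseline_rates)
    assert res.converged


def test_minimal_speed_fisher_closed_form():
    for mu in (0.0, 0.01, 0.2):
        rates = ModelRates(alpha=1, nu=5, mu=mu, k_p=0, k_m=0)
        c = minimal_wave_speed(WaveSpeedQuery(rates=rates, resolution=1e-8))
        assert c == pytest.approx(2 * math.sqrt(0.5 * (1 - mu)), abs=1e-6)


def test_no_wave_beyond_critical_apoptosis():
    rates = ModelRates(alpha=1, nu=5, mu=0.0, k_p=1, k_m=2)
    mu_c = critical_apoptosis(1, 1, 2)
    assert minimal_wave_speed(rates.replace(mu=mu_c * 1.01)) == 0.0
    assert minimal_wave_speed(rates.replace(mu=mu_c * 0.99)) > 0.0


@settings(max_examples=20, deadline=None, derandomize=True)
@given(s=st.floats(0.2, 5.0))
def test_speed_scales_linearly_under_uniform_rate_scaling(s):
    """Scaling all five rates by s is a pure rescaling of time (lengths are
    unchanged), so c* scales by exactly s and the decay rates lambda are
    unchanged: the quartic factors as s^2 F(lambda; c/s)."""
    base = ModelRates(alpha=1, nu=4, mu=0.05, k_p=1, k_m=2)
    scaled = ModelRates(alpha=s, nu=4 * s, mu=0.05 * s, k_p=s, k_m=2 * s)
    c1 = minimal_wave_speed(WaveSpeedQuery(rates=base, resolution=1e-8))
    c2 = minimal_wave_speed(WaveSpeedQuery(rates=scaled, resolution=1e-8))
    assert c2 == pytest.approx(s * c1, rel=1e-5, abs=1e-6)


def test_fixed_points_zero_death_limit_and_root_finder_oracle():
    # mu -> 0: equilibrium set by the switching ratio alone
    fp = fixed_points(ModelRates(alpha=1, nu=5, mu=0.0, k_p=3, k_m=1))
    assert fp.invaded == pytest.approx((0.75, 0.25), abs=1e-12)
    # k_m = 0, mu = 0: all-P invaded state
    fp = fixed_points(ModelRates(alpha=1, nu=5, mu=0.0, k_p=0, k_m=0))
    assert fp.invaded == pytest.approx((1.0, 0.0))
    # generic: agrees with a numeric root of the homogeneous kinetics
    rates = ModelRates(alpha=1, nu=2, mu=0.1, k_p=1, k_m=1)
    fp = fixed_points(rates)

    def kinetics(v):
        p, m = v
        return [
            rates.alpha * (1 - p - m) * p - (rates.mu + rates.k_m) * p
            + rates.k_p * m,
            -(rates.mu + rates.k_p) * m + rates.k_m * p,
        ]

    root = fsolve(kinetics, [0.5, 0.3], full_output=False, xtol=1e-13)
    assert fp.invaded == pytest.approx(tuple(root), abs=1e-10)


def test_fixed_point_extinct_when_mu_exceeds_mu_c():
    mu_c = critical_apoptosis(1, 1, 2)
    fp = fixed_points(ModelRates(alpha=1, nu=5, mu=mu_c * 1.05, k_p=1, k_m=2))
    assert fp.invaded is None


def test_critical_apoptosis_limits_and_speed_crosscheck():
    assert critical_apoptosis(1.0, 5.0, 0.0) == pytest.approx(1.0)
    assert critical_apoptosis(0.7, 2.0, 0.0) == pytest.approx(0.7)
    # k_p -> infinity with k_m fixed: switching back is instantaneous
    assert critical_apoptosis(1.0, 1e8, 2.0) == pytest.approx(1.0, rel=1e-6)
    # mu_c is where c*(mu) vanishes
    mu_c = critical_apoptosis(1.0, 1.0, 2.0)
    rates = ModelRates(alpha=1, nu=5, mu=0, k_p=1, k_m=2)
    assert minimal_wave_speed(rates.replace(mu=mu_c + 1e-4)) == 0.0
    assert 0 < minimal_wave_speed(rates.replace(mu=mu_c - 1e-4)) < 0.1


def test_critical_exponent_half_for_decoupled_fisher():
    """k_m = 0 reduces to c = 2 sqrt(D_a (alpha - mu)): exact square-root
    vanishing at mu_c = alpha."""
    res = critical_exponent(ModelRates(alpha=1, nu=5, mu=0, k_p=1, k_m=0))
    assert res.mu_c == pytest.approx(1.0)
    assert res.beta == pytest.approx(0.5, abs=5e-3)


def test_speed_monotone_in_alpha_nu_and_antitone_in_mu():
    grid = {
        "alpha": [0.5, 1.0, 2.0],
        "nu": [1.0, 4.0, 10.0],
        "mu": [0.0, 0.1, 0.3],
    }
    base = ModelRates(alpha=1, nu=4, mu=0.05, k_p=1, k_m=2)
    for param, values in grid.items():
        speeds = [
            minimal_wave_speed(base.replace(**{param: v})) for v in values
        ]
        diffs = np.diff(speeds)
        if param == "mu":
            assert np.all(diffs <= 1e-9)
        else:
            assert np.all(diffs >= -1e-9)


def test_speed_has_interior_maximum_in_k_m():
    """At fixed k_p the speed first rises (migration frees space) then falls
    (too few cells proliferate): an interior maximum in k_m."""
    k_ms = np.logspace(-2, 1.3, 12)
    rates = ModelRates(alpha=1, nu=5, mu=0.01, k_p=1, k_m=0)
    speeds = np.array([
        minimal_wave_speed(rates.replace(k_m=float(k))) for k in k_ms
    ])
    i = int(np.argmax(speeds))
    assert 0 < i < len(k_ms) - 1
    assert speeds[i] > speeds[0] and speeds[i] > speeds[-1]


def test_dimension_rescale_identity_and_per_axis_values():
    rates = ModelRates(alpha=1, nu=5, mu=0.01, k_p=1, k_m=1)
    q1 = dimension_rescale(rates, 1)
    assert q1.effective_dimension == 1 and q1.rates == rates
    from gogrow import diffusion_constants
    assert diffusion_constants(rates, 2).D_nu == pytest.approx(1.25)
    # rescaling reduces the predicted speed (less diffusion along the normal)
    c1 = minimal_wave_speed(dimension_rescale(rates, 1))
    c2 = minimal_wave_speed(dimension_rescale(rates, 2))
    assert c2 < c1
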