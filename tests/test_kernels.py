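"""Disorder-kernel unit and property tests.

The Feller kernel Upsilon(t; lam) is the Laplace transform of the
integrated diffusivity; these tests pin its normalization, monotonicity,
derivative, conditional form, closed-form time integral and the limiting
regimes, against independent oracles (finite differences, quadrature,
closed forms).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import erfcx, gammaln, roots_genlaguerre

from hetfpt import (
    DisorderParams,
    FellerKernel,
    HomogeneousKernel,
    MittagLefflerKernel,
    feller_upsilon,
    feller_upsilon_prime,
    mittag_leffler,
    stationary_moment,
    upsilon_given_D0,
    upsilon_time_integral,
)

PARAM_GRID = [
    DisorderParams(1.0, 1.0, 2.0),     # nu = 1/2 (strong disorder)
    DisorderParams(1.0, 0.5, 1.0),     # nu = 4
    DisorderParams(2.0, 1.5, 0.3),     # nu ~ 2.96
    DisorderParams(0.5, 2.0, 5.0),     # nu = 0.025 (very strong)
]


@pytest.mark.parametrize("params", PARAM_GRID)
def test_kernel_normalization_and_bounds(params):
    """Upsilon(0; lam) = 1 and Upsilon(t; 0) = 1 exactly; values in (0, 1]."""
    lam = np.array([0.0, 0.3, 7.0, 500.0])
    assert np.all(feller_upsilon(params, 0.0, lam) == 1.0)
    t = np.array([0.0, 0.01, 1.0, 50.0])
    assert np.all(feller_upsilon(params, t, 0.0) == 1.0)
    vals = feller_upsilon(params, t[:, None], lam[None, :])
    logs = FellerKernel(params).log_upsilon(t[:, None], lam[None, :])
    assert np.all(vals >= 0) and np.all(vals <= 1.0)
    assert np.all(np.isfinite(logs))  # log-space contract: never overflows
    assert np.all(vals[logs > -700] > 0)


@pytest.mark.parametrize("params", PARAM_GRID)
def test_kernel_monotone_in_time(params):
    t = np.logspace(-3, 2, 200) * params.tau
    for lam in (0.1, 1.0, 30.0):
        logv = FellerKernel(params).log_upsilon(t, lam)
        assert np.all(np.diff(logv) < 0)


def test_homogeneous_recovery_point(near_hom_params):
    """sigma -> 0: Upsilon -> exp(-dbar t lam) (here to 1e-6 at sigma=1e-8)."""
    got = feller_upsilon(near_hom_params, 1.0, 1.0)
    assert got == pytest.approx(math.exp(-1.0), rel=1e-6)


@pytest.mark.parametrize("mode", ["sigma", "tau"])
def test_homogeneous_recovery_uniform(mode):
    """sup_t |Upsilon - exp(-dbar t lam)| -> 0 as sigma -> 0 or tau -> 0."""
    lam, tau0 = 2.0, 1.0
    t = np.linspace(1e-3, 10.0, 300) * tau0
    sups = []
    for eps in (0.3, 0.03, 0.003):
        p = (DisorderParams(1.0, eps, tau0) if mode == "sigma"
             else DisorderParams(1.0, 1.0, eps * tau0))
        sups.append(np.max(np.abs(feller_upsilon(p, t, lam) - np.exp(-t * lam))))
    assert sups[0] > sups[1] > sups[2]
    assert sups[2] < 1e-4


def test_upsilon_prime_matches_finite_difference():
    """Upsilon' agrees with a central difference of Upsilon (rel 1e-5)."""
    cases = [
        (DisorderParams(1.0, 1.0, 2.0), 1.0, 4.0),
        (DisorderParams(1.0, 1.0, 2.0), 0.2, 1.0),
        (DisorderParams(1.0, 0.5, 1.0), 3.0, 0.7),
        (DisorderParams(0.5, 2.0, 5.0), 0.5, 10.0),
    ]
    for params, t, lam in cases:
        h = 1e-5 * t
        fd = (feller_upsilon(params, t + h, lam) - feller_upsilon(params, t - h, lam)) / (2 * h)
        assert feller_upsilon_prime(params, t, lam) == pytest.approx(fd, rel=1e-5)


def test_upsilon_prime_sign_and_hom_limit(near_hom_params):
    p = DisorderParams(1.0, 1.0, 2.0)
    assert feller_upsilon_prime(p, 1.0, 0.0) == 0.0
    assert feller_upsilon_prime(p, 1.0, 3.0) < 0.0
    got = feller_upsilon_prime(near_hom_params, 1.0, 1.0)
    assert got == pytest.approx(-math.exp(-1.0), rel=1e-6)


def test_domain_errors():
    p = DisorderParams(1.0, 1.0, 2.0)
    with pytest.raises(ValueError):
        feller_upsilon(p, -1.0, 1.0)
    with pytest.raises(ValueError):
        feller_upsilon(p, 1.0, -1.0)
    with pytest.raises(ValueError):
        upsilon_given_D0(p, 1.0, 1.0, D0=0.0)
    with pytest.raises(ValueError):
        upsilon_time_integral(p, 0.0)


# ----------------------------------------------------------------------
# Conditional kernel
# ----------------------------------------------------------------------

def test_conditional_kernel_trivial_values():
    p = DisorderParams(1.0, 1.0, 1.0)
    assert upsilon_given_D0(p, 0.0, 5.0, 0.7) == pytest.approx(1.0, abs=1e-14)
    assert upsilon_given_D0(p, 3.0, 0.0, 0.7) == pytest.approx(1.0, abs=1e-14)


def test_conditional_kernel_stationary_average():
    """Averaging Upsilon(t; lam | D0) over the stationary Gamma law of D0
    reproduces the unconditional kernel (Gauss-Laguerre oracle, rel 1e-6)."""
    p = DisorderParams(1.0, 1.0, 1.0)  # nu = 1
    t, lam = 2.0, 3.0
    nu = p.nu
    x, w = roots_genlaguerre(300, nu - 1.0)
    D0 = p.dbar * x / nu
    avg = np.sum(w * upsilon_given_D0(p, t, lam, D0)) / math.exp(gammaln(nu))
    assert avg == pytest.approx(float(feller_upsilon(p, t, lam)), rel=1e-6)


def test_conditional_kernel_sigma0_is_relaxation_path():
    """For sigma -> 0 the conditional kernel is exp(-lam * integral of the
    deterministic relaxation D(t) = dbar + (D0-dbar) e^{-t/tau})."""
    p = DisorderParams(1.0, 1e-7, 2.0)
    D0, t, lam = 3.0, 1.5, 0.8
    T = p.dbar * t + (D0 - p.dbar) * p.tau * (1 - math.exp(-t / p.tau))
    assert upsilon_given_D0(p, t, lam, D0) == pytest.approx(math.exp(-lam * T), rel=1e-5)


# ----------------------------------------------------------------------
# Time integral (mean-FPT building block)
# ----------------------------------------------------------------------

def test_time_integral_hom_limit():
    assert upsilon_time_integral(DisorderParams(1.0, 0.0, 1.0), 2.0) == pytest.approx(0.5)
    assert upsilon_time_integral(DisorderParams(1.0, 1e-9, 1.0), 2.0) == pytest.approx(0.5, rel=1e-8)


def test_time_integral_vs_quadrature():
    """Closed Gauss-2F1 form vs adaptive quadrature of the kernel, rel 1e-8."""
    p = DisorderParams(1.0, 1.0, 2.0)
    closed = upsilon_time_integral(p, 1.0)
    direct, _ = quad(lambda s: feller_upsilon(p, s, 1.0), 0.0, 200 * p.tau, limit=500)
    assert closed == pytest.approx(direct, rel=1e-8)


def test_time_integral_random_draws_vs_quadrature():
    """Closed form equals direct quadrature over random parameter draws."""
    rng = np.random.default_rng(5)
    for _ in range(10):
        p = DisorderParams(rng.uniform(0.3, 2.0), rng.uniform(0.1, 2.0), rng.uniform(0.2, 3.0))
        lam = 10 ** rng.uniform(-1, 1.5)
        closed = upsilon_time_integral(p, lam)
        spike = 25.0 / (p.dbar * lam)
        v1, _ = quad(lambda s: feller_upsilon(p, s, lam), 0.0, spike, limit=400)
        v2, _ = quad(lambda s: feller_upsilon(p, s, lam), spike, spike + 300 * p.tau, limit=400)
        assert closed == pytest.approx(v1 + v2, rel=1e-8)


def test_time_integral_disorder_slows_kinetics():
    """int Upsilon dt >= 1/(dbar lam): dynamic disorder slows mean decay."""
    rng = np.random.default_rng(11)
    for _ in range(40):
        p = DisorderParams(rng.uniform(0.2, 3.0), rng.uniform(0.05, 3.0), rng.uniform(0.05, 3.0))
        lam = 10 ** rng.uniform(-2, 3)
        assert upsilon_time_integral(p, lam) >= 1.0 / (p.dbar * lam) * (1 - 1e-12)


# ----------------------------------------------------------------------
# Stationary moments
# ----------------------------------------------------------------------

def test_stationary_moments():
    p_half = DisorderParams(1.0, 1.0, 2.0)  # nu = 1/2
    p2 = DisorderParams(1.0, np.sqrt(0.5), 1.0)  # nu = 2
    assert stationary_moment(p_half, 1.0) == pytest.approx(1.0)
    assert stationary_moment(p2, 2.0) - 1.0 == pytest.approx(1.0 / p2.nu)
    assert stationary_moment(p2, 2.0) == pytest.approx(1.5)  # Gamma(4)/(Gamma(2) 4)
    assert stationary_moment(p_half, -1.0) == math.inf  # k <= -nu diverges
    assert stationary_moment(DisorderParams(2.0, 0.0, 1.0), 3.0) == pytest.approx(8.0)


# ----------------------------------------------------------------------
# Mittag-Leffler CTRW kernel
# ----------------------------------------------------------------------

def test_mittag_leffler_alpha_to_one_probe():
    assert mittag_leffler(-1.0, 0.999) == pytest.approx(math.exp(-1.0), abs=1e-2)


def test_mittag_leffler_half_closed_form():
    """E_{1/2}(-x) = exp(x^2) erfc(x) = erfcx(x)."""
    for x in (0.3, 1.0, 4.0, 20.0, 200.0):
        assert mittag_leffler(-x, 0.5) == pytest.approx(float(erfcx(x)), rel=1e-8)


def test_mittag_leffler_series_vs_integral_representation():
    """Taylor summation vs the spectral integral representation, rel 1e-8."""
    alpha, x = 0.5, 1.0

    def K(r):
        return (r ** (alpha - 1) * math.sin(alpha * math.pi) / math.pi
                / (r ** (2 * alpha) + 2 * r**alpha * math.cos(alpha * math.pi) + 1))

    t = x ** (1 / alpha)
    ref, _ = quad(lambda r: math.exp(-r * t) * K(r), 0, np.inf, limit=400)
    assert mittag_leffler(-x, alpha) == pytest.approx(ref, rel=1e-8)


def test_mittag_leffler_kernel_contract():
    k = MittagLefflerKernel(0.6, 1.0)
    assert np.all(k.upsilon(0.0, np.array([0.0, 1.0, 10.0])) == 1.0)
    assert np.all(k.upsilon(np.array([0.5, 2.0]), 0.0) == 1.0)
    t = np.logspace(-2, 1, 40)
    v = k.upsilon(t, 1.0)
    assert np.all(np.diff(v) < 0)
    # derivative consistency with finite differences
    h = 1e-6
    fd = (k.upsilon(1.0 + h, 2.0) - k.upsilon(1.0 - h, 2.0)) / (2 * h)
    assert k.upsilon_prime(1.0, 2.0) == pytest.approx(float(fd), rel=1e-5)
    with pytest.raises(ValueError):
        MittagLefflerKernel(1.2, 1.0)
    with pytest.raises(ValueError):
        mittag_leffler(-1.0, 0.0)


# ----------------------------------------------------------------------
# Limiting regimes in (mu, 1/nu)
# ----------------------------------------------------------------------

def test_limit_weak_disorder_fixed_mu():
    """1/nu -> 0 at fixed mu: Upsilon -> hom with O(1/nu) error."""
    lam, t = 5.0, 0.3
    hom = math.exp(-t * lam)
    devs = []
    for nu in (4.0, 16.0, 64.0):
        p = DisorderParams.from_dimensionless(1.0, 1.0, mu=1.0, nu=nu)
        devs.append(abs(float(feller_upsilon(p, t, lam)) - hom))
    assert devs[0] > devs[1] > devs[2]
    assert devs[1] / devs[2] == pytest.approx(4.0, rel=0.3)  # O(1/nu) scaling


def test_limit_small_scale_fixed_nu():
    """mu -> 0 at fixed nu: pointwise hom convergence with O(mu^2) error,
    but the deviation grows with lam at fixed mu (short times never
    homogenize)."""
    lam, t = 5.0, 0.3
    hom = math.exp(-t * lam)
    devs = []
    for mu in (0.08, 0.04, 0.02):
        p = DisorderParams.from_dimensionless(1.0, 1.0, mu=mu, nu=2.0)
        devs.append(abs(float(feller_upsilon(p, t, lam)) - hom))
    assert devs[0] > devs[1] > devs[2]
    assert devs[1] / devs[2] == pytest.approx(4.0, rel=0.3)  # O(mu^2) scaling
    # at fixed mu the deviation grows along the eigenvalue ladder
    p = DisorderParams.from_dimensionless(1.0, 1.0, mu=0.05, nu=2.0)
    lams = np.array([1.0, 10.0, 100.0, 1000.0])
    rel_dev = np.abs(np.log(feller_upsilon(p, 0.01, lams)) - (-0.01 * lams)) / (0.01 * lams)
    assert np.all(np.diff(rel_dev) > 0)


def test_dimensionless_roundtrip():
    p = DisorderParams.from_dimensionless(2.0, 3.0, mu=0.7, inv_nu=1.5)
    assert p.mu(3.0) == pytest.approx(0.7)
    assert p.inv_nu == pytest.approx(1.5)
    assert p.dbar == 2.0


# ----------------------------------------------------------------------
# Property tests (hypothesis, derandomized)
# ----------------------------------------------------------------------

@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    dbar=st.floats(0.1, 5.0),
    sigma=st.floats(0.01, 3.0),
    tau=st.floats(0.05, 5.0),
    t=st.floats(0.0, 50.0),
    lam=st.floats(0.0, 100.0),
)
def test_kernel_bounds_property(dbar, sigma, tau, t, lam):
    p = DisorderParams(dbar, sigma, tau)
    v = float(feller_upsilon(p, t, lam))
    assert 0.0 <= v <= 1.0
    assert np.isfinite(float(FellerKernel(p).log_upsilon(t, lam)))
    assert float(feller_upsilon_prime(p, t, lam)) <= 0.0
    if t == 0.0 or lam == 0.0:
        assert v == 1.0


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    sigma=st.floats(0.05, 2.0),
    tau=st.floats(0.1, 3.0),
    lam=st.floats(0.01, 50.0),
    D0=st.floats(0.05, 5.0),
)
def test_conditional_kernel_bounds_property(sigma, tau, lam, D0):
    p = DisorderParams(1.0, sigma, tau)
    v = float(upsilon_given_D0(p, 1.3, lam, D0))
    assert 0.0 < v <= 1.0


def test_kernel_objects_share_contract(fig5_params, hom_params):
    t = np.array([0.3, 1.7])
    lam = 2.0
    fk = FellerKernel(fig5_params)
    assert np.allclose(fk.upsilon(t, lam), feller_upsilon(fig5_params, t, lam))
    hk = HomogeneousKernel(1.0)
    assert np.allclose(hk.upsilon(t, lam), np.exp(-t * lam))
    assert np.allclose(
        hk.upsilon_prime_over_lam(t, 0.0), -1.0 * np.exp(-0.0 * t)
    )
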