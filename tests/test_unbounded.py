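"""Half-line / half-space and ball-exterior tests.

Oracles: the classical Gaussian/erf closed forms of homogeneous
diffusion, the Smoluchowski steady rate 4 pi c0 dbar R, conservation
identities (normalization, escape probability, defining relations of the
flux) and the ordering of the exact flux between its homogeneous and
short-time-superstatistical envelopes.
"""

import math

import numpy as np
import pytest
from scipy.integrate import simpson
from scipy.special import erf

from hetfpt import DisorderParams, HomogeneousKernel
from hetfpt.unbounded import (
    BallExteriorProblem,
    HalfLineProblem,
    exterior_flux,
    exterior_fpt_density,
    exterior_survival,
    halfline_flux,
    halfline_fpt_density,
    halfline_propagator,
    halfline_survival,
    multiparticle_survival,
    naive_flux_exterior,
    smoluchowski_prefactor,
)

T_MID = np.logspace(-2, 2, 20)


@pytest.fixture(scope="module")
def hl_hom():
    return HalfLineProblem(1.0, DisorderParams(1.0, 1e-8, 1.0))


@pytest.fixture(scope="module")
def hl_fig5():
    return HalfLineProblem(1.0, DisorderParams(1.0, 1.0, 2.0))


@pytest.fixture(scope="module")
def ext_hom():
    return BallExteriorProblem(1.0, 1.2, DisorderParams(1.0, 1e-8, 1.0), c0=1.0)


@pytest.fixture(scope="module")
def ext_fig():
    return BallExteriorProblem(1.0, 1.2, DisorderParams(1.0, 1.0, 2.0), c0=1.0)


# ----------------------------------------------------------------------
# Half-line
# ----------------------------------------------------------------------

def test_halfline_hom_density(hl_hom):
    ref = 1.0 / np.sqrt(4 * np.pi * T_MID**3) * np.exp(-1.0 / (4 * T_MID))
    got = halfline_fpt_density(hl_hom, T_MID).density
    assert np.allclose(got, ref, rtol=1e-6)


def test_halfline_hom_survival(hl_hom):
    ref = erf(1.0 / np.sqrt(4 * T_MID))
    got = halfline_survival(hl_hom, T_MID).survival
    assert np.allclose(got, ref, rtol=1e-6)
    assert halfline_survival(hl_hom, np.array([0.0])).survival[0] == 1.0


def test_halfline_hom_flux(hl_hom):
    ref = np.sqrt(1.0 / (np.pi * T_MID))
    got = halfline_flux(hl_hom, 1.0, T_MID).metadata["J"]
    assert np.allclose(got, ref, rtol=1e-6)
    # t = 0 is the +inf sentinel (integrable singularity)
    assert halfline_flux(hl_hom, 1.0, np.array([0.0])).metadata["J"][0] == np.inf


def test_halfline_density_normalizes(hl_fig5):
    """int rho dt + surviving mass = 1 (recurrent domain)."""
    t = np.logspace(-4, 5, 2000)
    dens = halfline_fpt_density(hl_fig5, t).density
    S_end = halfline_survival(hl_fig5, t[-1:]).survival[0]
    assert simpson(dens, x=t) + S_end == pytest.approx(1.0, abs=1e-5)


def test_halfline_longtime_is_brownian(hl_fig5):
    """rho(t) / [x0/sqrt(4 pi dbar t^3)] -> 1 by t = 1e3 tau (within 2%):
    unbounded exploration averages out the disorder at long times."""
    t = 1e3 * hl_fig5.params.tau
    got = halfline_fpt_density(hl_fig5, np.array([t])).density[0]
    ref = 1.0 / math.sqrt(4 * math.pi * t**3)
    assert got / ref == pytest.approx(1.0, abs=0.02)


def test_halfline_density_is_minus_dS_dt(hl_fig5):
    h = 1e-5
    for ti in (0.1, 1.0, 10.0):
        S = halfline_survival(hl_fig5, np.array([ti - h, ti + h])).survival
        fd = -(S[1] - S[0]) / (2 * h)
        d = halfline_fpt_density(hl_fig5, np.array([ti])).density[0]
        assert d == pytest.approx(fd, rel=1e-4)


def test_halfline_propagator(hl_hom, hl_fig5):
    # absorbing endpoint
    assert halfline_propagator(hl_fig5, 0.0, 1.0) == 0.0
    # hom: image-method Gaussian difference
    x = np.array([0.5, 1.0, 2.5])
    t = 0.7
    got = halfline_propagator(hl_hom, x, t)
    g = lambda y: np.exp(-(y**2) / (4 * t)) / math.sqrt(4 * math.pi * t)
    ref = g(x - 1.0) - g(x + 1.0)
    assert np.allclose(got, ref, rtol=1e-6)
    # spatial integral equals the survival probability
    xg = np.linspace(0.0, 30.0, 1200)
    P = halfline_propagator(hl_fig5, xg, 2.0)
    S = halfline_survival(hl_fig5, np.array([2.0])).survival[0]
    assert simpson(P, x=xg) == pytest.approx(S, rel=1e-4)


def test_halfline_flux_defining_relation(hl_fig5):
    """J(t) = int dx0 c0 rho(t|x0): the flux superimposes single-particle
    arrival densities (coarse x0 quadrature)."""
    t = 1.0
    x0g = np.linspace(1e-3, 25.0, 180)
    dens = np.array([
        halfline_fpt_density(HalfLineProblem(x0, hl_fig5.params), np.array([t])).density[0]
        for x0 in x0g
    ])
    J_quad = np.trapezoid(dens, x0g)
    J = halfline_flux(hl_fig5, 1.0, np.array([t])).metadata["J"][0]
    assert J_quad == pytest.approx(J, rel=1e-2)


def test_halfline_validation(hl_fig5):
    with pytest.raises(ValueError):
        HalfLineProblem(0.0, hl_fig5.params)
    with pytest.raises(ValueError):
        halfline_fpt_density(hl_fig5, np.array([0.0, 1.0]))


# ----------------------------------------------------------------------
# Exterior of a reactive ball
# ----------------------------------------------------------------------

def test_exterior_hom_closed_forms(ext_hom):
    R, r0 = 1.0, 1.2
    a = r0 - R
    S_ref = a / r0 + (R / r0) * erf(a / np.sqrt(4 * T_MID))
    assert np.allclose(exterior_survival(ext_hom, T_MID).survival, S_ref, rtol=1e-6)
    rho_ref = (R / r0) * a * np.exp(-(a**2) / (4 * T_MID)) / np.sqrt(4 * np.pi * T_MID**3)
    assert np.allclose(exterior_fpt_density(ext_hom, T_MID).density, rho_ref, rtol=1e-6)
    J_ref = 4 * np.pi * (1.0 + 1.0 / np.sqrt(np.pi * T_MID))
    assert np.allclose(exterior_flux(ext_hom, T_MID).metadata["J"], J_ref, rtol=1e-6)


def test_exterior_initial_and_escape(ext_fig):
    assert exterior_survival(ext_fig, np.array([0.0])).survival[0] == 1.0
    # S(infinity) = (r0 - R)/r0: the escape probability (the approach is
    # ~ (R/r0) a/sqrt(pi dbar t), so 1e-6 needs t ~ 1e10)
    S_late = exterior_survival(ext_fig, np.array([1e10])).survival[0]
    assert S_late == pytest.approx(0.2 / 1.2, abs=1e-6)


def test_exterior_density_mass(ext_fig):
    """Total reaction probability R/r0; the rest escapes to infinity."""
    t = np.logspace(-4, 6, 1500)
    dens = exterior_fpt_density(ext_fig, t).density
    S_end = exterior_survival(ext_fig, t[-1:]).survival[0]
    mass = simpson(dens, x=t) + (S_end - 0.2 / 1.2)
    assert mass == pytest.approx(1.0 / 1.2, abs=1e-5)


def test_exterior_flux_longtime_smoluchowski(ext_fig):
    """J(t) decreases monotonically to the Smoluchowski rate 4 pi c0 dbar R."""
    t = np.logspace(-2, 4, 30)
    J = exterior_flux(ext_fig, t).metadata["J"]
    JS = 4 * np.pi
    assert np.all(np.diff(J) < 0)
    assert np.all(J > JS)
    assert J[-1] == pytest.approx(JS, rel=1e-2)


def test_smoluchowski_prefactor_values():
    """Gamma(nu+1/2)/(sqrt(nu) Gamma(nu)): 0.80 at nu = 1/2 (exactly
    sqrt(2/pi)), sqrt(pi)/2 at nu = 1, and -> 1 as nu -> infinity."""
    assert smoluchowski_prefactor(0.5) == pytest.approx(math.sqrt(2 / math.pi), rel=1e-12)
    assert round(smoluchowski_prefactor(0.5), 2) == 0.80
    assert smoluchowski_prefactor(1.0) == pytest.approx(math.sqrt(math.pi) / 2, rel=1e-12)
    assert smoluchowski_prefactor(1e6) == pytest.approx(1.0, abs=1e-6)
    with pytest.raises(ValueError):
        smoluchowski_prefactor(0.0)


def test_smoluchowski_prefactor_monotone():
    nu = np.logspace(-3, 6, 200)
    vals = np.array([smoluchowski_prefactor(v) for v in nu])
    assert np.all(np.diff(vals) > 0)
    assert np.all(vals <= 1.0)


def test_exterior_flux_shorttime_prefactor(ext_fig):
    """As t -> 0 the divergent term of J(t) carries the reduced prefactor
    Gamma(nu+1/2)/(sqrt(nu) Gamma(nu)) instead of 1."""
    p = ext_fig.params  # nu = 1/2
    pref = smoluchowski_prefactor(p.nu)
    t = np.array([1e-7])
    J = exterior_flux(ext_fig, t).metadata["J"][0]
    JS = 4 * np.pi
    div = (J / JS - 1.0) * math.sqrt(math.pi * t[0])
    assert div == pytest.approx(pref, rel=5e-3)


def test_naive_flux_pitfall(ext_hom, ext_fig):
    """The concentration-gradient flux equals the exact one only for
    homogeneous diffusion; under disorder it differs at finite times
    while sharing the steady limit."""
    t = np.logspace(-2, 2, 15)
    J_hom = exterior_flux(ext_hom, t).metadata["J"]
    J_app_hom = naive_flux_exterior(ext_hom, t).metadata["J"]
    assert np.allclose(J_hom, J_app_hom, rtol=1e-6)
    J = exterior_flux(ext_fig, t).metadata["J"]
    J_app = naive_flux_exterior(ext_fig, t).metadata["J"]
    assert np.max(np.abs(J - J_app) / J) > 0.01
    JS = 4 * np.pi
    assert naive_flux_exterior(ext_fig, np.array([1e6])).metadata["J"][0] == pytest.approx(JS, rel=1e-2)


def test_flux_between_envelopes():
    """On the (nu in {2, 0.5}) x (mu in [0.1, 10]) grid every J(t)/J_S
    curve lies between the homogeneous flux (upper envelope) and the
    short-time superstatistical bound (lower envelope).  The flux is not
    monotone in mu, and the homogeneous curve is only approximately the
    upper bound: a 2% allowance covers the small intermediate-time
    excursions above it; the superstatistical lower bound is strict."""
    t = np.logspace(-3, 2, 12)
    for nu in (2.0, 0.5):
        pref = smoluchowski_prefactor(nu)
        upper = 1.0 + 1.0 / np.sqrt(np.pi * t)
        lower = 1.0 + pref / np.sqrt(np.pi * t)
        for mu in (0.1, 1.0, 10.0):
            p = DisorderParams.from_dimensionless(1.0, 1.0, mu=mu, nu=nu)
            prob = BallExteriorProblem(1.0, 1.2, p, c0=1.0)
            JJS = exterior_flux(prob, t).metadata["J_over_JS"]
            assert np.all(JJS <= upper * 1.02)
            assert np.all(JJS >= lower * (1 - 1e-6))


# ----------------------------------------------------------------------
# Collective search
# ----------------------------------------------------------------------

def test_multiparticle_thermodynamic_dual_forms(ext_fig):
    """The flux-integral and kernel-integral expressions for S_inf agree."""
    t = np.array([0.0, 0.5, 2.0, 10.0])
    a = multiparticle_survival(ext_fig, "thermodynamic", 0.05, t, form="flux")
    b = multiparticle_survival(ext_fig, "thermodynamic", 0.05, t, form="kernel")
    assert np.max(np.abs(a - b)) < 1e-6
    both = multiparticle_survival(ext_fig, "thermodynamic", 0.05, t, form="both")
    assert np.allclose(both, a, atol=1e-6)


def test_multiparticle_thermodynamic_hom_closed_form(ext_hom):
    """Homogeneous limit: -ln S_inf = 4 pi c0 R dbar (t + 2R sqrt(t/(pi dbar)))."""
    c0, t = 0.05, 0.5
    got = multiparticle_survival(ext_hom, "thermodynamic", c0, np.array([t]), form="both")[0]
    ref = math.exp(-4 * math.pi * c0 * (t + 2 * math.sqrt(t / math.pi)))
    assert got == pytest.approx(ref, rel=1e-6)


def test_multiparticle_monotone_in_concentration(ext_fig):
    t = np.array([1.0])
    vals = [multiparticle_survival(ext_fig, "thermodynamic", c0, t, form="kernel")[0]
            for c0 in (0.01, 0.05, 0.2)]
    assert vals[0] > vals[1] > vals[2]


def test_multiparticle_finite_N(ext_fig):
    """S_N = (shell-average of S)^N; N = 1 is the plain volume average."""
    t = np.array([0.5])
    S1 = multiparticle_survival(ext_fig, 1, 0.05, t, R_max=5.0)[0]
    S4 = multiparticle_survival(ext_fig, 4, 0.05, t, R_max=5.0)[0]
    assert 0.0 < S1 < 1.0
    assert S4 == pytest.approx(S1**4, rel=1e-10)
    with pytest.raises(ValueError):
        multiparticle_survival(ext_fig, 2, 0.05, t)  # missing R_max
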