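"""Subordination: heterogeneous FPTs as first crossings of random barriers.

Heterogeneous diffusion is homogeneous (unit-diffusivity) Brownian motion
run at the random internal time T_t = int_0^t D_s ds.  A first-passage
event therefore decomposes into two independent layers:

1. thermal randomness: the duration T_hom of the Brownian path to the
   target, with the classical unit-diffusivity FPT density of the
   geometry;
2. disorder randomness: the moment t at which the nondecreasing process
   T_t first crosses the barrier T_hom.

Sampling both layers gives an exact Monte-Carlo simulator of
heterogeneous first-passage times that never touches the spectral
formulas -- the package-wide cross-validation oracle.  The same picture
gives analytic access to the first-crossing density q(t;T) through a
numerical Laplace inversion of -Upsilon'(t;lambda)/lambda, and to the FPT
density by averaging q over the barrier distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .feller import feller_step, sample_stationary_D
from .kernels import (
    _feller_core,
    _feller_prime_factor,
    feller_log_upsilon,
)
from .params import DisorderParams

__all__ = [
    "HalfLineGeometry",
    "BallInteriorGeometry",
    "BallExteriorGeometry",
    "MCEnsemble",
    "hom_ball_survival",
    "sample_hom_internal_fpt",
    "first_crossing_times",
    "sample_het_fpt",
    "q_first_crossing_density",
    "integrated_diffusivity_density",
    "subordination_density",
]


# ----------------------------------------------------------------------
# Geometries (for the homogeneous internal-time layer)
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class HalfLineGeometry:
    """Absorbing endpoint at 0, start at x0 > 0."""

    x0: float

    def __post_init__(self):
        if not self.x0 > 0:
            raise ValueError("x0 must be > 0")


@dataclass(frozen=True)
class BallInteriorGeometry:
    """Reactive sphere of radius R, start at the center."""

    R: float

    def __post_init__(self):
        if not self.R > 0:
            raise ValueError("R must be > 0")


@dataclass(frozen=True)
class BallExteriorGeometry:
    """Reactive sphere of radius R, start at radius r0 > R (may escape)."""

    R: float
    r0: float

    def __post_init__(self):
        if not self.r0 > self.R > 0:
            raise ValueError("need r0 > R > 0")


@dataclass
class MCEnsemble:
    """Simulated heterogeneous FPT samples with censoring flags.

    ``censored`` marks either escape to infinity (exterior geometry) or a
    crossing beyond the simulation horizon; the corresponding ``samples``
    entries are +inf.
    """

    samples: np.ndarray
    censored: np.ndarray
    params: DisorderParams
    geometry: object
    seed: object = None

    @property
    def hits(self) -> np.ndarray:
        return self.samples[~self.censored]

    def to_tsv(self, path) -> None:
        p = self.params
        with open(path, "w") as fh:
            fh.write(f"# geometry={self.geometry} dbar={p.dbar} sigma={p.sigma} "
                     f"tau={p.tau} seed={self.seed}\n")
            fh.write("sample_id\tfpt\tcensored\n")
            for i, (s, c) in enumerate(zip(self.samples, self.censored)):
                fh.write(f"{i}\t{s:.10g}\t{int(c)}\n")


# ----------------------------------------------------------------------
# Homogeneous internal-time FPT draws (unit diffusivity)
# ----------------------------------------------------------------------

def _levy_hitting_time(dist: float, n: int, rng: np.random.Generator):
    """T = dist^2 / (2 Z^2), Z standard normal: the unit-diffusivity
    hitting time of a point at distance dist on the half-line (Levy law,
    density dist * exp(-dist^2/(4T)) / sqrt(4 pi T^3))."""
    Z = rng.standard_normal(n)
    return dist**2 / (2.0 * Z**2)


def hom_ball_survival(u):
    """Unit-diffusivity survival from the center of a unit ball vs u = T/R^2.

    Dual theta representations: the spectral series
    2 sum (-1)^{n+1} e^{-pi^2 n^2 u} at large u, and its modular transform
    1 - (2/sqrt(pi u)) sum_{k>=0} e^{-(2k+1)^2/(4u)} at small u.
    """
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = u < 0.15
    if small.any():
        us = u[small]
        k = np.arange(0, 6)
        s = np.exp(-((2 * k[None, :] + 1.0) ** 2) / (4.0 * us[:, None])).sum(axis=1)
        out[small] = 1.0 - 2.0 / np.sqrt(math.pi * us) * s
    if (~small).any():
        ul = u[~small]
        n = np.arange(1, 60)
        out[~small] = 2.0 * (
            (-1.0) ** (n[None, :] + 1) * np.exp(-math.pi**2 * n[None, :] ** 2 * ul[:, None])
        ).sum(axis=1)
    return np.clip(out, 0.0, 1.0)


def _ball_center_hitting_time(R: float, n: int, rng: np.random.Generator):
    """Inverse-CDF draws of the unit-diffusivity exit time from the center
    of a ball of radius R, by vectorized bisection on the survival."""
    U = rng.random(n)
    lo = np.full(n, -16.0)  # log(T/R^2) brackets
    hi = np.full(n, 4.0)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        S = hom_ball_survival(np.exp(mid))
        too_late = S < U  # survival below target: T too large
        hi = np.where(too_late, mid, hi)
        lo = np.where(too_late, lo, mid)
    return R**2 * np.exp(0.5 * (lo + hi))


def sample_hom_internal_fpt(geometry, n: int, rng: np.random.Generator):
    """Draw n unit-diffusivity FPTs ('internal-time barriers') for a geometry.

    Returns (barriers, censored): censored entries (exterior escape, with
    probability 1 - R/r0) carry barrier = +inf.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    censored = np.zeros(n, dtype=bool)
    if isinstance(geometry, HalfLineGeometry):
        T = _levy_hitting_time(geometry.x0, n, rng)
    elif isinstance(geometry, BallInteriorGeometry):
        T = _ball_center_hitting_time(geometry.R, n, rng)
    elif isinstance(geometry, BallExteriorGeometry):
        hit = rng.random(n) < geometry.R / geometry.r0
        T = np.full(n, np.inf)
        T[hit] = _levy_hitting_time(geometry.r0 - geometry.R, int(hit.sum()), rng)
        censored = ~hit
    else:
        raise TypeError(f"unknown geometry {geometry!r}")
    return T, censored


# ----------------------------------------------------------------------
# First crossings of the integrated diffusivity
# ----------------------------------------------------------------------

def first_crossing_times(params: DisorderParams, barriers, rng: np.random.Generator,
                         dt: float | None = None, max_horizon: float | None = None,
                         D0="stationary", coupled: bool = False):
    """Times at which T_t = int_0^t D_s ds first crosses each barrier.

    Paths start from the stationary diffusivity law (or a fixed D0),
    advance with exact Feller transitions, accumulate T_t by the
    trapezoidal rule, and the crossing time is found by exact linear
    interpolation of the piecewise-linear T_t within the crossing step.
    Barriers are grouped into step-size buckets dt_i = min(tau,
    T_i/dbar)/50 (quantized by powers of two) unless ``dt`` is given.
    Crossings beyond ``max_horizon`` come back as +inf.

    With ``coupled=True`` each path gets its own spawned child generator
    (split by position), so two calls with the same rng seed consume
    identical per-path randomness regardless of the barrier values: the
    common-random-number mode under which monotone coupling (a larger
    barrier never crosses earlier) holds exactly.  The default mode shares
    one stream across the shrinking active set -- faster for large
    ensembles, reproducible for a fixed barrier vector, but not coupled
    across barrier perturbations.
    """
    barriers = np.asarray(barriers, dtype=float)
    n = len(barriers)
    out = np.full(n, np.inf)
    finite = np.isfinite(barriers)
    if max_horizon is None:
        ref = np.quantile(barriers[finite], 0.99) / params.dbar if finite.any() else 0.0
        max_horizon = max(1e4 * params.tau, 1e3 * ref, 1.0)
    if params.is_homogeneous:
        # deterministic relaxation path from D0 (= dbar for stationary)
        if isinstance(D0, str):
            out[finite] = barriers[finite] / params.dbar
        else:
            out[finite] = _deterministic_crossing(params, float(D0), barriers[finite])
        out[out > max_horizon] = np.inf
        return out
    if coupled:
        children = rng.spawn(n)
        dt_vec = (np.full(n, float(dt)) if dt is not None
                  else np.minimum(params.tau, barriers / params.dbar) / 50.0)
        for i in np.where(finite)[0]:
            out[i] = _cross_bucket(params, barriers[i : i + 1], float(dt_vec[i]),
                                   children[i], max_horizon, D0)[0]
        return out
    if dt is not None:
        buckets = {float(dt): np.where(finite)[0]}
    else:
        dt_i = np.minimum(params.tau, barriers[finite] / params.dbar) / 50.0
        k = np.clip(np.round(np.log2(params.tau / 50.0 / np.maximum(dt_i, 1e-300))), 0, 40)
        base = params.tau / 50.0
        idx_f = np.where(finite)[0]
        buckets = {}
        for kk in np.unique(k):
            buckets[base * 2.0 ** (-float(kk))] = idx_f[k == kk]
    for dt_b, idx in buckets.items():
        if len(idx) == 0:
            continue
        out[idx] = _cross_bucket(params, barriers[idx], dt_b, rng, max_horizon, D0)
    return out


def _deterministic_crossing(params, D0, barriers):
    """Solve int_0^t (dbar + (D0-dbar) e^{-s/tau}) ds = T by bisection."""
    dbar, tau = params.dbar, params.tau

    def Tt(t):
        return dbar * t + (D0 - dbar) * tau * (-np.expm1(-t / tau))

    lo = np.zeros_like(barriers)
    hi = np.maximum(2.0 * barriers / dbar, 4.0 * tau)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        under = Tt(mid) < barriers
        lo = np.where(under, mid, lo)
        hi = np.where(under, hi, mid)
    return 0.5 * (lo + hi)


def _cross_bucket(params, barriers, dt, rng, max_horizon, D0):
    n = len(barriers)
    if isinstance(D0, str):
        D = sample_stationary_D(params, n, rng)
    else:
        D = np.full(n, float(D0))
    out = np.full(n, np.inf)
    Tacc = np.zeros(n)
    alive = np.arange(n)
    t = 0.0
    while len(alive) and t < max_horizon:
        D_new = feller_step(params, D[alive], dt, rng)
        inc = 0.5 * (D[alive] + D_new) * dt
        T_new = Tacc[alive] + inc
        crossed = T_new >= barriers[alive]
        if crossed.any():
            ci = alive[crossed]
            frac = (barriers[ci] - Tacc[ci]) / (T_new[crossed] - Tacc[ci])
            out[ci] = t + frac * dt
        Tacc[alive] = T_new
        D[alive] = D_new
        alive = alive[~crossed]
        t += dt
    return out


def sample_het_fpt(params: DisorderParams, geometry, n: int,
                   rng: np.random.Generator, dt: float | None = None,
                   max_horizon: float | None = None, D0="stationary",
                   seed_label=None) -> MCEnsemble:
    """Simulate n heterogeneous first-passage times by subordination.

    Per sample: draw the internal-time barrier T_hom of the geometry,
    simulate a Feller diffusivity path (stationary start by default), and
    return the first-crossing time of T_t over the barrier.  Exterior
    escapes and beyond-horizon crossings are censored (+inf samples); a
    beyond-horizon crossing in a *bounded* geometry raises, since there
    every barrier must be crossed.
    """
    barriers, censored = sample_hom_internal_fpt(geometry, n, rng)
    times = first_crossing_times(params, barriers, rng, dt=dt,
                                 max_horizon=max_horizon, D0=D0)
    horizon_censored = np.isinf(times) & ~censored
    if horizon_censored.any() and isinstance(geometry, BallInteriorGeometry):
        if max_horizon is not None:
            censored = censored | horizon_censored
        else:
            raise RuntimeError(
                f"{int(horizon_censored.sum())} bounded-domain sample(s) failed to cross "
                "within the horizon; enlarge max_horizon")
    else:
        censored = censored | horizon_censored
    return MCEnsemble(samples=times, censored=censored, params=params,
                      geometry=geometry, seed=seed_label)


# ----------------------------------------------------------------------
# Laplace-inversion access to q(t;T) and Q(t;T)
# ----------------------------------------------------------------------

def _talbot_invert(F, T, M: int = 48):
    """Fixed-Talbot inversion of a Laplace transform F at the point T > 0.

    f(T) ~ (2/(5T)) sum_{k=0}^{M-1} Re[gamma_k F(delta_k / T)]
    (Abate & Valko).  Vectorized over an array of T values.
    """
    T = np.atleast_1d(np.asarray(T, dtype=float))
    k = np.arange(1, M)
    theta = k * math.pi / M
    cot = 1.0 / np.tan(theta)
    delta = np.empty(M, dtype=complex)
    delta[0] = 2.0 * M / 5.0
    delta[1:] = 2.0 * k * math.pi / 5.0 * (cot + 1j)
    gamma = np.empty(M, dtype=complex)
    gamma[0] = 0.5 * np.exp(delta[0])
    gamma[1:] = (1.0 + 1j * theta * (1.0 + cot**2) - 1j * cot) * np.exp(delta[1:])
    s = delta[None, :] / T[:, None]  # (nT, M)
    vals = F(s)
    out = (2.0 / (5.0 * T)) * np.real(vals @ gamma)
    return out


def _q_laplace(params, t: float, s):
    """-Upsilon'(t; lam)/lam on a complex lam array (the LT of q(t;T) in T)."""
    pf = _feller_prime_factor(params, t, s)
    return pf * np.exp(feller_log_upsilon(params, t, s)) / s


def _q_mpmath(params, t: float, T: float, dps: int = 30, degree: int = 40) -> float:
    """High-precision fallback inversion via mpmath Talbot.

    The contour integrand spans e^{E} in magnitude with E = nu t/(2 tau),
    so callers scale ``dps`` with E to keep digits in hand.
    """
    import mpmath as mp

    mp.mp.dps = dps
    dbar, sigma, tau = map(mp.mpf, (params.dbar, params.sigma, params.tau))
    nu = dbar / (tau * sigma**2)

    def F(lam):
        w = mp.sqrt(1 + 4 * sigma**2 * tau**2 * lam)
        e = mp.e ** (-w * t / tau)
        ups = ((4 * w * mp.e ** (-(w - 1) * t / (2 * tau))) / ((w + 1) ** 2 - (w - 1) ** 2 * e)) ** nu
        b = ((w - 1) / (w + 1)) ** 2
        upsp = -(nu / (2 * tau)) * ((w - 1) + 2 * w * b * e / (1 - b * e)) * ups
        return -upsp / lam

    return float(mp.invertlaplace(F, T, method="talbot", degree=degree))


def _third_cumulant(params: DisorderParams, t: float) -> float:
    """kappa_3 of T_t by five-point differentiation of log Upsilon in lam.

    log Upsilon(t; lam) is the cumulant generating function of -T_t; the
    stable log-space kernel evaluation makes small-lam differences safe.
    """
    from .feller import integrated_moments

    _, v, _ = integrated_moments(params, t)
    h = 0.5 / math.sqrt(max(float(v), 1e-300))
    st2 = (params.sigma * params.tau) ** 2
    h = min(h, 0.05 / (4.0 * st2))  # stay well clear of the branch point
    lam = h * np.array([-2.0, -1.0, 1.0, 2.0])
    g = feller_log_upsilon(params, t, lam)
    return float((-g[0] + 2.0 * g[1] - 2.0 * g[2] + g[3]) / (2.0 * h**3))


def _q_gaussian(params: DisorderParams, t: float, T) -> np.ndarray:
    """q(t;T) in the quasi-deterministic regime via the CLT with a first
    Edgeworth (skewness) correction: T_t is nearly Gaussian there, and
    q = -d/dt P(T_t < T) is taken by central differencing in t."""
    from scipy.stats import norm as _norm

    from .feller import integrated_moments

    T = np.asarray(T, dtype=float)

    def cdf(ti):
        m, v, _ = integrated_moments(params, ti)
        s = math.sqrt(float(v))
        z = (T - float(m)) / s
        g1 = _third_cumulant(params, ti) / s**3
        return _norm.cdf(z) - _norm.pdf(z) * (g1 / 6.0) * (z**2 - 1.0)

    h = 1e-5 * t
    return np.asarray((cdf(t - h) - cdf(t + h)) / (2.0 * h))


#: the contour integrand spans e^{E} in magnitude with E = nu t/(2 tau):
#: below _E_DOUBLE double precision suffices; up to _E_MPMATH the mpmath
#: fallback runs at dps ~ E/2; beyond that T_t is within
#: O(1/sqrt(nu t/tau)) of Gaussian and the Edgeworth route takes over
_E_DOUBLE = 20.0
_E_MPMATH = 200.0


def q_first_crossing_density(params: DisorderParams, t, T, M: int = 48,
                             check: bool = True):
    """First-crossing density q(t;T): the pdf (in t) of the moment the
    integrated diffusivity T_t crosses the level T.

    Computed by fixed-Talbot numerical inversion, in the variable T, of
    the Laplace identity  LT_T[q(t; .)](lam) = -Upsilon'(t; lam)/lam.
    With ``check=True`` the inversion is repeated at a lower order and the
    mpmath high-precision fallback is used where the two disagree.
    Normalized as a density in t:  int_0^inf q(t;T) dt = 1 at fixed T.
    """
    if params.is_homogeneous:
        raise ValueError("q(t;T) is a Dirac mass delta(t - T/dbar) for "
                         "deterministic diffusivity; no inversion is defined")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    T_arr = np.atleast_1d(np.asarray(T, dtype=float))
    if np.any(t_arr <= 0) or np.any(T_arr <= 0):
        raise ValueError("need t > 0 and T > 0")
    st2 = (params.sigma * params.tau) ** 2
    out = np.empty((len(t_arr), len(T_arr)))
    for i, ti in enumerate(t_arr):
        E = params.dbar * ti / (2.0 * st2)
        if E > _E_MPMATH:
            # deep quasi-deterministic regime: contour inversion would need
            # hundreds of digits, while T_t is essentially Gaussian
            out[i] = _q_gaussian(params, float(ti), T_arr)
            continue
        if E > _E_DOUBLE:
            dps = int(40 + E / 2.0)
            degree = int(30 + E / 3.0)
            out[i] = [_q_mpmath(params, float(ti), float(Tj), dps=dps, degree=degree)
                      for Tj in T_arr]
            continue
        with np.errstate(over="ignore", invalid="ignore"):
            hi = _talbot_invert(lambda s: _q_laplace(params, ti, s), T_arr, M=M)
            bad = ~np.isfinite(hi)
            if check:
                lo = _talbot_invert(lambda s: _q_laplace(params, ti, s), T_arr, M=M - 16)
                finite_hi = np.where(np.isfinite(hi), hi, 0.0)
                scale = np.maximum(np.abs(finite_hi),
                                   1e-12 * max(np.max(np.abs(finite_hi)), 1e-300))
                bad = bad | ~np.isfinite(lo) | (np.abs(hi - lo) > 1e-5 * scale)
        for j in np.where(bad)[0]:
            hi[j] = _q_mpmath(params, ti, float(T_arr[j]))
        out[i] = hi
    out = out[:, 0] if np.ndim(T) == 0 else out
    return out[0] if np.ndim(t) == 0 else out


def integrated_diffusivity_density(params: DisorderParams, t, T, M: int = 48):
    """Q(t;T): the pdf of the integrated diffusivity T_t, by inversion of
    its Laplace transform Upsilon(t; lam) in lam at the point T."""
    if params.is_homogeneous:
        raise ValueError("Q(t;T) is a Dirac mass for deterministic diffusivity")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    T_arr = np.atleast_1d(np.asarray(T, dtype=float))
    out = np.empty((len(t_arr), len(T_arr)))
    for i, ti in enumerate(t_arr):
        out[i] = _talbot_invert(
            lambda s: np.exp(feller_log_upsilon(params, ti, s)), T_arr, M=M
        )
    out = out[:, 0] if np.ndim(T) == 0 else out
    return out[0] if np.ndim(t) == 0 else out


# ----------------------------------------------------------------------
# Subordination route to the FPT density
# ----------------------------------------------------------------------

def _hom_fpt_density_unit(geometry, T):
    """Unit-diffusivity FPT density rho_hom(T | geometry)."""
    T = np.asarray(T, dtype=float)
    if isinstance(geometry, HalfLineGeometry):
        x0 = geometry.x0
        return x0 * np.exp(-x0**2 / (4.0 * T)) / np.sqrt(4.0 * math.pi * T**3)
    if isinstance(geometry, BallExteriorGeometry):
        a = geometry.r0 - geometry.R
        w = geometry.R / geometry.r0
        return w * a * np.exp(-a**2 / (4.0 * T)) / np.sqrt(4.0 * math.pi * T**3)
    if isinstance(geometry, BallInteriorGeometry):
        # -dS/dT via the dual theta series
        R = geometry.R
        u = T / R**2
        out = np.empty_like(u)
        small = u < 0.15
        if small.any():
            us = u[small]
            k = np.arange(0, 6)
            x = (2 * k[None, :] + 1.0) ** 2 / (4.0 * us[:, None])
            s = ((1.0 / us[:, None]) * (x - 0.5) * np.exp(-x)).sum(axis=1)
            out[small] = 2.0 / np.sqrt(math.pi * us) * s / R**2
        if (~small).any():
            ul = u[~small]
            n = np.arange(1, 60)
            lamn = math.pi**2 * n**2
            out[~small] = (
                2.0 * ((-1.0) ** (n[None, :] + 1) * lamn[None, :]
                       * np.exp(-lamn[None, :] * ul[:, None])).sum(axis=1) / R**2
            )
        return out
    raise TypeError(f"unknown geometry {geometry!r}")


def subordination_density(params: DisorderParams, geometry, t_grid,
                          n_panels: int = 60, M: int = 48):
    """FPT density by the subordination route:

        rho(t|x0) = int_0^inf dT q(t;T) rho_hom(T|x0),

    with q from the numerical Laplace inversion and rho_hom the
    unit-diffusivity FPT density of the geometry.  Independent of (and in
    agreement with) the direct spectral/Fourier formulas.  For the
    homogeneous kernel q collapses onto delta(t - T/dbar) and the exact
    identity rho(t) = dbar * rho_hom(dbar t) is returned.
    """
    t = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if np.any(t <= 0):
        raise ValueError("grid must be positive")
    if params.is_homogeneous:
        return params.dbar * _hom_fpt_density_unit(geometry, params.dbar * t)
    out = np.empty_like(t)
    from scipy.special import roots_legendre

    nodes, weights = roots_legendre(12)
    for i, ti in enumerate(t):
        T_ref = params.dbar * ti
        lo, hi = math.log(T_ref * 1e-5), math.log(T_ref * 2e3)
        edges = np.linspace(lo, hi, n_panels + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        halves = 0.5 * np.diff(edges)
        logT = (mids[:, None] + halves[:, None] * nodes[None, :]).ravel()
        T = np.exp(logT)
        q = q_first_crossing_density(params, ti, T, M=M, check=False)
        integrand = q * _hom_fpt_density_unit(geometry, T) * T  # d(logT) measure
        w_full = (halves[:, None] * weights[None, :]).ravel()
        out[i] = float(integrand @ w_full)
    return out
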