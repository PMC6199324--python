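"""Disorder kernels: the function Upsilon(t; lambda) and friends.

In a reactive confining domain the propagator of heterogeneous diffusion
admits a spectral decomposition over Laplacian eigenmodes in which the
homogeneous factor ``exp(-dbar * t * lambda)`` is replaced by a *disorder
kernel* ``Upsilon(t; lambda)`` -- the Laplace transform, evaluated at
``lambda``, of the probability density of the integrated diffusivity
``T_t = int_0^t D_s ds``.  All first-passage and reaction-rate formulas in
this package are expressed through ``Upsilon`` and its time derivative, so
swapping the diffusivity model amounts to swapping the kernel.

For the Feller (square-root) diffusivity model the kernel is closed-form:

    Upsilon(t; lam) = ( 4 w e^{-(w-1) t/(2 tau)}
                        / ((w+1)^2 - (w-1)^2 e^{-w t/tau}) )^nu,

with ``w = sqrt(1 + 4 sigma^2 tau^2 lam)`` and ``nu = dbar/(tau sigma^2)``.
All evaluations are carried out in log-space with expm1/log1p-safe
differences, so that large ``nu * t / tau`` never overflows and the
homogeneous limit ``sigma -> 0`` is reached smoothly to machine precision.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from typing import Callable

import numpy as np
from scipy.special import gammaln, hyp2f1

from .params import DisorderParams

__all__ = [
    "DisorderKernel",
    "FellerKernel",
    "HomogeneousKernel",
    "DeterministicDiffusivityKernel",
    "MittagLefflerKernel",
    "feller_upsilon",
    "feller_log_upsilon",
    "feller_upsilon_prime",
    "upsilon_given_D0",
    "upsilon_time_integral",
    "stationary_moment",
    "mittag_leffler",
]


def _check_domain(t, lam) -> None:
    if np.any(np.asarray(t) < 0):
        raise ValueError("time t must be >= 0")
    if np.any(np.asarray(lam) < 0):
        raise ValueError("spectral parameter lam must be >= 0")


# ----------------------------------------------------------------------
# Feller kernel core (supports real and complex lam; complex is used by
# the numerical Laplace inversion in the subordination module)
# ----------------------------------------------------------------------

def _log1p(x):
    if np.iscomplexobj(x):
        return np.log(1.0 + x)
    return np.log1p(x)


def _one_minus_exp(u):
    """1 - exp(-u), expm1-safe for real input."""
    if np.iscomplexobj(u):
        return 1.0 - np.exp(-u)
    return -np.expm1(-u)


def _feller_core(params: DisorderParams, t, lam):
    """Common stable building blocks (omega, omega-1, 1-e^{-w t/tau})."""
    st = params.sigma * params.tau
    eps = 4.0 * st * st * lam
    omega = np.sqrt(1.0 + eps)
    om1 = eps / (1.0 + omega)  # omega - 1, cancellation-free
    u = omega * t / params.tau
    emu = np.exp(-u)
    return omega, om1, emu


def feller_log_upsilon(params: DisorderParams, t, lam):
    """log Upsilon(t; lam) for the Feller kernel (vectorized, overflow-free).

    Identity used:  nu (w-1) / (2 tau) = 2 dbar lam / (1 + w), so the decay
    exponent stays finite-precision even when ``sigma -> 0`` (nu -> inf).
    """
    if params.is_homogeneous:
        return -params.dbar * np.asarray(t, dtype=float) * lam
    omega, om1, emu = _feller_core(params, t, lam)
    decay = -2.0 * params.dbar * lam * t / (1.0 + omega)
    bracket = om1 * om1 * (1.0 - emu) / (4.0 * omega)
    return decay - params.nu * _log1p(bracket)


def feller_upsilon(params: DisorderParams, t, lam):
    """Upsilon(t; lam) for the Feller diffusivity model.

    Equals 1 at t = 0 or lam = 0, and decreases monotonically in t for
    lam > 0; dimensionless, always in (0, 1].
    """
    _check_domain(t, lam)
    t = np.asarray(t, dtype=float)
    lam = np.asarray(lam, dtype=float)
    return np.exp(feller_log_upsilon(params, t, lam))


def _feller_prime_factor(params: DisorderParams, t, lam):
    """-(Upsilon'/Upsilon) = A + B, both terms stable as sigma or lam -> 0."""
    omega, om1, emu = _feller_core(params, t, lam)
    st = params.sigma * params.tau
    A = 2.0 * params.dbar * lam / (1.0 + omega)
    b = (om1 / (1.0 + omega)) ** 2
    B = (
        16.0 * params.dbar * st * st * lam * lam * omega * emu
        / ((1.0 + omega) ** 4 * (1.0 - b * emu))
    )
    return A + B


def feller_upsilon_prime(params: DisorderParams, t, lam):
    """Time derivative d Upsilon / dt; <= 0, and 0 at lam = 0."""
    _check_domain(t, lam)
    t = np.asarray(t, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if params.is_homogeneous:
        d = params.dbar
        return -d * lam * np.exp(-d * t * lam)
    return -_feller_prime_factor(params, t, lam) * np.exp(
        feller_log_upsilon(params, t, lam)
    )


def _feller_upsilon_prime_over_lam(params: DisorderParams, t, lam):
    """Upsilon'(t; lam)/lam, with the analytic lam -> 0 limit (-dbar) built in."""
    t = np.asarray(t, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if params.is_homogeneous:
        d = params.dbar
        return -d * np.exp(-d * t * lam)
    omega, om1, emu = _feller_core(params, t, lam)
    st = params.sigma * params.tau
    A_over = 2.0 * params.dbar / (1.0 + omega)
    b = (om1 / (1.0 + omega)) ** 2
    B_over = (
        16.0 * params.dbar * st * st * lam * omega * emu
        / ((1.0 + omega) ** 4 * (1.0 - b * emu))
    )
    return -(A_over + B_over) * np.exp(feller_log_upsilon(params, t, lam))


# ----------------------------------------------------------------------
# Conditional kernel at fixed initial diffusivity (no stationary average)
# ----------------------------------------------------------------------

def upsilon_given_D0(params: DisorderParams, t, lam, D0):
    """Upsilon(t; lam | D0): disorder kernel conditioned on D_0 = D0.

    Averaging this over the stationary Gamma law of D0 recovers the
    unconditional Feller kernel.  Stable rewriting used::

        log Upsilon = -2 dbar lam t/(1+w)
                      - nu log1p(-(w-1)(1-e^{-u})/(2w))
                      - 2 D0 tau lam (1-e^{-u}) / (w+1+(w-1) e^{-u}),

    with u = w t / tau; all factors are sigma-cancellation free, and the
    sigma -> 0 limit reproduces exp(-lam * integral of the deterministic
    relaxation path) exactly.
    """
    _check_domain(t, lam)
    if np.any(np.asarray(D0) <= 0):
        raise ValueError("initial diffusivity D0 must be > 0")
    t = np.asarray(t, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if params.is_homogeneous:
        return np.exp(-params.dbar * t * lam)
    omega, om1, emu = _feller_core(params, t, lam)
    one_m = 1.0 - emu
    denom = omega + 1.0 + om1 * emu
    log_pref = -2.0 * params.dbar * lam * t / (1.0 + omega) - params.nu * np.log1p(
        -om1 * one_m / (2.0 * omega)
    )
    log_cond = -2.0 * D0 * params.tau * lam * one_m / denom
    return np.exp(log_pref + log_cond)


# ----------------------------------------------------------------------
# Time integral of the kernel (mean-FPT building block)
# ----------------------------------------------------------------------

#: crossover below which the Gauss-hypergeometric form is replaced by its
#: leading behaviour 1/(dbar lam) * (1 + O(nu z)); with nu*z below this
#: threshold the dropped correction is under 1e-12 relative.
_HYP_SMALL_Z = 1e-12


def upsilon_time_integral(params: DisorderParams, lam):
    """int_0^infty Upsilon(t; lam) dt via the closed Gauss-2F1 form.

    For each eigenvalue this is the per-mode contribution to the mean FPT.
    Always >= 1/(dbar * lam): the dynamic disorder slows the mean kinetics.
    Raises for lam = 0 where the integral diverges.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("upsilon_time_integral requires lam > 0 (diverges at 0)")
    if params.is_homogeneous:
        return 1.0 / (params.dbar * lam)
    omega = params.omega(lam)
    om1 = params.omega_minus_one(lam)
    z = (om1 / (1.0 + omega)) ** 2
    nu = params.nu
    # prefactor 2 tau (4w)^nu / (nu (w-1) (w+1)^{2 nu})
    #   == (1+w)/(2 dbar lam) * (1 - z)^nu
    log_pow = nu * np.log1p(-z)
    pref = (1.0 + omega) / (2.0 * params.dbar * lam) * np.exp(log_pow)
    a = nu * om1 / (2.0 * omega)
    small = nu * z < _HYP_SMALL_Z
    if nu > 1e10:
        # quasi-homogeneous regime: 2F1(a, nu; a+1; z) -> exp(nu z) with
        # a >> 1 and z -> 0; combined with (1-z)^nu this leaves
        # exp(-nu z^2/2 (1 + 2z/3 + O(z^2))), which never overflows
        return (1.0 + omega) / (2.0 * params.dbar * lam) * np.exp(
            -0.5 * nu * z**2 * (1.0 + 2.0 * z / 3.0)
        )
    with np.errstate(over="ignore", invalid="ignore"):
        hyp = np.where(small, 1.0, hyp2f1(a, nu, a + 1.0, np.where(small, 0.0, z)))
    out = pref * hyp
    bad = ~np.isfinite(np.atleast_1d(out))
    if bad.any():
        # scipy's hyp2f1 gives up when nu is very large with z not small
        # (the closed form then needs astronomical cancellation between
        # (1-z)^nu and 2F1); integrate the log-stable kernel directly there
        from scipy.integrate import quad as _quad

        out_flat = np.atleast_1d(np.asarray(out, dtype=float))
        lam_flat = np.broadcast_to(lam, out_flat.shape)
        om_flat = np.broadcast_to(omega, out_flat.shape)
        for i in np.where(bad)[0]:
            t_spike = (1.0 + om_flat[i]) / (2.0 * params.dbar * lam_flat[i])
            t_up = 30.0 * t_spike + 50.0 * params.tau
            fn = lambda s: math.exp(float(feller_log_upsilon(params, s, lam_flat[i])))
            val, _ = _quad(fn, 0.0, 25.0 * t_spike, limit=300)
            val2, _ = _quad(fn, 25.0 * t_spike, t_up, limit=300)
            out_flat[i] = val + val2
        out = out_flat.reshape(np.shape(out)) if np.shape(out) else float(out_flat[0])
    return out


# ----------------------------------------------------------------------
# Stationary diffusivity moments
# ----------------------------------------------------------------------

def stationary_moment(params: DisorderParams, k: float) -> float:
    """k-th moment of the stationary Gamma diffusivity law.

    Gamma(nu + k) / (Gamma(nu) nu^k) * dbar^k for k > -nu; returns the
    ``math.inf`` sentinel (not an error) when the moment diverges
    (k <= -nu).  Valid for non-integer and negative orders.
    """
    if params.is_homogeneous:
        return params.dbar**k
    nu = params.nu
    if k <= -nu:
        return math.inf
    log_m = gammaln(nu + k) - gammaln(nu) - k * math.log(nu) + k * math.log(params.dbar)
    return float(math.exp(log_m))


# ----------------------------------------------------------------------
# Mittag-Leffler function and CTRW kernel
# ----------------------------------------------------------------------

def _ml_series(x: float, alpha: float, beta: float):
    """Taylor sum of E_{a,b}(-x); returns (value, est. relative error)."""
    s = 1.0 / math.gamma(beta)
    max_abs = abs(s)
    term_log_peak = -math.inf
    sign = 1.0
    converged = False
    log_x = math.log(x)
    for k in range(1, 400):
        sign = -sign
        tl = k * log_x - gammaln(alpha * k + beta)
        if tl > 600.0:  # would overflow; the series is hopeless here
            return s, math.inf
        term = sign * math.exp(tl)
        s += term
        max_abs = max(max_abs, abs(term))
        if tl < term_log_peak and abs(term) < 1e-18 * max(abs(s), 1e-300):
            converged = True
            break
        term_log_peak = max(term_log_peak, tl)
    if not converged:
        return s, math.inf
    err = max_abs * 1e-16 / max(abs(s), 1e-300)
    return s, err


def _ml_asymptotic(x: float, alpha: float, beta: float):
    """Optimally truncated large-x expansion of E_{a,b}(-x).

    E_{a,b}(-x) ~ sum_{k>=1} (-1)^{k+1} x^{-k} / Gamma(beta - alpha k);
    1/Gamma(beta - alpha k) is evaluated through the reflection formula to
    dodge the Gamma poles.  Returns (value, est. relative error).
    """
    s = 0.0
    prev = math.inf
    last = math.inf
    log_x = math.log(x)
    for k in range(1, 200):
        arg = beta - alpha * k
        # 1/Gamma(arg) = sin(pi*arg) * Gamma(1-arg) / pi; at the Gamma
        # poles (arg a non-positive integer) the term vanishes identically,
        # but floating sin(pi*n) returns ~1e-16 garbage -- skip explicitly.
        if abs(arg - round(arg)) < 1e-12 and round(arg) <= 0:
            continue
        sin_term = math.sin(math.pi * arg)
        log_mag = math.log(abs(sin_term)) + gammaln(1.0 - arg) - math.log(math.pi) - k * log_x
        if log_mag > 700.0:
            break
        mag = math.exp(log_mag)
        if mag > prev:  # optimal truncation reached
            break
        s += (-1.0) ** (k + 1) * math.copysign(mag, sin_term)
        last = mag
        prev = mag
    err = last / max(abs(s), 1e-300)
    return s, err


def _ml_series_pos(z: float, alpha: float, beta: float) -> float:
    """Taylor sum for z > 0 (all terms positive; no cancellation)."""
    s = 1.0 / math.gamma(beta)
    for k in range(1, 400):
        term = math.exp(k * math.log(z) - gammaln(alpha * k + beta))
        s += term
        if term < 1e-18 * s:
            break
    return s


def _ml_spectral(x: float, alpha: float, beta: float) -> float:
    """Spectral (completely monotone) integral for E_{a,1} and E_{a,a}, x > 0.

    E_a(-t^a)          = int_0^inf e^{-r t} K_a(r) dr,
    E_{a,a}(-t^a) t^{a-1} = int_0^inf r e^{-r t} K_a(r) dr,

    with K_a(r) = (1/pi) r^{a-1} sin(a pi) / (r^{2a} + 2 r^a cos(a pi) + 1)
    and t = x^{1/a}; evaluated on a log grid (integrand is smooth there).
    """
    from scipy.integrate import quad

    t = x ** (1.0 / alpha)
    spi, cpi = math.sin(math.pi * alpha), math.cos(math.pi * alpha)
    power = 1.0 if beta == alpha else 0.0

    def f(u):
        r = math.exp(u)
        K = r**alpha * spi / (math.pi * (r ** (2 * alpha) + 2.0 * r**alpha * cpi + 1.0))
        return math.exp(-r * t) * K * r**power

    lo = min(-50.0, -5.0 * math.log(max(t, 1.0)))
    hi = max(5.0, math.log(700.0 / t) if t > 0 else 5.0)
    val, _ = quad(f, lo, hi, limit=400)
    if beta == alpha:
        val *= t ** (1.0 - alpha)
    return val


def _ml_scalar(z: float, alpha: float, beta: float) -> float:
    if z == 0.0:
        return 1.0 / math.gamma(beta)
    if z > 0:
        return _ml_series_pos(z, alpha, beta)
    x = -z
    v_s, e_s = _ml_series(x, alpha, beta)
    if e_s < 1e-12:
        return v_s
    v_a, e_a = _ml_asymptotic(x, alpha, beta)
    if min(e_a, e_s) > 1e-10 and (beta == 1.0 or beta == alpha):
        return _ml_spectral(x, alpha, beta)
    return v_a if e_a < e_s else v_s


def mittag_leffler(z, alpha: float, beta: float = 1.0):
    """Two-parameter Mittag-Leffler function E_{alpha,beta}(z), 0 < alpha < 1.

    Intended for real z <= 0 (completely monotone branch used by the CTRW
    kernel); small positive arguments are also accepted.  Uses the Taylor
    series where it is well conditioned and switches to the optimally
    truncated asymptotic expansion at large ``|z|``, choosing per element
    whichever carries the smaller error estimate.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    z_arr = np.asarray(z, dtype=float)
    out = np.empty(z_arr.shape, dtype=float)
    it = np.nditer(z_arr, flags=["multi_index"])
    for val in it:
        out[it.multi_index] = _ml_scalar(float(val), alpha, beta)
    return out if z_arr.ndim else float(out)


# ----------------------------------------------------------------------
# Kernel objects: the pluggable contract used by every spectral formula
# ----------------------------------------------------------------------

class DisorderKernel(ABC):
    """Contract for a disorder kernel Upsilon(t; lam).

    Invariants: Upsilon(0, lam) = Upsilon(t, 0) = 1; Upsilon is
    non-increasing in t at fixed lam > 0; upsilon_prime <= 0.
    """

    name: str = "kernel"

    @abstractmethod
    def upsilon(self, t, lam): ...

    @abstractmethod
    def upsilon_prime(self, t, lam): ...

    def log_upsilon(self, t, lam):
        return np.log(self.upsilon(t, lam))

    def upsilon_prime_over_lam(self, t, lam):
        """Upsilon'(t; lam)/lam; overridden where the lam->0 limit is analytic."""
        lam = np.asarray(lam, dtype=float)
        return self.upsilon_prime(t, lam) / lam


class FellerKernel(DisorderKernel):
    """Disorder kernel of the Feller (square-root) diffusivity model."""

    name = "feller"

    def __init__(self, params: DisorderParams):
        self.params = params

    def upsilon(self, t, lam):
        return feller_upsilon(self.params, t, lam)

    def log_upsilon(self, t, lam):
        _check_domain(t, lam)
        return feller_log_upsilon(
            self.params, np.asarray(t, dtype=float), np.asarray(lam, dtype=float)
        )

    def upsilon_prime(self, t, lam):
        return feller_upsilon_prime(self.params, t, lam)

    def upsilon_prime_over_lam(self, t, lam):
        _check_domain(t, lam)
        return _feller_upsilon_prime_over_lam(self.params, t, lam)

    def time_integral(self, lam):
        return upsilon_time_integral(self.params, lam)


class HomogeneousKernel(DisorderKernel):
    """Constant diffusivity: Upsilon = exp(-dbar t lam) (ordinary diffusion)."""

    name = "hom"

    def __init__(self, dbar: float):
        if not dbar > 0:
            raise ValueError("dbar must be > 0")
        self.dbar = dbar

    def upsilon(self, t, lam):
        _check_domain(t, lam)
        return np.exp(-self.dbar * np.asarray(t, dtype=float) * lam)

    def log_upsilon(self, t, lam):
        _check_domain(t, lam)
        return -self.dbar * np.asarray(t, dtype=float) * np.asarray(lam, dtype=float)

    def upsilon_prime(self, t, lam):
        _check_domain(t, lam)
        lam = np.asarray(lam, dtype=float)
        return -self.dbar * lam * np.exp(-self.dbar * np.asarray(t, dtype=float) * lam)

    def upsilon_prime_over_lam(self, t, lam):
        _check_domain(t, lam)
        return -self.dbar * np.exp(-self.dbar * np.asarray(t, dtype=float) * np.asarray(lam, dtype=float))

    def time_integral(self, lam):
        lam = np.asarray(lam, dtype=float)
        if np.any(lam <= 0):
            raise ValueError("time integral diverges at lam = 0")
        return 1.0 / (self.dbar * lam)


class DeterministicDiffusivityKernel(DisorderKernel):
    """Deterministically prescribed D(t): Upsilon = exp(-lam * T(t)).

    ``T_of_t`` must be the running integral of ``d_of_t`` starting at 0.
    The associated first-crossing density is a Dirac mass -- the fully
    coherent limit of the subordination picture.
    """

    name = "deterministic"

    def __init__(self, d_of_t: Callable, T_of_t: Callable):
        self.d_of_t = d_of_t
        self.T_of_t = T_of_t

    def upsilon(self, t, lam):
        _check_domain(t, lam)
        T = np.asarray(self.T_of_t(np.asarray(t, dtype=float)))
        return np.exp(-np.asarray(lam, dtype=float) * T)

    def upsilon_prime(self, t, lam):
        _check_domain(t, lam)
        t = np.asarray(t, dtype=float)
        lam = np.asarray(lam, dtype=float)
        return -lam * np.asarray(self.d_of_t(t)) * self.upsilon(t, lam)

    def upsilon_prime_over_lam(self, t, lam):
        _check_domain(t, lam)
        t = np.asarray(t, dtype=float)
        return -np.asarray(self.d_of_t(t)) * self.upsilon(t, lam)


class MittagLefflerKernel(DisorderKernel):
    """Heavy-tailed CTRW kernel: Upsilon = E_alpha(-D_alpha t^alpha lam).

    Models a continuous-time random walk with anomalous waiting-time
    exponent 0 < alpha < 1 and generalized diffusivity ``d_alpha``.  Plugs
    into every spectral formula exactly like the Feller kernel.
    """

    name = "mittag-leffler"

    def __init__(self, alpha: float, d_alpha: float):
        if not 0.0 < alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
        if not d_alpha > 0:
            raise ValueError("d_alpha must be > 0")
        self.alpha = alpha
        self.d_alpha = d_alpha

    def upsilon(self, t, lam):
        _check_domain(t, lam)
        t = np.asarray(t, dtype=float)
        lam = np.asarray(lam, dtype=float)
        z = -self.d_alpha * np.power(t, self.alpha) * lam
        return mittag_leffler(z, self.alpha)

    def upsilon_prime(self, t, lam):
        """d/dt E_a(-c t^a) = -c t^{a-1} E_{a,a}(-c t^a); defined for t > 0."""
        _check_domain(t, lam)
        t = np.asarray(t, dtype=float)
        lam = np.asarray(lam, dtype=float)
        if np.any(t == 0):
            raise ValueError("Mittag-Leffler upsilon_prime diverges at t = 0")
        c = self.d_alpha * lam
        z = -c * np.power(t, self.alpha)
        return -c * np.power(t, self.alpha - 1.0) * mittag_leffler(z, self.alpha, self.alpha)
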