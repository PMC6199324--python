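"""Exact results for unbounded reactive geometries.

Half-line / half-space with a perfectly reactive endpoint (the statistics
of the first passage to a reactive hyperplane reduce to the 1-D problem),
and the exterior of a perfectly reactive sphere -- the classical
Smoluchowski geometry.  The Laplacian spectrum is continuous, so the
spectral sums become Fourier-type integrals over the wavenumber q with the
disorder kernel evaluated at lam = q^2:

    half-line:  S(t|x0)   = (2/pi) int_0^inf dq/q sin(q x0) Upsilon(t; q^2)
    exterior:   S(t|r0)   = (r0-R)/r0
                            + (2R/(pi r0)) int_0^inf dq/q sin(q(r0-R)) Upsilon(t; q^2)
    fluxes:     J involves int_0^inf dq Upsilon'(t; q^2)/q^2

The oscillatory integrals are evaluated with Gauss-Legendre panels between
consecutive zeros of the sine; the integrands decay exponentially in q for
t > 0, which terminates the panel sweep.  The q -> 0 limit of
Upsilon'(t; q^2)/q^2 (= -dbar + O(q^2)) is computed analytically through
the kernel's ``upsilon_prime_over_lam`` to avoid 0/0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import roots_legendre

from .kernels import DisorderKernel, FellerKernel
from .params import DisorderParams
from .spectral import FPTCurve

__all__ = [
    "HalfLineProblem",
    "BallExteriorProblem",
    "halfline_survival",
    "halfline_fpt_density",
    "halfline_propagator",
    "halfline_flux",
    "exterior_survival",
    "exterior_fpt_density",
    "exterior_flux",
    "naive_flux_exterior",
    "smoluchowski_prefactor",
    "multiparticle_survival",
]


@dataclass(frozen=True)
class HalfLineProblem:
    """Particle on (0, inf) started at x0 > 0; absorbing endpoint at 0."""

    x0: float
    params: DisorderParams

    def __post_init__(self) -> None:
        if not self.x0 > 0:
            raise ValueError("start point x0 must be > 0")

    @property
    def kernel(self) -> DisorderKernel:
        return FellerKernel(self.params)


@dataclass(frozen=True)
class BallExteriorProblem:
    """Particle outside a reactive ball of radius R, started at radius r0 > R."""

    R: float
    r0: float
    params: DisorderParams
    c0: float | None = None

    def __post_init__(self) -> None:
        if not (self.r0 > self.R > 0):
            raise ValueError("need r0 > R > 0")

    @property
    def kernel(self) -> DisorderKernel:
        return FellerKernel(self.params)


# ----------------------------------------------------------------------
# Quadrature engines
# ----------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = roots_legendre(16)
_PANEL_BLOCK = 64
_OSC_RTOL = 1e-11
_MAX_PANELS = 400_000


def _oscillatory_integral(f, period_scale: float, n_t: int, rtol: float = _OSC_RTOL):
    """int_0^inf f(q, idx) dq for an integrand oscillating with zero spacing
    pi/period_scale; ``f(q, idx)`` maps a q-vector and an index array into
    the time grid to a (len(idx), len(q)) array.

    Gauss-Legendre panels between consecutive sine zeros.  Each time point
    is swept independently: once its last two panel blocks fall below rtol
    of its running sum it drops out of the evaluation, so short times
    (whose integrands decay slowly in q) do not force long times to keep
    integrating.
    """
    h = math.pi / period_scale
    acc = np.zeros(n_t)
    last = np.zeros(n_t)
    small_count = np.zeros(n_t, dtype=int)
    active = np.arange(n_t)
    # inner sweep: geometric panels covering (0, h); resolves integrands
    # whose q-width is far below the first sine zero (long times)
    inner_edges = [0.0]
    w = h * 1e-12
    while inner_edges[-1] < h:
        inner_edges.append(min(inner_edges[-1] + w, h))
        w *= 1.8
    inner_edges = np.asarray(inner_edges)
    mids = 0.5 * (inner_edges[:-1] + inner_edges[1:])
    halves = 0.5 * np.diff(inner_edges)
    q = (mids[:, None] + halves[:, None] * _GL_NODES[None, :]).ravel()
    vals = f(q, active).reshape(n_t, len(mids), len(_GL_NODES))
    acc += np.einsum("tpk,p,k->t", vals, halves, _GL_WEIGHTS)
    # outer sweep: panels between consecutive sine zeros
    half = 0.5 * h
    k = 1
    while k < _MAX_PANELS:
        edges = h * np.arange(k, k + _PANEL_BLOCK + 1)
        mid = 0.5 * (edges[:-1] + edges[1:])
        q = (mid[:, None] + half * _GL_NODES[None, :]).ravel()
        vals = f(q, active).reshape(len(active), _PANEL_BLOCK, len(_GL_NODES))
        contrib = half * np.einsum("tpk,k->t", vals, _GL_WEIGHTS)
        acc[active] += contrib
        last[active] = np.abs(contrib)
        scale = np.maximum(np.abs(acc[active]), 1e-300)
        small = np.abs(contrib) <= rtol * scale
        small_count[active] = np.where(small, small_count[active] + 1, 0)
        active = active[small_count[active] < 2]
        if len(active) == 0:
            return acc, last
        k += _PANEL_BLOCK
    raise RuntimeError(
        "oscillatory quadrature failed to converge within "
        f"{_MAX_PANELS} panels (period scale {period_scale:g}); "
        "the time grid may reach too far below the kernel decay scale"
    )


def _halfaxis_integral(f, q_scale: float, n_t: int, rtol: float = 1e-11):
    """int_0^inf f(q, idx) dq for a smooth non-oscillatory decaying
    integrand; same active-set contract as _oscillatory_integral.

    Geometrically growing Gauss-Legendre panels starting at the scale of
    the integrand's width.
    """
    acc = np.zeros(n_t)
    lo = 0.0
    width = q_scale * 1e-9
    small_count = np.zeros(n_t, dtype=int)
    active = np.arange(n_t)
    for _ in range(400):
        hi = lo + width
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        q = mid + half * _GL_NODES
        contrib = half * (f(q, active) @ _GL_WEIGHTS)
        acc[active] += contrib
        scale = np.maximum(np.abs(acc[active]), 1e-300)
        small = np.abs(contrib) <= rtol * scale
        small_count[active] = np.where(small, small_count[active] + 1, 0)
        active = active[small_count[active] < 3]
        if len(active) == 0:
            return acc
        lo = hi
        width *= 1.6
    raise RuntimeError("half-axis quadrature failed to converge")


def _as_grid(t_grid):
    t = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    return t


# ----------------------------------------------------------------------
# Half-line
# ----------------------------------------------------------------------

def halfline_survival(prob: HalfLineProblem, t_grid, kernel: DisorderKernel | None = None) -> FPTCurve:
    """Survival probability on the half-line; S(0) = 1, S(inf) = 0."""
    kernel = kernel or prob.kernel
    t = _as_grid(t_grid)
    x0 = prob.x0
    out = np.ones_like(t)
    pos = t > 0
    if pos.any():
        tcol = t[pos][:, None]

        def f(q, idx):
            return np.sin(q * x0)[None, :] / q[None, :] * kernel.upsilon(tcol[idx], q[None, :] ** 2)

        val, _ = _oscillatory_integral(f, x0, int(pos.sum()))
        out[pos] = np.clip(2.0 / math.pi * val, 0.0, 1.0)
    return FPTCurve(t=t, survival=out, metadata={"geometry": "half-line", "kernel": kernel.name, "x0": x0})


def halfline_fpt_density(prob: HalfLineProblem, t_grid, kernel: DisorderKernel | None = None) -> FPTCurve:
    """FPT density rho(t|x0) on the half-line; normalized to 1 (recurrent)."""
    kernel = kernel or prob.kernel
    t = _as_grid(t_grid)
    if np.any(t == 0):
        raise ValueError("density grid must exclude t = 0")
    x0 = prob.x0
    tcol = t[:, None]

    def f(q, idx):
        return -np.sin(q * x0)[None, :] / q[None, :] * kernel.upsilon_prime(tcol[idx], q[None, :] ** 2)

    val, err = _oscillatory_integral(f, x0, len(t))
    dens = 2.0 / math.pi * val
    return FPTCurve(t=t, density=dens, truncation_error=2.0 / math.pi * err,
                    metadata={"geometry": "half-line", "kernel": kernel.name, "x0": x0})


def halfline_propagator(prob: HalfLineProblem, x, t: float, kernel: DisorderKernel | None = None):
    """Propagator P(x, t | x0) on the half-line with absorbing endpoint 0.

    Image-method difference of two free-line Fourier kernels:
    (1/pi) int_0^inf dq [cos(q(x-x0)) - cos(q(x+x0))] Upsilon(t; q^2).
    Vanishes identically at x = 0.
    """
    kernel = kernel or prob.kernel
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    if t == 0:
        raise ValueError("propagator at t = 0 is a Dirac mass; use t > 0")
    x0 = prob.x0
    scale = np.max(x + x0)

    def f(q, idx):
        diff = np.cos(q[None, :] * (x[idx] - x0)[:, None]) - np.cos(q[None, :] * (x[idx] + x0)[:, None])
        return diff * kernel.upsilon(np.array([[t]]), q[None, :] ** 2)

    val, _ = _oscillatory_integral(f, scale, len(x))
    out = val / math.pi
    out[x == 0] = 0.0
    return out if out.shape != (1,) else float(out[0])


def halfline_flux(prob: HalfLineProblem, c0: float, t_grid, kernel: DisorderKernel | None = None) -> FPTCurve:
    """Macroscopic reaction rate (per unit area) on a reactive hyperplane.

    J(t) = -(2 c0 / pi) int_0^inf dq Upsilon'(t; q^2)/q^2 for a uniform
    initial concentration c0; decays to zero as the half-space empties.
    t = 0 is reported as +inf (integrable singularity).
    """
    if not c0 > 0:
        raise ValueError("c0 must be > 0")
    kernel = kernel or prob.kernel
    t = _as_grid(t_grid)
    out = np.full_like(t, np.inf)
    pos = t > 0
    if pos.any():
        tcol = t[pos][:, None]

        def f(q, idx):
            return -kernel.upsilon_prime_over_lam(tcol[idx], q[None, :] ** 2)

        q_scale = 1.0 / math.sqrt(prob.params.dbar * float(np.min(t[pos])))
        val = _halfaxis_integral(f, q_scale, int(pos.sum()))
        out[pos] = 2.0 * c0 / math.pi * val
    return FPTCurve(t=t, metadata={"geometry": "half-line-flux", "kernel": kernel.name,
                                   "c0": c0, "J": out})


# ----------------------------------------------------------------------
# Exterior of a reactive ball
# ----------------------------------------------------------------------

def exterior_survival(prob: BallExteriorProblem, t_grid, kernel: DisorderKernel | None = None) -> FPTCurve:
    """S(t|r0) outside a reactive sphere; S(0) = 1, S(inf) = (r0-R)/r0."""
    kernel = kernel or prob.kernel
    t = _as_grid(t_grid)
    R, r0 = prob.R, prob.r0
    a = r0 - R
    escape = a / r0
    out = np.ones_like(t)
    pos = t > 0
    if pos.any():
        tcol = t[pos][:, None]

        def f(q, idx):
            return np.sin(q * a)[None, :] / q[None, :] * kernel.upsilon(tcol[idx], q[None, :] ** 2)

        val, _ = _oscillatory_integral(f, a, int(pos.sum()))
        out[pos] = np.clip(escape + 2.0 * R / (math.pi * r0) * val, 0.0, 1.0)
    return FPTCurve(t=t, survival=out,
                    metadata={"geometry": "ball-exterior", "kernel": kernel.name,
                              "R": R, "r0": r0, "escape_probability": escape})


def exterior_fpt_density(prob: BallExteriorProblem, t_grid, kernel: DisorderKernel | None = None) -> FPTCurve:
    """FPT density to the sphere; total mass R/r0 (escape to infinity)."""
    kernel = kernel or prob.kernel
    t = _as_grid(t_grid)
    if np.any(t == 0):
        raise ValueError("density grid must exclude t = 0")
    R, r0 = prob.R, prob.r0
    a = r0 - R
    tcol = t[:, None]

    def f(q, idx):
        return -np.sin(q * a)[None, :] / q[None, :] * kernel.upsilon_prime(tcol[idx], q[None, :] ** 2)

    val, err = _oscillatory_integral(f, a, len(t))
    dens = 2.0 * R / (math.pi * r0) * val
    return FPTCurve(t=t, density=dens, truncation_error=2.0 * R / (math.pi * r0) * err,
                    metadata={"geometry": "ball-exterior", "kernel": kernel.name,
                              "R": R, "r0": r0, "total_mass": R / r0})


def _flux_integral(kernel, t_pos, dbar):
    """int_0^inf dq Upsilon'(t; q^2)/q^2 (negative) for each t > 0."""
    tcol = t_pos[:, None]

    def f(q, idx):
        return kernel.upsilon_prime_over_lam(tcol[idx], q[None, :] ** 2)

    q_scale = 1.0 / math.sqrt(dbar * float(np.min(t_pos)))
    return _halfaxis_integral(f, q_scale, len(t_pos))


def exterior_flux(prob: BallExteriorProblem, t_grid, kernel: DisorderKernel | None = None) -> FPTCurve:
    """Macroscopic rate onto the sphere for uniform bulk concentration c0.

    J(t) = 4 pi c0 R dbar (1 - (2R/(pi dbar)) int dq Upsilon'(t;q^2)/q^2);
    decays monotonically to the Smoluchowski steady rate J_S = 4 pi c0
    dbar R.  The normalized curve J/J_S is in ``metadata["J_over_JS"]``.
    """
    if prob.c0 is None:
        raise ValueError("BallExteriorProblem.c0 must be set for flux computations")
    kernel = kernel or prob.kernel
    t = _as_grid(t_grid)
    dbar = prob.params.dbar
    JS = 4.0 * math.pi * prob.c0 * dbar * prob.R
    out = np.full_like(t, np.inf)
    pos = t > 0
    if pos.any():
        I = _flux_integral(kernel, t[pos], dbar)
        out[pos] = JS * (1.0 - 2.0 * prob.R / (math.pi * dbar) * I)
    return FPTCurve(t=t, metadata={"geometry": "ball-exterior-flux", "kernel": kernel.name,
                                   "R": prob.R, "r0": prob.r0, "c0": prob.c0,
                                   "J": out, "J_over_JS": out / JS, "J_S": JS})


def naive_flux_exterior(prob: BallExteriorProblem, t_grid, kernel: DisorderKernel | None = None) -> FPTCurve:
    """The concentration-gradient ('naive') flux approximation.

    J_app(t) = 4 pi R c0 dbar (1 + (2R/pi) int_0^inf dq Upsilon(t; q^2)):
    computed from the mean-diffusivity gradient of the survival profile.
    It shares the long-time limit J_S with the exact flux but differs at
    finite times for any genuinely heterogeneous kernel; the two coincide
    only for homogeneous diffusion.  Provided for comparison -- a pitfall
    of transplanting homogeneous-diffusion tools.
    """
    if prob.c0 is None:
        raise ValueError("BallExteriorProblem.c0 must be set for flux computations")
    kernel = kernel or prob.kernel
    t = _as_grid(t_grid)
    dbar = prob.params.dbar
    JS = 4.0 * math.pi * prob.c0 * dbar * prob.R
    out = np.full_like(t, np.inf)
    pos = t > 0
    if pos.any():
        tcol = t[pos][:, None]

        def f(q, idx):
            return kernel.upsilon(tcol[idx], q[None, :] ** 2)

        q_scale = 1.0 / math.sqrt(dbar * float(np.min(t[pos])))
        I = _halfaxis_integral(f, q_scale, int(pos.sum()))
        out[pos] = JS * (1.0 + 2.0 * prob.R / math.pi * I)
    return FPTCurve(t=t, metadata={"geometry": "ball-exterior-naive-flux", "kernel": kernel.name,
                                   "J": out, "J_over_JS": out / JS, "J_S": JS})


def smoluchowski_prefactor(nu: float) -> float:
    """Short-time rate prefactor Gamma(nu + 1/2)/(sqrt(nu) Gamma(nu)).

    Multiplies the divergent t^{-1/2} term of the Smoluchowski rate at
    short times under dynamic disorder; grows monotonically from 0 to 1 as
    nu runs from 0 to infinity (homogeneous limit).
    """
    if not nu > 0:
        raise ValueError("nu must be > 0")
    from scipy.special import gammaln as _gammaln

    return float(math.exp(_gammaln(nu + 0.5) - _gammaln(nu) - 0.5 * math.log(nu)))


# ----------------------------------------------------------------------
# Collective search by many independent particles
# ----------------------------------------------------------------------

def multiparticle_survival(prob: BallExteriorProblem, N, c0: float, t_grid,
                           R_max: float | None = None, form: str = "both"):
    """Survival of a target against N searchers (or the thermodynamic limit).

    Finite N: the particles start uniformly in the shell R < r < R_max and
    S_N(t) = (volume average of S(t|r0))^N.  ``N="thermodynamic"``: N and
    R_max go to infinity at fixed concentration c0 and

        S_inf(t) = exp(-int_0^t J(t') dt')
                 = exp(-4 pi c0 R dbar (t + (2R/(pi dbar))
                        int_0^inf dq (1 - Upsilon(t; q^2))/q^2)),

    computed by both routes (``form="flux"``, ``"kernel"`` or ``"both"``;
    with "both" the two are cross-checked and their mean returned).
    """
    t = _as_grid(t_grid)
    if N == "thermodynamic":
        prob_c = BallExteriorProblem(prob.R, prob.r0, prob.params, c0)
        vals = {}
        if form in ("flux", "both"):
            vals["flux"] = _thermo_via_flux(prob_c, t)
        if form in ("kernel", "both"):
            vals["kernel"] = _thermo_via_kernel(prob_c, t)
        if form == "both":
            a, b = vals["flux"], vals["kernel"]
            if np.max(np.abs(a - b)) > 1e-6:
                raise RuntimeError("thermodynamic-limit survival: the flux-integral and "
                                   "kernel-integral forms disagree beyond 1e-6")
            return 0.5 * (a + b)
        return next(iter(vals.values()))
    if not (isinstance(N, (int, np.integer)) and N >= 1):
        raise ValueError("N must be a positive integer or 'thermodynamic'")
    if R_max is None or not R_max > prob.R:
        raise ValueError("finite-N mode requires an outer radius R_max > R")
    # volume average of S(t|r0) over the shell by radial Gauss-Legendre
    nodes, weights = roots_legendre(64)
    mid, half = 0.5 * (R_max + prob.R), 0.5 * (R_max - prob.R)
    r_nodes = mid + half * nodes
    V = 4.0 / 3.0 * math.pi * (R_max**3 - prob.R**3)
    S_acc = np.zeros_like(t)
    for r0_i, w_i in zip(r_nodes, weights):
        p_i = BallExteriorProblem(prob.R, float(r0_i), prob.params)
        S_i = exterior_survival(p_i, t).survival
        S_acc += w_i * half * 4.0 * math.pi * r0_i**2 * S_i / V
    return np.clip(S_acc, 0.0, 1.0) ** N


def _thermo_via_flux(prob: BallExteriorProblem, t):
    """exp(-int_0^t J) with the t'^{-1/2} singularity removed by t' = s^2."""
    nodes, weights = roots_legendre(96)
    out = np.empty_like(t)
    for i, ti in enumerate(t):
        if ti == 0:
            out[i] = 1.0
            continue
        smax = math.sqrt(ti)
        s = 0.5 * smax * (nodes + 1.0)
        J = exterior_flux(prob, s**2).metadata["J"]
        integral = 0.5 * smax * np.sum(weights * 2.0 * s * J)
        out[i] = math.exp(-integral)
    return out


def _thermo_via_kernel(prob: BallExteriorProblem, t):
    kernel = prob.kernel
    dbar = prob.params.dbar
    JS = 4.0 * math.pi * prob.c0 * dbar * prob.R
    out = np.empty_like(t)
    pos = t > 0
    out[~pos] = 1.0
    if pos.any():
        tcol = t[pos][:, None]

        def f(q, idx):
            lam = q[None, :] ** 2
            return -np.expm1(kernel.log_upsilon(tcol[idx], lam)) / lam

        q_scale = 1.0 / math.sqrt(dbar * float(np.min(t[pos])))
        I = _halfaxis_integral(f, q_scale, int(pos.sum()))
        out[pos] = np.exp(-JS * (t[pos] + 2.0 * prob.R / (math.pi * dbar) * I))
    return out
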