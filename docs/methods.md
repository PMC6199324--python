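# Methods

## Model and assumptions

A point particle diffuses in a reactive geometry while its diffusivity
D_t performs a Feller (square-root) process

    dD_t = (dbar − D_t) dt/τ + σ √(2 D_t) dW_t ,

independent of the particle's position.  This is the annealed-disorder
idealization of a rearranging medium: by the time the particle revisits a
location the environment has changed, so mobility fluctuations enter as a
time-dependent, spatially structureless random coefficient.  The
square-root noise keeps D_t strictly positive (the zero boundary is
non-attainable in law under the no-flux convention adopted here) and
makes the stationary law Gamma(ν, dbar/ν) with ν = dbar/(τσ²).  All real
ν > 0 are supported; 0 < ν < 1 is the strong-disorder regime where the
stationary density diverges at D = 0.

Assumptions worth keeping in mind: the diffusivity is shared by all
spatial directions (displacements are correlated through it, so the free
propagator in d dimensions does not factorize); targets are perfectly
absorbing (Dirichlet) and inert walls perfectly reflecting (Neumann) —
partial (Robin) reactivity is *not* representable in this marginal
framework and is out of scope; diffusivities of distinct particles are
independent in the many-particle formulas.

## Parameters

| symbol | meaning | units | default/typical |
| --- | --- | --- | --- |
| dbar | mean diffusivity | length²/time | 1 (sets units) |
| σ | diffusivity fluctuation amplitude | length/√time | — |
| τ | medium rearrangement time | time | — |
| 1/ν = τσ²/dbar | disorder strength (stationary var/mean²) | — | 0.1–10 |
| μ = στ/R | disorder scale vs geometry | — | 0.1–10 |
| R, L, x₀, r₀ | geometry sizes / start point | length | — |
| c₀ | initial particle concentration | length⁻³ (or ⁻¹) | 1 |

`DisorderParams.from_dimensionless` inverts (μ, 1/ν) → (σ, τ) at fixed
(dbar, R): σ = dbar/(Rμν), τ = R²νμ²/dbar.  Benchmark parameter sets
used throughout tests: the half-line set (dbar=1, σ=1, x₀=1, τ=2; ν=1/2)
and ball/exterior families on μ, 1/ν ∈ [0.1, 10] with r₀/R = 1.2.

## Numerical choices

**Kernel evaluation.**  ϒ(t;λ) is always computed in log space with the
rewriting log ϒ = −2 dbar λ t/(1+ω) − ν·log1p[(ω−1)²(1−e^{−ωt/τ})/(4ω)],
ω−1 evaluated as 4σ²τ²λ/(1+ω).  This is overflow-free for any ν·t/τ and
reaches the homogeneous limit smoothly; σ = 0 (or τ = 0) dispatches to
the exact exponential rather than evaluating a 0/0.  ν = ∞ is a sentinel,
never a float.  Below the double-precision underflow (log ϒ < −745) the
linear-scale value is exactly 0 while `log_upsilon` stays finite.

**Kernel time integral.**  The Gauss-₂F₁ closed form is used wherever
scipy evaluates it; the prefactor is folded into (1+ω)/(2 dbar λ)·(1−z)^ν
with ν·log1p(−z) in the exponent.  For ν·z < 1e−12 the hypergeometric
factor is 1 to the working precision and is skipped (the crossover is an
implementation choice; the dropped correction is below 1e−12 relative).
For ν > 1e10 the confluent limit ₂F₁ → e^{νz} is combined analytically
with (1−z)^ν into exp(−νz²/2·(1+2z/3)).  In the rare corner where scipy
returns a non-finite value (huge ν with z not small), the stable
log-space kernel is integrated directly by adaptive quadrature split at
the decay scale.

**Spectral sums.**  Mode series are accumulated in blocks of 256 with
truncation driven by the per-mode envelope |coeffₙ·ϒ′(t;λₙ)| (block sums
alternate and cancel long before individual terms decay, so they cannot
be trusted for convergence).  A time point is flagged unconverged when
the envelope has not fallen below 1e−12 of the running sum at n_max;
curves carry the flag in `metadata["converged"]`.  At short times the
required depth grows like n ≳ 40/(νσπt) (heterogeneous) or R/(π√(dbar t))
(homogeneous); density values below ~1e−12 of the curve peak sit at the
double-precision cancellation floor of the alternating sum and are noise.
Very short times are better served by the superstatistical law in
`hetfpt.approx`.  The mean-FPT series is summed exactly (math.fsum) with
an alternating-tail correction of half the extrapolated next term.

**Oscillatory wavenumber integrals** (half-line and ball exterior) use
16-point Gauss–Legendre panels between consecutive zeros of sin(qa),
preceded by a geometric inner sweep of (0, π/a) starting 12 decades below
the first zero so that integrands concentrated near q = 0 (long times)
are resolved.  Each time point retires from the sweep independently once
two consecutive panel blocks fall below 1e−11 of its running sum; the
integrands decay like exp(−νσqt) in q, which bounds the sweep.  The q → 0
limit of ϒ′(t;q²)/q² (→ −dbar) is taken analytically through
`upsilon_prime_over_lam` to avoid 0/0.  Flux-type (non-oscillatory)
integrals use geometrically growing panels from a sub-feature width.
t = 0 fluxes are reported as +inf sentinels (integrable singularity).

**Exact diffusivity simulation.**  Transitions of D_t are sampled from
the exact law — a scaled noncentral χ² with 2ν degrees of freedom, drawn
as Gamma(ν + Poisson(·), 2c) — so marginals carry no discretization bias
at any ν, including ν < 1 where Euler schemes go negative.  (An Euler
full-truncation simulator lives in the test suite as an independent
oracle.)  The integrated diffusivity uses the trapezoidal rule at
dt = τ/50 by default; the variance bias at that step is budgeted at 1%
in all Monte-Carlo moment comparisons.  First crossings of a barrier are
located by exact linear interpolation of the piecewise-linear T_t,
consistent with the trapezoid order; per-sample steps are
min(τ, T/dbar)/50, quantized in powers of two so samples can be stepped
in vectorized buckets.  One ensemble generator is used by default (fast,
reproducible for a fixed barrier set); `coupled=True` spawns one child
stream per path, the common-random-number mode under which the monotone
coupling of crossing times in the barrier is exact.  This replaces the
originally planned always-per-path splitting, which costs an order of
magnitude in the vectorized stepping loop.

**Laplace inversion** of −ϒ′(t;λ)/λ (the transform of the first-crossing
density q(t;T)) uses fixed-Talbot with M = 48 nodes, cross-checked at
M = 32; disagreeing or non-finite points fall back to mpmath Talbot.  The
contour integrand spans e^E in magnitude with E = νt/(2τ), so the method
is precision-limited: for 20 < E ≤ 200 the fallback runs at dps ≈ 40+E/2;
beyond E = 200 (quasi-deterministic regime, cv²(T_t) ≲ 1/200) q is
evaluated from the CLT with a first Edgeworth (skewness) correction, the
third cumulant taken by five-point differencing of log ϒ in λ and the
t-derivative of the crossing CDF by central differences.  Both
hand-overs were validated against first-crossing Monte Carlo at the
boundaries.  For exactly homogeneous parameters q is a Dirac mass and
the inversion refuses; the subordination density then uses the identity
ρ(t) = dbar·ρ_hom(dbar·t) directly.

**Mittag–Leffler kernel.**  E_{α,β}(−x) is computed by the Taylor series
where its largest term loses fewer than ~4 digits, by the optimally
truncated large-x expansion otherwise (Γ-pole terms skipped exactly), and
— when both error estimates exceed 1e−10 and β ∈ {1, α} — by the
completely monotone spectral integral on a log grid.  Accuracy is ~1e−10
for α ≳ 0.3; for very small α (≤ 0.2) the middle band degrades to ~1e−4
because the spectral weight develops an untruncatable algebraic tail.
This exceeds the needs of the kernel contract tests by a wide margin.

**Superstatistics.**  The Gamma-averaged Gaussian kernel K_ν(z) is built
from log-Γ and the scaled Bessel K (kve), overflow-free at large z and
with its integrable z^{2ν−1} divergence at z = 0 (ν < 1/2) handled by
quadrature.  Validity windows implement t/τ ≪ min{1, δ²/(στ)²} with a
factor-of-10 margin (configurable); asymptotic laws refuse silent
extrapolation (`override=True` evaluates anyway, flagged).  Note that at
large disorder scale μ the binding limit of the window is ν δ²/dbar, not
τ — the superstatistical ball density is accurate to 10% only within
t ≲ 0.1·min(τ, νδ²/dbar), which is the window the tests enforce.

**Most probable FPT.**  The closed-form estimate t_mp =
(1 + 5/(2ν))^{−1} δ²/dbar (from the leading exponential asymptotics) and
the numerical argmax of the full Bessel-K short-time density are both
exposed; they differ by an O(1), ν-dependent factor (about 2 at ν = 1/2).
The package reports both rather than resolving the discrepancy in favour
of either.

## What the simulator emulates — and what it does not

The subordination Monte Carlo draws (i) a unit-diffusivity Brownian
first-passage "internal time" for the geometry — half-line by the exact
inverse-square-Gaussian identity T = x₀²/(2Z²), ball center by inverse
CDF on the dual theta-function survival, exterior by a Bernoulli(R/r₀)
hit indicator times the half-line law at distance r₀−R — and (ii) an
exact Feller path whose running integral is tracked to its first
crossing of that barrier.  This reproduces the *marginal* first-passage
law exactly (up to time discretization of the crossing), which is what
all analytic formulas here describe.  It does not model spatial
correlation of the disorder (the diffusivity has no spatial structure),
inter-particle diffusivity correlations, hydrodynamic or excluded-volume
interactions, or partially reactive boundaries; agreement of tests on
synthetic ensembles therefore validates the mathematical machinery, not
the fidelity of the annealed-disorder idealization to any particular
cytoplasmic system.

Censoring: exterior-geometry escapes (probability 1 − R/r₀) and
beyond-horizon crossings are returned as +inf with a flag; distributional
tests condition on the sub-horizon range against the conditional analytic
CDF.

## Design choices on genuinely open points

- The flux "envelopes" (homogeneous transient above, short-time
  prefactor law below) are enforced with a strict lower bound but a 2%
  upper allowance: the exact exterior flux measurably exceeds the
  homogeneous curve by up to ~1.4% at intermediate times for small μ, and
  only the lower envelope is claimed as a bound by the theory.
- Problem sizes in tests and the acceptance script: 10⁵ paths for
  Monte-Carlo kernel and density cross-checks (3-SE criteria), 2×10⁴ for
  auxiliary distributional tests, spectral bases of 10⁴–4×10⁵ modes
  chosen from the short-time depth estimate above, wavenumber sweeps
  capped at 4×10⁵ panels.  These sizes put Monte-Carlo error, series
  truncation and quadrature error each below the tolerance they are
  tested against.
- Quantile-based broadening measures use the analytic survival (bisected
  to 1e−9) rather than Monte-Carlo quantiles, so the strict monotonicity
  assertions are deterministic.

## Known limitations

- Short-time spectral densities below ~1e−12 of peak are cancellation
  noise; use the superstatistical law there.
- q(t;T) in the band E = νt/(2τ) ∈ (20, 200] costs ~0.1–1 s per point
  (arbitrary-precision fallback); deep in the quasi-deterministic regime
  the Edgeworth route is percent-level accurate, not exact.
- The Mittag–Leffler middle band for α ≤ 0.2 is ~1e−4 accurate.
- Robin (partial reactivity) boundaries, Lévy-driven and geometric-
  Brownian diffusivity models are intentionally not implemented; the
  kernel contract accepts user implementations.
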