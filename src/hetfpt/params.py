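"""Parameters of the annealed-disorder (diffusing-diffusivity) model.

The local diffusivity D_t of a particle in a rearranging medium is modelled
by the Feller (square-root / Cox--Ingersoll--Ross) process

    dD_t = (dbar - D_t) dt / tau + sigma * sqrt(2 D_t) dW_t,

whose stationary law is Gamma with mean ``dbar`` and shape ``nu``.  Three
dimensional parameters govern everything:

``dbar``
    mean diffusivity (length^2 / time),
``sigma``
    amplitude of diffusivity fluctuations (length / time^{1/2}),
``tau``
    correlation (rearrangement) time of the medium (time).

Two derived dimensionless numbers control the physics: the disorder
strength ``1/nu = tau * sigma**2 / dbar`` (variance-to-squared-mean ratio of
the stationary diffusivity) and, in a domain of size R, the disorder scale
``mu = sigma * tau / R`` comparing the disorder correlation length
``sigma * tau`` to the geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["DisorderParams"]


@dataclass(frozen=True)
class DisorderParams:
    """The triple (dbar, sigma, tau) of the Feller diffusivity model.

    ``sigma = 0`` (or ``tau = 0``) is accepted and represents exactly
    homogeneous diffusion with constant diffusivity ``dbar``; the shape
    parameter ``nu`` is then the ``math.inf`` sentinel.
    """

    dbar: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if not self.dbar > 0:
            raise ValueError(f"mean diffusivity dbar must be > 0, got {self.dbar}")
        if self.sigma < 0:
            raise ValueError(f"fluctuation amplitude sigma must be >= 0, got {self.sigma}")
        if self.tau < 0:
            raise ValueError(f"correlation time tau must be >= 0, got {self.tau}")
        if self.tau == 0 and self.sigma > 0:
            # tau -> 0 at fixed sigma is the homogeneous limit; normalise it
            object.__setattr__(self, "sigma", 0.0)

    # ------------------------------------------------------------------
    @property
    def nu(self) -> float:
        """Shape parameter nu = dbar / (tau sigma^2); +inf when homogeneous."""
        if self.is_homogeneous:
            return math.inf
        return self.dbar / (self.tau * self.sigma**2)

    @property
    def inv_nu(self) -> float:
        """Disorder strength 1/nu = var{D} / mean{D}^2 of the stationary law."""
        if self.is_homogeneous:
            return 0.0
        return self.tau * self.sigma**2 / self.dbar

    @property
    def is_homogeneous(self) -> bool:
        return self.sigma == 0.0 or self.tau == 0.0

    # ------------------------------------------------------------------
    def omega(self, lam):
        """omega(lambda) = sqrt(1 + 4 sigma^2 tau^2 lambda) >= 1."""
        return np.sqrt(1.0 + 4.0 * (self.sigma * self.tau) ** 2 * np.asarray(lam, dtype=float))

    def omega_minus_one(self, lam):
        """omega - 1 computed without cancellation for small sigma^2 tau^2 lambda."""
        eps = 4.0 * (self.sigma * self.tau) ** 2 * np.asarray(lam, dtype=float)
        return eps / (1.0 + np.sqrt(1.0 + eps))

    def mu(self, R: float) -> float:
        """Disorder scale mu = sigma tau / R for a geometry of size R > 0."""
        if not R > 0:
            raise ValueError("geometry size R must be > 0")
        return self.sigma * self.tau / R

    # ------------------------------------------------------------------
    @classmethod
    def from_dimensionless(
        cls,
        dbar: float,
        R: float,
        mu: float,
        nu: float | None = None,
        inv_nu: float | None = None,
    ) -> "DisorderParams":
        """Build (dbar, sigma, tau) from the dimensionless pair (mu, 1/nu).

        Inverts mu = sigma tau / R and 1/nu = tau sigma^2 / dbar at fixed
        (dbar, R):  sigma = dbar / (R mu nu),  tau = R^2 nu mu^2 / dbar.
        """
        if (nu is None) == (inv_nu is None):
            raise ValueError("specify exactly one of nu or inv_nu")
        if nu is None:
            if inv_nu == 0:
                return cls(dbar, 0.0, 1.0)
            nu = 1.0 / inv_nu
        if not (mu > 0 and nu > 0 and R > 0):
            raise ValueError("mu, nu and R must be positive")
        sigma = dbar / (R * mu * nu)
        tau = R**2 * nu * mu**2 / dbar
        return cls(dbar, sigma, tau)
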