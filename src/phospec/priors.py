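"""Prior and MCMC configuration containers.

The coefficient prior is a spike-and-slab mixture: with prior probability
``p0`` a coefficient is exactly zero (spike, a point mass), otherwise it is
drawn from a normal slab ``N(mu, nu)``.  Variance components get weakly
informative inverse-gamma priors IG(0.01, 0.01) by default, and the
spatial-dependence parameter ``phi`` a uniform prior on a model-specific
interval: (0, 1) for the exponential correlogram, the eigenvalue-derived
interval for the CAR model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeSlabPrior", "VariancePrior", "PhiPrior", "MCMCConfig"]


@dataclass
class SpikeSlabPrior:
    """Mixture prior on regression coefficients.

    Parameters may be scalars (shared across coefficients) or arrays of
    length p.  ``p0`` is the prior probability of *exclusion*
    (gamma_j = 0); ``mu``/``nu`` are the slab mean and variance, on the
    standardized-predictor scale.

    The default ``p0 = 0.9`` encodes the sparsity premise of band
    selection — a prior expected model size of one predictor in ten.  A
    non-sparse prior (say 0.5) lets many spurious slab coefficients ride
    along in every draw when p is comparable to n, which visibly deflates
    the residual-variance posterior.
    """

    p0: float | np.ndarray = 0.9
    mu: float | np.ndarray = 0.0
    nu: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.p0) <= 0) or np.any(np.asarray(self.p0) >= 1):
            raise ValueError("p0 must lie strictly in (0, 1)")
        if np.any(np.asarray(self.nu) <= 0):
            raise ValueError("slab variance nu must be > 0")

    def expand(self, p: int) -> tuple:
        """Broadcast (p0, mu, nu) to length-p arrays."""
        return (
            np.broadcast_to(np.asarray(self.p0, float), (p,)).copy(),
            np.broadcast_to(np.asarray(self.mu, float), (p,)).copy(),
            np.broadcast_to(np.asarray(self.nu, float), (p,)).copy(),
        )


@dataclass
class VariancePrior:
    """Inverse-gamma prior IG(alpha, eta) in shape/rate parametrization."""

    alpha: float = 0.01
    eta: float = 0.01

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.eta <= 0:
            raise ValueError("inverse-gamma hyper-parameters must be > 0")


@dataclass
class PhiPrior:
    """Uniform prior U(lo, hi) on the spatial-dependence parameter."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("phi prior requires lo < hi")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass
class MCMCConfig:
    """Chain-length and tuning settings for the Gibbs/MH sampler.

    Defaults mirror the full analysis protocol (100k iterations, first
    half discarded, keep one draw in five); ``reduced()`` gives the
    desk-scale protocol used for simulation checks.
    """

    n_iter: int = 100_000
    burn_in: int = 50_000
    thin: int = 5
    seed: int = 0
    phi_proposal_sd: float = 0.25
    adapt_phi: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @classmethod
    def reduced(cls, seed: int = 0, **kwargs) -> "MCMCConfig":
        kwargs.setdefault("n_iter", 10_000)
        kwargs.setdefault("burn_in", 5_000)
        kwargs.setdefault("thin", 5)
        return cls(seed=seed, **kwargs)
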