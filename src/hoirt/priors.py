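"""Prior and MCMC run configuration.

Priors follow the hierarchical Bayesian formulation of the model:

* mu_(g) ~ MVN(0, Sigma_H) with Sigma_H a correlation matrix whose
  off-diagonal elements are 0.5;
* sigma2_(g)(d) ~ Uniform(sigma2_bounds)  (default (0, 5): the support must
  cover group variances above 1, which arise whenever a non-anchor group is
  more heterogeneous than the anchor);
* lam_(g)(d) ~ Uniform(-1, 1);
* omega_i(g) ~ MVN(0, rho_omega_(g)) with unit variances;
* alpha_j, beta_j ~ four-parameter Beta (shapes upsilon, omega; support
  (a, b));
* Sigma_omega_(g) ~ Inverse-Wishart(nu0 = D + 2, scale with unit diagonal
  and 0.2 off-diagonal), transformed to the correlation matrix rho_omega.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ParameterError

__all__ = ["FourBeta", "PriorConfig", "MCMCConfig", "log_prior_item"]


@dataclass(frozen=True)
class FourBeta:
    """Four-parameter Beta: shapes (upsilon, omega) on support (a, b)."""

    upsilon: float
    omega: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.upsilon <= 0 or self.omega <= 0:
            raise ParameterError("4Beta shape parameters must be positive")
        if not self.a < self.b:
            raise ParameterError("4Beta support requires a < b")

    def logpdf(self, x) -> np.ndarray:
        """Log density; -inf outside (a, b)."""
        return stats.beta.logpdf(np.asarray(x, dtype=float), self.upsilon,
                                 self.omega, loc=self.a, scale=self.b - self.a)

    def rvs(self, size, rng: np.random.Generator) -> np.ndarray:
        return self.a + (self.b - self.a) * rng.beta(self.upsilon, self.omega,
                                                     size=size)

    @property
    def median(self) -> float:
        return float(stats.beta.ppf(0.5, self.upsilon, self.omega, loc=self.a,
                                    scale=self.b - self.a))


@dataclass
class PriorConfig:
    """Hyperparameters of every prior block.

    The 4Beta hyperparameters default to weakly informative settings that
    comfortably cover typical 2PL item parameters (alpha in (0.2, 2.5),
    beta in (-4, 4)); all are configurable.
    """

    sigma2_bounds: tuple[float, float] = (0.0, 5.0)
    lambda_bounds: tuple[float, float] = (-1.0, 1.0)
    mu_offdiag: float = 0.5
    alpha_4beta: FourBeta = field(default_factory=lambda: FourBeta(1.5, 1.5, 0.2, 2.5))
    beta_4beta: FourBeta = field(default_factory=lambda: FourBeta(1.1, 1.1, -4.0, 4.0))
    iw_df: int | None = None          # defaults to D + 2 at run time
    iw_offdiag: float = 0.2

    def __post_init__(self) -> None:
        lo, hi = self.sigma2_bounds
        if not 0 <= lo < hi:
            raise ParameterError("sigma2_bounds must satisfy 0 <= lo < hi")
        lo, hi = self.lambda_bounds
        if not -1 <= lo < hi <= 1:
            raise ParameterError("lambda_bounds must lie within [-1, 1]")

    def mu_prior_cov(self, D: int) -> np.ndarray:
        """Sigma_H: D x D correlation matrix, off-diagonal mu_offdiag."""
        S = np.full((D, D), self.mu_offdiag)
        np.fill_diagonal(S, 1.0)
        return S

    def iw_scale(self, H: int) -> np.ndarray:
        """Lambda_0: H x H scale with unit diagonal and iw_offdiag off it."""
        S = np.full((H, H), self.iw_offdiag)
        np.fill_diagonal(S, 1.0)
        return S

    def iw_nu0(self, D: int) -> int:
        """Inverse-Wishart degrees of freedom; D + 2 unless overridden."""
        return int(self.iw_df) if self.iw_df is not None else D + 2


@dataclass
class MCMCConfig:
    """Sampler run settings.

    ``model_variant`` is "saturated" (group-specific lam, sigma2, rho_omega),
    "common_covariance" (one shared lam vector, sigma2 fixed at 1 so the
    common covariance is a correlation matrix, one shared rho_omega; group
    means stay free), or "pooled" (common covariance *and* common means --
    every group's mean fixed at the anchor's 0, the "same means and
    covariances across studies" alternate used as a comparison baseline).
    """

    n_chains: int = 2
    n_iter: int = 4000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0
    model_variant: str = "saturated"
    adapt: bool = True
    target_accept: float = 0.35
    proposal_scales: dict = field(default_factory=lambda: {
        "theta": 1.0, "omega": 0.6, "sigma2": 0.3, "lam": 0.08,
        "rho": 0.08, "seesaw": 0.15, "shift": 0.05, "scale": 0.03,
        "alpha": 0.15, "beta": 0.15,
    })
    save_trait_draws: int = 200       # max retained theta/omega draws kept

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ConfigurationError("n_chains must be >= 1")
        if not 0 <= self.burn_in < self.n_iter:
            raise ConfigurationError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        if self.model_variant not in ("saturated", "common_covariance",
                                      "pooled"):
            raise ConfigurationError(
                f"unknown model_variant {self.model_variant!r}")

    @property
    def n_kept(self) -> int:
        """Retained draws per chain: (n_iter - burn_in) // thin."""
        return (self.n_iter - self.burn_in) // self.thin


def log_prior_item(alpha, beta, priors: PriorConfig):
    """Joint 4Beta log prior of one item's (alpha, beta).

    Returns -inf outside either support, which a Metropolis step treats as
    automatic rejection rather than an error.  Broadcasts over arrays.
    """
    return priors.alpha_4beta.logpdf(alpha) + priors.beta_4beta.logpdf(beta)
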