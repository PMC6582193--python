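"""Implied first-order covariance/correlation structure and trait scores.

The higher-order model implies, for each group, a structured covariance
matrix among the D first-order traits: the diagonal is sigma2_(d); the
covariance between two dimensions sharing a second-order component is
sigma_(d) sigma_(d') lam_(d) lam_(d'), and between dimensions on different
components it picks up the second-order correlation,
sigma_(d) sigma_(d') lam_(d) lam_(d') rho_omega(h, h').  On the correlation
scale these reduce to lam lam' and lam lam' rho, which is also the form the
common-covariance (anchor-constrained) model variant takes directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .model import DimensionMap, GroupParameters, PersonTraits

__all__ = ["ImpliedCovariance", "implied_covariance", "implied_correlation",
           "trait_scores", "posterior_implied_matrices"]


@dataclass
class ImpliedCovariance:
    """Per-group D x D implied matrices with a covariance/correlation flag."""

    matrices: np.ndarray            # (G, D, D)
    scale: str                      # "covariance" or "correlation"

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.scale not in ("covariance", "correlation"):
            raise ParameterError(f"unknown scale {self.scale!r}")
        for g, S in enumerate(self.matrices):
            if not np.allclose(S, S.T):
                raise ParameterError(f"implied matrix for group {g} not symmetric")
            if np.linalg.eigvalsh(S).min() < -1e-10:
                raise ParameterError(
                    f"implied matrix for group {g} not positive semidefinite")

    def __getitem__(self, g: int) -> np.ndarray:
        return self.matrices[g]


def implied_covariance(params: GroupParameters,
                       dims: DimensionMap) -> ImpliedCovariance:
    """Model-implied covariance matrices of the first-order traits per group.

    Diagonal sigma2_(d); off-diagonal sigma sigma' lam lam' within a
    second-order component and sigma sigma' lam lam' rho_omega(h,h') across
    components.  (The conditional variance of theta_(d) | omega is the
    smaller sigma2_(d)(1 - lam_(d)^2); marginally the shared omega adds the
    covariance terms back.)
    """
    G, D = params.mu.shape
    comp = dims.loading
    out = np.empty((G, D, D))
    for g in range(G):
        s = np.sqrt(params.sigma2[g])
        lam = params.lam[g]
        rho_hh = params.rho_omega[g][np.ix_(comp, comp)]   # (D, D)
        out[g] = np.outer(s * lam, s * lam) * rho_hh
        np.fill_diagonal(out[g], params.sigma2[g])
    return ImpliedCovariance(matrices=out, scale="covariance")


def implied_correlation(params: GroupParameters,
                        dims: DimensionMap) -> ImpliedCovariance:
    """Implied correlation matrices: the covariance rescaled by 1/(sigma sigma').

    Under the anchor-constrained common-covariance variant (sigma2 = 1)
    this equals lam lam' within a component and lam lam' rho_omega across
    components directly.
    """
    if np.any(params.sigma2 <= 0):
        raise ParameterError("sigma2 must be positive to form correlations")
    cov = implied_covariance(params, dims)
    out = np.empty_like(cov.matrices)
    for g in range(out.shape[0]):
        s = np.sqrt(np.diag(cov.matrices[g]))
        out[g] = cov.matrices[g] / np.outer(s, s)
        np.fill_diagonal(out[g], 1.0)
    return ImpliedCovariance(matrices=out, scale="correlation")


def trait_scores(draws) -> PersonTraits:
    """Expected a posteriori (posterior-mean) trait scores with posterior SDs.

    Works from the online posterior summaries accumulated over every
    retained draw of every chain, so a single retained draw returns that
    draw itself.
    """
    if draws.n_kept == 0:
        raise ParameterError("posterior draws are empty")
    return PersonTraits(theta=draws.theta_mean.copy(),
                        omega=draws.omega_mean.copy(),
                        theta_sd=draws.theta_sd.copy(),
                        omega_sd=draws.omega_sd.copy())


def posterior_implied_matrices(draws, scale: str = "covariance",
                               how: str = "per_draw") -> ImpliedCovariance:
    """Posterior summary of the implied matrices.

    ``how="per_draw"`` (default) reconstructs the matrix at every retained
    draw and averages — the estimand is a nonlinear function of the
    structural parameters, so this differs from plugging in posterior means,
    which ``how="plugin"`` provides for comparison.
    """
    dims = draws.dims
    comp = dims.loading
    if how == "plugin":
        params = draws.group_parameters()
        fn = implied_covariance if scale == "covariance" else implied_correlation
        return fn(params, dims)
    if how != "per_draw":
        raise ParameterError(f"unknown mode {how!r}")
    C, K, G, D = draws.lam.shape
    lam = draws.lam.reshape(-1, G, D)
    sig2 = draws.sigma2.reshape(-1, G, D)
    rho = draws.rho.reshape(-1, G, *draws.rho.shape[3:])
    acc = np.zeros((G, D, D))
    n = lam.shape[0]
    for t in range(n):
        s = np.sqrt(sig2[t])
        for g in range(G):
            rho_hh = rho[t, g][np.ix_(comp, comp)]
            S = np.outer(s[g] * lam[t, g], s[g] * lam[t, g]) * rho_hh
            np.fill_diagonal(S, sig2[t, g])
            if scale == "correlation":
                ss = np.sqrt(np.diag(S))
                S = S / np.outer(ss, ss)
                np.fill_diagonal(S, 1.0)
            acc[g] += S
    acc /= n
    # averaging preserves PSD (convex combination of PSD matrices)
    return ImpliedCovariance(matrices=acc, scale=scale)
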