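"""Core domain types and the 2PL multi-unidimensional higher-order IRT model.

The measurement model is a two-parameter logistic (2PL) item response
function in which every item loads on exactly one of D first-order latent
dimensions ("multi-unidimensional").  The first-order traits theta are in
turn generated by H second-order traits omega through group-specific linear
loadings:

    theta_{i(g)(d)} | omega  ~  N( mu_{(g)(d)} + lam_{(g)(d)} * sigma_{(g)(d)}
                                   * omega_{i(g)(h(d))},
                                   sigma2_{(g)(d)} * (1 - lam_{(g)(d)}^2) )

so that when omega has unit variance the marginal variance of theta is
exactly sigma2.  Groups (studies) share item parameters; one anchor group
has mu = 0 and sigma2 = 1 to resolve the latent-metric indeterminacy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ParameterError, ShapeError

__all__ = [
    "ItemBank",
    "DimensionMap",
    "ResponseMatrix",
    "GroupParameters",
    "PersonTraits",
    "response_probability",
    "log_likelihood",
    "theta_conditional_density",
]

#: probabilities are clamped to [EPS, 1-EPS] before taking logs
EPS = 1e-12


@dataclass
class ItemBank:
    """Item parameters and item -> first-order-dimension assignment.

    Parameters
    ----------
    item_id
        Item labels, length J.
    dimension
        0-based first-order dimension index of each item, length J.
    discrimination
        Slope alpha_j > 0 of each item.
    difficulty
        Location beta_j of each item.
    """

    item_id: list[str]
    dimension: np.ndarray
    discrimination: np.ndarray
    difficulty: np.ndarray

    def __post_init__(self) -> None:
        self.dimension = np.asarray(self.dimension, dtype=int)
        self.discrimination = np.asarray(self.discrimination, dtype=float)
        self.difficulty = np.asarray(self.difficulty, dtype=float)
        J = len(self.item_id)
        if not (self.dimension.shape == self.discrimination.shape
                == self.difficulty.shape == (J,)):
            raise ShapeError("item_id, dimension, discrimination and difficulty "
                             "must all have the same length")
        if len(set(self.item_id)) != J:
            raise ParameterError("duplicate item ids in item bank")
        if np.any(self.discrimination <= 0):
            bad = [self.item_id[k] for k in np.flatnonzero(self.discrimination <= 0)]
            raise ParameterError(f"non-positive discrimination for items {bad}")

    @property
    def n_items(self) -> int:
        return len(self.item_id)

    def items_per_dimension(self, D: int | None = None) -> np.ndarray:
        """J(d): item count per dimension; their sum equals J."""
        D = int(self.dimension.max()) + 1 if D is None else D
        return np.bincount(self.dimension, minlength=D)


@dataclass
class DimensionMap:
    """First-order -> second-order dimension structure.

    ``loading[d]`` gives the 0-based second-order component h on which
    first-order dimension d loads.  H = 1, 2 and >= 3 correspond to the
    univariate, bivariate and general multivariate model variants.
    """

    D: int
    H: int
    loading: np.ndarray

    def __post_init__(self) -> None:
        self.loading = np.asarray(self.loading, dtype=int)
        if self.loading.shape != (self.D,):
            raise ShapeError(f"loading must have length D={self.D}")
        if np.any((self.loading < 0) | (self.loading >= self.H)):
            raise ParameterError("loading entries must be in 0..H-1")
        present = np.unique(self.loading)
        if len(present) != self.H:
            missing = sorted(set(range(self.H)) - set(present.tolist()))
            raise ParameterError(f"second-order components {missing} have no "
                                 "first-order dimension loading on them")

    @property
    def k(self) -> int:
        """Number of first-order dimensions loading on the first component."""
        return int(np.sum(self.loading == 0))


@dataclass
class ResponseMatrix:
    """Binary person x item responses with missingness mask and group labels.

    ``X`` is 0/1 wherever ``observed`` is True; masked cells are ignored by
    the likelihood (missing-at-random).  ``group`` holds 0-based group
    indices; ``group_labels`` maps them back to the user-facing labels.
    """

    X: np.ndarray
    observed: np.ndarray
    group: np.ndarray
    group_labels: list[str] = field(default_factory=list)
    item_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.observed = np.asarray(self.observed, dtype=bool)
        self.group = np.asarray(self.group, dtype=int)
        if self.X.shape != self.observed.shape:
            raise ShapeError("X and observed must have identical shapes")
        if self.group.shape != (self.X.shape[0],):
            raise ShapeError("group must have one entry per person")
        vals = self.X[self.observed]
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ParameterError("observed responses must be 0 or 1")
        if not self.group_labels:
            self.group_labels = [str(g + 1) for g in range(self.n_groups)]
        if not self.item_ids:
            self.item_ids = [f"item{j + 1}" for j in range(self.n_items)]

    @property
    def n_persons(self) -> int:
        return self.X.shape[0]

    @property
    def n_items(self) -> int:
        return self.X.shape[1]

    @property
    def n_groups(self) -> int:
        return int(self.group.max()) + 1 if self.group.size else 0

    @property
    def N_g(self) -> np.ndarray:
        """Per-group person counts; sums to the total person count."""
        return np.bincount(self.group, minlength=self.n_groups)


@dataclass
class GroupParameters:
    """Structural parameters of all G groups.

    mu, sigma2 and lam are (G, D) arrays; rho_omega is a (G, H, H) stack of
    correlation matrices; sigma_omega holds the transient inverse-Wishart
    covariance draws used by the correlation sampler and has no model-level
    meaning.  The anchor group has mu = 0 and sigma2 = 1 identically.
    """

    mu: np.ndarray
    sigma2: np.ndarray
    lam: np.ndarray
    rho_omega: np.ndarray
    anchor: np.ndarray
    sigma_omega: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.rho_omega = np.asarray(self.rho_omega, dtype=float)
        self.anchor = np.asarray(self.anchor, dtype=bool)
        G, D = self.mu.shape
        if self.sigma2.shape != (G, D) or self.lam.shape != (G, D):
            raise ShapeError("mu, sigma2 and lam must all be (G, D)")
        if self.rho_omega.ndim != 3 or self.rho_omega.shape[0] != G:
            raise ShapeError("rho_omega must be (G, H, H)")
        if self.anchor.shape != (G,):
            raise ShapeError("anchor must be a length-G boolean vector")
        if not self.anchor.any():
            raise ParameterError("at least one group must be the anchor")
        if np.any(self.sigma2 <= 0):
            raise ParameterError("sigma2 must be strictly positive")
        if np.any(np.abs(self.lam) >= 1):
            raise ParameterError("|lam| must be < 1")
        for g in range(G):
            R = self.rho_omega[g]
            if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
                raise ParameterError(f"rho_omega[{g}] is not a correlation matrix")
            if np.linalg.eigvalsh(R).min() <= 0:
                raise ParameterError(f"rho_omega[{g}] is not positive definite")
        if self.anchor.any():
            a = np.flatnonzero(self.anchor)
            if not (np.allclose(self.mu[a], 0.0) and np.allclose(self.sigma2[a], 1.0)):
                raise ParameterError("anchor group must have mu = 0 and sigma2 = 1")

    @property
    def n_groups(self) -> int:
        return self.mu.shape[0]

    @property
    def n_dimensions(self) -> int:
        return self.mu.shape[1]

    @property
    def n_components(self) -> int:
        return self.rho_omega.shape[1]


@dataclass
class PersonTraits:
    """Per-person first-order (theta) and second-order (omega) trait scores.

    When produced as posterior summaries, ``theta_sd``/``omega_sd`` hold the
    posterior standard deviations alongside the posterior-mean scores.
    """

    theta: np.ndarray
    omega: np.ndarray
    theta_sd: np.ndarray | None = None
    omega_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.theta.shape[0] != self.omega.shape[0]:
            raise ShapeError("theta and omega must cover the same persons")


def response_probability(theta_value, alpha, beta):
    """Probability of endorsing an item under the 2PL model.

    Evaluates  exp[alpha (theta - beta)] / (1 + exp[alpha (theta - beta)])
    through a numerically stable logistic, so large |alpha (theta - beta)|
    neither overflows nor underflows to an exact 0/1 log argument.
    Broadcasts over array inputs.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ParameterError("discrimination alpha must be strictly positive")
    z = alpha * (np.asarray(theta_value, dtype=float) - np.asarray(beta, dtype=float))
    return stats.logistic.cdf(z)


def _bernoulli_loglik_cells(X, observed, z):
    """Per-cell log-likelihood x*z - log(1+e^z), zero where unobserved."""
    # stable softplus: log(1 + e^z) = max(z, 0) + log1p(e^{-|z|})
    sp = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    ll = X * z - sp
    return np.where(observed, ll, 0.0)


def log_likelihood(data: ResponseMatrix, traits: PersonTraits,
                   items: ItemBank) -> float:
    """Observed-data log-likelihood of a binary response matrix.

    Sums x*log(p) + (1-x)*log(1-p) over observed cells only; missing cells
    contribute zero (missing-at-random).  The probability for cell (i, j)
    uses the theta component of the item's own dimension, so the total
    decomposes additively over groups and over dimensions.
    """
    if traits.theta.shape[0] != data.n_persons:
        raise ShapeError("traits cover a different number of persons than data")
    if items.n_items != data.n_items:
        raise ShapeError("item bank size differs from the response matrix")
    if items.dimension.max(initial=-1) >= traits.theta.shape[1]:
        raise ShapeError("item bank references dimensions missing from traits")
    th = traits.theta[:, items.dimension]                       # (N, J)
    z = items.discrimination * (th - items.difficulty)
    Xf = np.where(data.observed, data.X, 0).astype(float)
    return float(_bernoulli_loglik_cells(Xf, data.observed, z).sum())


def theta_conditional_density(theta_value, omega_value, mu, sigma2, lam):
    """Density of a first-order trait given its second-order trait.

    theta | omega ~ N(mu + lam*sigma*omega, sigma2*(1 - lam^2)); with omega
    of unit variance the marginal variance of theta is sigma2.  Broadcasts.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(sigma2 <= 0):
        raise ParameterError("sigma2 must be strictly positive")
    if np.any(np.abs(lam) >= 1):
        raise ParameterError("|lam| must be < 1")
    mean = np.asarray(mu, dtype=float) + lam * np.sqrt(sigma2) * np.asarray(
        omega_value, dtype=float)
    var = sigma2 * (1.0 - lam ** 2)
    return stats.norm.pdf(np.asarray(theta_value, dtype=float), loc=mean,
                          scale=np.sqrt(var))
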