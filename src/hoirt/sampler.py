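"""Metropolis-Hastings-within-Gibbs sampler for the multi-group HO-IRT model.

One sweep updates, in fixed order:

1. theta   -- element-wise random-walk MH against item likelihood x
              hierarchical normal prior;
2. omega   -- element-wise random-walk MH against MVN(0, rho_omega) prior x
              theta-conditional terms;
3. mu      -- exact Gibbs draw from its MVN full conditional (non-anchor
              groups only; the anchor group keeps mu = 0, sigma2 = 1);
4. sigma2  -- random-walk MH on (0, hi) support (skipped when the
              common-covariance variant fixes sigma2 = 1);
5. lam     -- random-walk MH on (-1, 1); pooled across groups under the
              common-covariance variant;
6. rho_omega -- parameter-expansion step: inverse-Wishart Gibbs draw of
              Sigma_omega, rescaled to a provisional correlation matrix and
              accepted or rejected by a Metropolis-Hastings ratio;
7. (alpha, beta) -- joint per-item random-walk MH with 4Beta priors;

followed by a deterministic sign alignment that keeps the loading of the
first dimension of every second-order component positive (the likelihood is
invariant under jointly flipping a lam block and its omega column, so the
posterior is sign-symmetric without this policy).

The per-block loops are vectorised over persons / items / dimensions; each
vectorised update is the plain symmetric random-walk Metropolis kernel that
:func:`mh_update_block` implements for a single block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ParameterError, ShapeError
from .model import (DimensionMap, GroupParameters, ItemBank, PersonTraits,
                    ResponseMatrix)
from .priors import MCMCConfig, PriorConfig, log_prior_item

__all__ = [
    "ChainState",
    "PosteriorDraws",
    "draw_mu",
    "mh_update_block",
    "draw_rho_omega",
    "sweep",
    "run_chains",
]


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


@dataclass
class _Layout:
    """Precomputed index structures shared by every sweep on one dataset."""

    Xf: np.ndarray                  # (N, J) float 0/1, 0 where missing
    M: np.ndarray                   # (N, J) bool observed mask
    dim_of_item: np.ndarray         # (J,)
    items_by_dim: list[np.ndarray]
    group: np.ndarray               # (N,)
    persons_by_group: list[np.ndarray]
    comp_of_dim: np.ndarray         # (D,)
    first_dim_of_comp: np.ndarray   # (H,)
    D: int
    H: int
    G: int

    @classmethod
    def build(cls, data: ResponseMatrix, items: ItemBank,
              dims: DimensionMap) -> "_Layout":
        if items.n_items != data.n_items:
            raise ShapeError("item bank size differs from response matrix")
        if items.dimension.max() >= dims.D:
            raise ShapeError("item bank references a dimension outside the map")
        obs_per_item = data.observed.sum(axis=0)
        if np.any(obs_per_item == 0):
            j = int(np.argmin(obs_per_item))
            raise ConfigurationError(
                f"item {data.item_ids[j]!r} has no observed responses")
        obs_per_person = data.observed.sum(axis=1)
        if np.any(obs_per_person == 0):
            i = int(np.argmin(obs_per_person))
            raise ConfigurationError(f"person at row {i} has no observed responses")
        G = data.n_groups
        dim = items.dimension
        first = np.array([int(np.flatnonzero(dims.loading == h)[0])
                          for h in range(dims.H)])
        return cls(
            Xf=np.where(data.observed, data.X, 0).astype(float),
            M=data.observed.astype(bool),
            dim_of_item=dim,
            items_by_dim=[np.flatnonzero(dim == d) for d in range(dims.D)],
            group=data.group,
            persons_by_group=[np.flatnonzero(data.group == g) for g in range(G)],
            comp_of_dim=dims.loading,
            first_dim_of_comp=first,
            D=dims.D, H=dims.H, G=G,
        )

    @property
    def n_persons(self) -> int:
        return self.Xf.shape[0]

    @property
    def n_items(self) -> int:
        return self.Xf.shape[1]


@dataclass
class ChainState:
    """Full parameter state of one chain plus cached likelihood terms."""

    theta: np.ndarray               # (N, D)
    omega: np.ndarray               # (N, H)
    mu: np.ndarray                  # (G, D)
    sigma2: np.ndarray              # (G, D)
    lam: np.ndarray                 # (G, D)
    rho: np.ndarray                 # (G, H, H)
    alpha: np.ndarray               # (J,)
    beta: np.ndarray                # (J,)
    anchor: np.ndarray              # (G,) bool
    ll_cell: np.ndarray             # (N, J) cached per-cell log-likelihood
    layout: _Layout
    scales: dict = field(default_factory=dict)
    accepted: dict = field(default_factory=dict)
    proposed: dict = field(default_factory=dict)

    def log_likelihood(self) -> float:
        """Total observed-data log-likelihood from the cell cache."""
        return float(self.ll_cell.sum())

    def structural_loglik(self) -> float:
        """Log density of the latent layers: sum of log P(theta | omega,
        structure) and log P(omega | rho) over persons.  Added to the item
        log-likelihood this gives the complete-data log-likelihood whose
        deviance registers structural misfit (the item-conditional deviance
        alone does not)."""
        lay = self.layout
        total = 0.0
        for g in range(lay.G):
            pg = lay.persons_by_group[g]
            om = self.omega[np.ix_(pg, lay.comp_of_dim)]
            v = self.sigma2[g] * (1.0 - self.lam[g] ** 2)
            mean = self.mu[g] + self.lam[g] * np.sqrt(self.sigma2[g]) * om
            resid = self.theta[pg] - mean
            n = len(pg)
            total += float(-0.5 * (n * np.log(2 * np.pi * v).sum()
                                   + (resid ** 2 / v).sum()))
            W = self.omega[pg]
            sign, logdet = np.linalg.slogdet(self.rho[g])
            P = np.linalg.inv(self.rho[g])
            total += float(-0.5 * (n * (lay.H * np.log(2 * np.pi) + logdet)
                                   + np.einsum("ij,jk,ik->", W, P, W)))
        return total

    def recompute_ll_cell(self) -> np.ndarray:
        """Cell log-likelihoods from scratch (tests compare to the cache)."""
        lay = self.layout
        th = self.theta[:, lay.dim_of_item]
        z = self.alpha * (th - self.beta)
        ll = lay.Xf * z - _softplus(z)
        return np.where(lay.M, ll, 0.0)

    def _count(self, block: str, acc: int, prop: int) -> None:
        self.accepted[block] = self.accepted.get(block, 0) + acc
        self.proposed[block] = self.proposed.get(block, 0) + prop


def draw_mu(theta_bar: np.ndarray, N_g: int, Sigma_g: np.ndarray,
            priors: PriorConfig, rng: np.random.Generator) -> np.ndarray:
    """Exact Gibbs draw of a group mean vector from its MVN full conditional.

    With prior mu ~ MVN(mu0 = 0, Lambda0) and theta-residual likelihood of
    sample mean ``theta_bar`` under covariance ``Sigma_g``:

        Sigma1 = (Lambda0^-1 + N Sigma^-1)^-1
        mu1    = Sigma1 (Lambda0^-1 mu0 + N Sigma^-1 theta_bar)

    When N_g = 0 the posterior equals the prior.
    """
    theta_bar = np.asarray(theta_bar, dtype=float)
    D = theta_bar.shape[0]
    L0 = priors.mu_prior_cov(D)
    if N_g == 0:
        Sigma1, mu1 = L0, np.zeros(D)
    else:
        try:
            L0inv = np.linalg.inv(L0)
            Sinv = np.linalg.inv(np.asarray(Sigma_g, dtype=float))
            Sigma1 = np.linalg.inv(L0inv + N_g * Sinv)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                f"singular trait covariance in mu update (N_g={N_g}): {e}") from e
        mu1 = Sigma1 @ (N_g * (Sinv @ theta_bar))
    L = np.linalg.cholesky(Sigma1)
    return mu1 + L @ rng.standard_normal(D)


def mh_update_block(current_values, log_target, proposal_scale,
                    rng: np.random.Generator):
    """One symmetric random-walk Metropolis step for a parameter block.

    Proposes current + scale * N(0, I) and accepts with probability
    min(1, exp(delta log target)).  ``log_target`` must be finite at the
    current state; -inf at the proposal is an automatic rejection.
    """
    cur = np.asarray(current_values, dtype=float)
    lt_cur = float(log_target(cur))
    if not np.isfinite(lt_cur):
        raise ParameterError("log target is not finite at the current state")
    prop = cur + proposal_scale * rng.standard_normal(cur.shape)
    lt_prop = float(log_target(prop))
    if np.log(rng.random()) < lt_prop - lt_cur:
        return prop, True
    return cur, False


def _mvn_loglik_zero_mean(S: np.ndarray, n: int, C: np.ndarray) -> float:
    """Log-likelihood (up to a constant) of n MVN(0, C) rows with scatter S."""
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        return -np.inf
    return -0.5 * (n * logdet + np.trace(np.linalg.solve(C, S)))


def correlation_log_prior(R: np.ndarray, nu0: int) -> float:
    """Log prior density (unnormalised) of a correlation matrix.

    The prior is the exact marginal distribution of the correlation matrix
    of Sigma_omega ~ Inverse-Wishart(nu0, diagonal scale): integrating the
    redundant variance scales out of the inverse-Wishart density gives

        pi(R)  propto  |R|^{-(nu0+H+1)/2}  prod_h [(R^-1)_hh]^{-nu0/2},

    which for H = 2 reduces to (1 - rho^2)^{(nu0-H+1)/2 - 1} -- a proper,
    symmetric, weakly informative density.  (Any diagonal scale matrix
    induces the same marginal; an off-diagonal scale element has no
    tractable closed form and would only tilt the prior slightly.)
    Returns -inf for a non-positive-definite matrix.
    """
    H = R.shape[0]
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        return -np.inf
    Rinv = np.linalg.inv(R)
    return (-(nu0 + H + 1) / 2.0 * logdet
            - nu0 / 2.0 * float(np.sum(np.log(np.diag(Rinv)))))


def draw_rho_omega(omega_draws: np.ndarray, priors: PriorConfig,
                   current_rho: np.ndarray, rng: np.random.Generator,
                   scale: float = 0.05, nu0: int | None = None):
    """Metropolis update of a second-order correlation matrix.

    The target is p(R | omega) proportional to pi(R) N(omega; 0, R) with
    pi the inverse-Wishart-induced correlation prior of
    :func:`correlation_log_prior`.  Each free (upper-triangle) entry gets a
    symmetric random-walk proposal; candidates that are not positive
    definite (or leave [-1, 1]) have zero prior density and are rejected,
    so the returned matrix is always a valid correlation matrix.

    A literal parameter-expansion move (inverse-Wishart Gibbs draw of
    Sigma_omega, rescaled and Metropolis-corrected) is stationary-correct
    but practically non-ergodic here: omega's scale is pinned by the
    lam*sigma*omega regression, so the expanded target concentrates the
    redundant scales near the prior while the inverse-Wishart conditional
    proposes them near omega's sample variances, and the independence
    sampler traps.  The entry-wise walk targets the same correlation
    posterior without the redundant scales.

    Returns ``(rho, n_accepted, n_proposed)``.  H = 1 is the degenerate
    identity case.
    """
    W = np.asarray(omega_draws, dtype=float)
    n, H = W.shape
    if H == 1:
        return np.ones((1, 1)), 0, 0
    nu0 = priors.iw_nu0(H) if nu0 is None else nu0
    S = W.T @ W
    R = np.asarray(current_rho, dtype=float).copy()

    def log_target(Rm):
        lp = correlation_log_prior(Rm, nu0)
        if not np.isfinite(lp):
            return -np.inf
        return lp + _mvn_loglik_zero_mean(S, n, Rm)

    lt_cur = log_target(R)
    acc = 0
    n_pairs = 0
    for h1 in range(H):
        for h2 in range(h1 + 1, H):
            n_pairs += 1
            cand = R.copy()
            step = scale * rng.standard_normal()
            cand[h1, h2] = cand[h2, h1] = R[h1, h2] + step
            if abs(cand[h1, h2]) >= 1:
                continue
            lt_cand = log_target(cand)
            if np.log(rng.random()) < lt_cand - lt_cur:
                R = cand
                lt_cur = lt_cand
                acc += 1
    return R, acc, n_pairs


# ---------------------------------------------------------------------------
# vectorised block updates used inside a sweep
# ---------------------------------------------------------------------------

def _update_theta(st: ChainState, rng: np.random.Generator) -> None:
    lay = st.layout
    g = lay.group
    for d in range(lay.D):
        cols = lay.items_by_dim[d]
        om = st.omega[:, lay.comp_of_dim[d]]
        m = st.mu[g, d] + st.lam[g, d] * np.sqrt(st.sigma2[g, d]) * om
        v = st.sigma2[g, d] * (1.0 - st.lam[g, d] ** 2)
        cur = st.theta[:, d]
        prop = cur + st.scales["theta"] * rng.standard_normal(cur.shape)
        z = st.alpha[cols] * (prop[:, None] - st.beta[cols])
        llp_cells = np.where(lay.M[:, cols],
                             lay.Xf[:, cols] * z - _softplus(z), 0.0)
        delta = (llp_cells.sum(axis=1) - st.ll_cell[:, cols].sum(axis=1)
                 + ((cur - m) ** 2 - (prop - m) ** 2) / (2.0 * v))
        acc = np.log(rng.random(cur.shape)) < delta
        st.theta[acc, d] = prop[acc]
        st.ll_cell[np.ix_(np.flatnonzero(acc), cols)] = llp_cells[acc]
        st._count("theta", int(acc.sum()), acc.size)


def _implied_cov(sigma2_row: np.ndarray, lam_row: np.ndarray,
                 rho_g: np.ndarray, comp: np.ndarray) -> np.ndarray:
    """Model-implied D x D trait covariance for one group.

    Marginalising omega out of theta = mu + lam sigma omega + eps gives
    theta ~ MVN(mu, C) with C_dd = sigma2_d and C_dd' =
    sigma_d sigma_d' lam_d lam_d' rho(h_d, h_d'); this is the matrix the
    structural full conditionals are evaluated against.
    """
    sl = np.sqrt(sigma2_row) * lam_row
    C = np.outer(sl, sl) * rho_g[np.ix_(comp, comp)]
    np.fill_diagonal(C, sigma2_row)
    return C


def _group_moments(st: ChainState) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """(n_g, sum theta_i, sum theta_i theta_i') per group, computed once per
    sweep after the theta update."""
    out = []
    for pg in st.layout.persons_by_group:
        th = st.theta[pg]
        out.append((len(pg), th.sum(axis=0), th.T @ th))
    return out


def _scatter_about(mom, mu: np.ndarray) -> np.ndarray:
    n, msum, S0 = mom
    return S0 - np.outer(msum, mu) - np.outer(mu, msum) + n * np.outer(mu, mu)


def _marg_ll(st: ChainState, g: int, mom, sigma2_row, lam_row, rho_g) -> float:
    """Marginal MVN log-likelihood of group g's theta (omega integrated)."""
    W = _scatter_about(mom[g], st.mu[g])
    C = _implied_cov(sigma2_row, lam_row, rho_g, st.layout.comp_of_dim)
    return _mvn_loglik_zero_mean(W, mom[g][0], C)


def _update_mu(st: ChainState, priors: PriorConfig, rng: np.random.Generator,
               mom, pooled: bool = False) -> None:
    """Exact Gibbs draw of each non-anchor group mean against the marginal
    MVN model theta ~ MVN(mu, C) with C the implied trait covariance.
    Under the pooled variant every mean stays fixed at the anchor's 0."""
    if pooled:
        return
    for g in range(st.layout.G):
        if st.anchor[g]:
            continue
        n, msum, _ = mom[g]
        C = _implied_cov(st.sigma2[g], st.lam[g], st.rho[g],
                         st.layout.comp_of_dim)
        st.mu[g] = draw_mu(msum / n, n, C, priors, rng)


def _update_sigma2(st: ChainState, priors: PriorConfig,
                   rng: np.random.Generator, mom) -> None:
    lo, hi = priors.sigma2_bounds
    for g in range(st.layout.G):
        if st.anchor[g]:
            continue
        ll_cur = _marg_ll(st, g, mom, st.sigma2[g], st.lam[g], st.rho[g])
        for d in range(st.layout.D):
            prop = st.sigma2[g, d] + st.scales["sigma2"] * rng.standard_normal()
            if not lo < prop < hi:
                st._count("sigma2", 0, 1)
                continue
            s2 = st.sigma2[g].copy()
            s2[d] = prop
            ll_prop = _marg_ll(st, g, mom, s2, st.lam[g], st.rho[g])
            if np.log(rng.random()) < ll_prop - ll_cur:
                st.sigma2[g, d] = prop
                ll_cur = ll_prop
                st._count("sigma2", 1, 1)
            else:
                st._count("sigma2", 0, 1)


def _lam_ll(st: ChainState, mom, lam_rows, common: bool) -> float:
    """Marginal log-likelihood as a function of the loadings (summed over
    groups under the common-covariance variant)."""
    if common:
        return sum(_marg_ll(st, g, mom, st.sigma2[g], lam_rows, st.rho[g])
                   for g in range(st.layout.G))
    raise AssertionError("per-group path handled inline")


def _update_lam(st: ChainState, priors: PriorConfig, rng: np.random.Generator,
                common: bool, mom) -> None:
    lo, hi = priors.lambda_bounds
    if common:
        ll_cur = _lam_ll(st, mom, st.lam[0], True)
        for d in range(st.layout.D):
            prop = st.lam[0, d] + st.scales["lam"] * rng.standard_normal()
            if not lo < prop < hi:
                st._count("lam", 0, 1)
                continue
            row = st.lam[0].copy()
            row[d] = prop
            ll_prop = _lam_ll(st, mom, row, True)
            if np.log(rng.random()) < ll_prop - ll_cur:
                st.lam[:, d] = prop
                ll_cur = ll_prop
                st._count("lam", 1, 1)
            else:
                st._count("lam", 0, 1)
        return
    for g in range(st.layout.G):
        ll_cur = _marg_ll(st, g, mom, st.sigma2[g], st.lam[g], st.rho[g])
        for d in range(st.layout.D):
            prop = st.lam[g, d] + st.scales["lam"] * rng.standard_normal()
            if not lo < prop < hi:
                st._count("lam", 0, 1)
                continue
            row = st.lam[g].copy()
            row[d] = prop
            ll_prop = _marg_ll(st, g, mom, st.sigma2[g], row, st.rho[g])
            if np.log(rng.random()) < ll_prop - ll_cur:
                st.lam[g, d] = prop
                ll_cur = ll_prop
                st._count("lam", 1, 1)
            else:
                st._count("lam", 0, 1)


def _update_lam_seesaw(st: ChainState, priors: PriorConfig,
                       rng: np.random.Generator, common: bool, mom) -> None:
    """Ridge move: lam_a -> e^v lam_a, lam_b -> e^-v lam_b for a pair of
    dimensions on one component.  Within-component products lam_a lam_b
    (which the implied covariances identify strongly) are preserved while
    the weakly identified ratio direction is traversed directly.  The map
    has unit Jacobian and v is symmetric, so the bare target ratio is the
    acceptance probability."""
    lay = st.layout
    lo, hi = priors.lambda_bounds
    s = st.scales["seesaw"]
    groups = [0] if common else range(lay.G)
    for g in groups:
        for h in range(lay.H):
            dims_h = np.flatnonzero(lay.comp_of_dim == h)
            if len(dims_h) < 2:
                continue
            n_pairs = 1 if len(dims_h) == 2 else len(dims_h)
            for i in range(n_pairs):
                da, db = dims_h[i], dims_h[(i + 1) % len(dims_h)]
                u = float(np.exp(s * rng.standard_normal()))
                la, lb = st.lam[g, da] * u, st.lam[g, db] / u
                if not (lo < la < hi and lo < lb < hi):
                    st._count("seesaw", 0, 1)
                    continue
                row = st.lam[g].copy()
                row[da], row[db] = la, lb
                if common:
                    delta = (_lam_ll(st, mom, row, True)
                             - _lam_ll(st, mom, st.lam[0], True))
                else:
                    delta = (_marg_ll(st, g, mom, st.sigma2[g], row, st.rho[g])
                             - _marg_ll(st, g, mom, st.sigma2[g], st.lam[g],
                                        st.rho[g]))
                if np.log(rng.random()) < delta:
                    if common:
                        st.lam[:, da] = la
                        st.lam[:, db] = lb
                    else:
                        st.lam[g, da] = la
                        st.lam[g, db] = lb
                    st._count("seesaw", 1, 1)
                else:
                    st._count("seesaw", 0, 1)


def _rho_ll(st: ChainState, mom, rho_m: np.ndarray, common: bool,
            g: int | None) -> float:
    if common:
        return sum(_marg_ll(st, gg, mom, st.sigma2[gg], st.lam[gg], rho_m)
                   for gg in range(st.layout.G))
    return _marg_ll(st, g, mom, st.sigma2[g], st.lam[g], rho_m)


def _update_rho(st: ChainState, priors: PriorConfig, rng: np.random.Generator,
                common: bool, mom) -> None:
    """Entry-wise Metropolis walk on each correlation matrix against the
    marginal trait likelihood and the inverse-Wishart-induced correlation
    prior of :func:`correlation_log_prior`."""
    lay = st.layout
    if lay.H == 1:
        return
    nu0 = priors.iw_nu0(lay.D)
    groups = [0] if common else range(lay.G)
    for g in groups:
        lp_cur = correlation_log_prior(st.rho[g], nu0)
        ll_cur = _rho_ll(st, mom, st.rho[g], common, g)
        for h1 in range(lay.H):
            for h2 in range(h1 + 1, lay.H):
                cand = st.rho[g].copy()
                step = st.scales["rho"] * rng.standard_normal()
                cand[h1, h2] = cand[h2, h1] = st.rho[g, h1, h2] + step
                if abs(cand[h1, h2]) >= 1:
                    st._count("rho", 0, 1)
                    continue
                lp_cand = correlation_log_prior(cand, nu0)
                if not np.isfinite(lp_cand):
                    st._count("rho", 0, 1)
                    continue
                ll_cand = _rho_ll(st, mom, cand, common, g)
                if np.log(rng.random()) < (lp_cand + ll_cand
                                           - lp_cur - ll_cur):
                    if common:
                        st.rho[:] = cand
                    else:
                        st.rho[g] = cand
                    lp_cur, ll_cur = lp_cand, ll_cand
                    st._count("rho", 1, 1)
                else:
                    st._count("rho", 0, 1)


def _draw_omega(st: ChainState, rng: np.random.Generator) -> None:
    """Exact conjugate Gibbs draw of every person's second-order traits.

    Given theta and the structural parameters, omega_i is MVN with
    precision rho^-1 + M (M diagonal with sum_d lam^2/(1-lam^2) per
    component) -- the regeneration step that makes the marginalised
    structural updates a valid partially collapsed Gibbs scheme.
    """
    lay = st.layout
    H = lay.H
    for g in range(lay.G):
        pg = lay.persons_by_group[g]
        lam, s2 = st.lam[g], st.sigma2[g]
        v = s2 * (1.0 - lam ** 2)
        w = lam * np.sqrt(s2) / v                      # b-coefficients
        a = lam ** 2 / (1.0 - lam ** 2)                # information per dim
        M = np.zeros((H, H))
        for h in range(H):
            M[h, h] = a[lay.comp_of_dim == h].sum()
        P = np.linalg.inv(st.rho[g]) + M
        V = np.linalg.inv(P)
        L = np.linalg.cholesky(V)
        B = (st.theta[pg] - st.mu[g]) * w              # (n_g, D)
        b = np.zeros((len(pg), H))
        for h in range(H):
            b[:, h] = B[:, lay.comp_of_dim == h].sum(axis=1)
        st.omega[pg] = b @ V + rng.standard_normal((len(pg), H)) @ L.T


def _update_items(st: ChainState, priors: PriorConfig,
                  rng: np.random.Generator) -> None:
    lay = st.layout
    J = lay.n_items
    prop_a = st.alpha + st.scales["alpha"] * rng.standard_normal(J)
    prop_b = st.beta + st.scales["beta"] * rng.standard_normal(J)
    lp_prop = log_prior_item(prop_a, prop_b, priors)
    lp_cur = log_prior_item(st.alpha, st.beta, priors)
    th = st.theta[:, lay.dim_of_item]
    z = prop_a * (th - prop_b)
    llp_cells = np.where(lay.M, lay.Xf * z - _softplus(z), 0.0)
    delta = (llp_cells.sum(axis=0) - st.ll_cell.sum(axis=0)
             + lp_prop - lp_cur)
    with np.errstate(invalid="ignore"):
        acc = np.log(rng.random(J)) < delta
    acc &= np.isfinite(lp_prop)
    st.alpha[acc] = prop_a[acc]
    st.beta[acc] = prop_b[acc]
    st.ll_cell[:, acc] = llp_cells[:, acc]
    st._count("item", int(acc.sum()), acc.size)


def _update_shift(st: ChainState, priors: PriorConfig,
                  rng: np.random.Generator, pooled: bool = False) -> None:
    """Per-dimension translation move: theta[:, d], the difficulties of
    dimension d's items and every non-anchor group mean shift by a common
    delta.  The item likelihood and the non-anchor hierarchical residuals
    are invariant under this map (unit Jacobian), so only the anchor
    group's trait prior (mu pinned at 0), the 4Beta difficulty priors and
    the MVN mean prior restore the location -- a soft ridge that
    element-wise updates mix poorly."""
    lay = st.layout
    anchor_like = st.anchor | pooled        # pooled: every mean is pinned
    anchor_groups = np.flatnonzero(anchor_like)
    D = lay.D
    Sinv = np.linalg.inv(priors.mu_prior_cov(D))
    for d in range(D):
        delta = st.scales["shift"] * rng.standard_normal()
        cols = lay.items_by_dim[d]
        beta_new = st.beta[cols] + delta
        lp = (priors.beta_4beta.logpdf(beta_new).sum()
              - priors.beta_4beta.logpdf(st.beta[cols]).sum())
        if not np.isfinite(lp):
            st._count("shift", 0, 1)
            continue
        # anchor-group residuals shift by delta (its mu stays 0)
        for g in anchor_groups:
            pg = lay.persons_by_group[g]
            om = st.omega[pg][:, lay.comp_of_dim[d]]
            v = st.sigma2[g, d] * (1.0 - st.lam[g, d] ** 2)
            r = (st.theta[pg, d] - st.mu[g, d]
                 - st.lam[g, d] * np.sqrt(st.sigma2[g, d]) * om)
            lp += (np.sum(r ** 2) - np.sum((r + delta) ** 2)) / (2.0 * v)
        # MVN(0, Sigma_H) prior on each shifted free mean vector
        for g in range(lay.G):
            if anchor_like[g]:
                continue
            mu_new = st.mu[g].copy()
            mu_new[d] += delta
            lp += 0.5 * (st.mu[g] @ Sinv @ st.mu[g] - mu_new @ Sinv @ mu_new)
        if np.log(rng.random()) < lp:
            st.theta[:, d] += delta
            st.beta[cols] = beta_new
            for g in range(lay.G):
                if not anchor_like[g]:
                    st.mu[g, d] += delta
            st._count("shift", 1, 1)
        else:
            st._count("shift", 0, 1)


def _update_scale(st: ChainState, priors: PriorConfig,
                  rng: np.random.Generator, common: bool) -> None:
    """Per-dimension scale move: theta[:, d] and the difficulties scale by
    c = e^v, discriminations by 1/c, and every non-anchor group's mean by c
    and variance by c^2.  The item likelihood and the non-anchor
    hierarchical densities are invariant up to the Jacobian
    c^(N_anchor + 3 G_free); only the anchor group's unit-variance prior
    and the item/mean priors restore the scale -- the multiplicative
    analogue of the translation ridge.  Skipped under the common-variance
    variants, where sigma2 is fixed."""
    if common:
        return
    lay = st.layout
    anchor_groups = np.flatnonzero(st.anchor)
    free_groups = np.flatnonzero(~st.anchor)
    lo, hi = priors.sigma2_bounds
    Sinv = np.linalg.inv(priors.mu_prior_cov(lay.D))
    n_anchor = sum(len(lay.persons_by_group[g]) for g in anchor_groups)
    for d in range(lay.D):
        v = st.scales["scale"] * rng.standard_normal()
        c = float(np.exp(v))
        cols = lay.items_by_dim[d]
        a_new = st.alpha[cols] / c
        b_new = st.beta[cols] * c
        lp = (priors.alpha_4beta.logpdf(a_new).sum()
              - priors.alpha_4beta.logpdf(st.alpha[cols]).sum()
              + priors.beta_4beta.logpdf(b_new).sum()
              - priors.beta_4beta.logpdf(st.beta[cols]).sum())
        s2_new = st.sigma2[free_groups, d] * c * c
        if not np.isfinite(lp) or np.any((s2_new <= lo) | (s2_new >= hi)):
            st._count("scale", 0, 1)
            continue
        for g in anchor_groups:
            pg = lay.persons_by_group[g]
            om = st.omega[pg][:, lay.comp_of_dim[d]]
            vv = st.sigma2[g, d] * (1.0 - st.lam[g, d] ** 2)
            m = st.mu[g, d] + st.lam[g, d] * np.sqrt(st.sigma2[g, d]) * om
            th = st.theta[pg, d]
            lp += (np.sum((th - m) ** 2) - np.sum((c * th - m) ** 2)) / (2 * vv)
        lp += (n_anchor + 3 * len(free_groups)) * v
        for g in free_groups:
            mu_new = st.mu[g].copy()
            mu_new[d] *= c
            lp += 0.5 * (st.mu[g] @ Sinv @ st.mu[g] - mu_new @ Sinv @ mu_new)
        if np.log(rng.random()) < lp:
            st.theta[:, d] *= c
            st.alpha[cols] = a_new
            st.beta[cols] = b_new
            st.mu[free_groups, d] *= c
            st.sigma2[free_groups, d] *= c * c
            st._count("scale", 1, 1)
        else:
            st._count("scale", 0, 1)


def _align_signs(st: ChainState, common: bool) -> None:
    """Enforce lam > 0 for the first dimension of each second-order component
    by jointly flipping the lam block, the omega column, and the rho_omega
    rows/columns of that component (a likelihood-preserving relabeling)."""
    lay = st.layout
    for h in range(lay.H):
        d0 = lay.first_dim_of_comp[h]
        dims_h = np.flatnonzero(lay.comp_of_dim == h)
        if common:
            if st.lam[0, d0] < 0:
                st.lam[:, dims_h] *= -1.0
                st.omega[:, h] *= -1.0
                for g in range(lay.G):
                    _flip_corr(st, g, h)
        else:
            for g in range(lay.G):
                if st.lam[g, d0] < 0:
                    st.lam[g, dims_h] *= -1.0
                    st.omega[lay.persons_by_group[g], h] *= -1.0
                    _flip_corr(st, g, h)


def _flip_corr(st: ChainState, g: int, h: int) -> None:
    st.rho[g, h, :] *= -1.0
    st.rho[g, :, h] *= -1.0


def sweep(state: ChainState, data: ResponseMatrix, priors: PriorConfig,
          config: MCMCConfig, rng: np.random.Generator) -> ChainState:
    """One full update cycle, then sign alignment.

    theta is updated element-wise against the item likelihood; the
    structural block (mu Gibbs, then sigma2 | lam | rho Metropolis walks)
    is updated against the marginal trait likelihood with omega integrated
    out analytically, after which omega is regenerated from its exact MVN
    conditional -- a partially collapsed Gibbs scheme that avoids the slow
    coupling between loadings and latent second-order traits.  Item
    parameters follow, then the per-dimension translation and scale ridge
    moves.  Anchor-group mu and sigma2 are never touched; under the
    common-covariance variant sigma2 stays fixed at 1 and a single shared
    lam vector and rho_omega are updated with pooled (summed-over-groups)
    marginal conditionals; the pooled variant additionally pins every
    group mean at 0.  Mutates and returns ``state``."""
    common = config.model_variant in ("common_covariance", "pooled")
    pooled = config.model_variant == "pooled"
    _update_theta(state, rng)
    mom = _group_moments(state)
    _update_mu(state, priors, rng, mom, pooled)
    if not common:
        _update_sigma2(state, priors, rng, mom)
    _update_lam(state, priors, rng, common, mom)
    _update_lam_seesaw(state, priors, rng, common, mom)
    _update_rho(state, priors, rng, common, mom)
    _draw_omega(state, rng)
    _update_items(state, priors, rng)
    _update_shift(state, priors, rng, pooled)
    _update_scale(state, priors, rng, common)
    _align_signs(state, common)
    return state


# ---------------------------------------------------------------------------
# chain driver
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Retained post-burn-in draws of every parameter block.

    Structural and item draws are stored per chain x retained iteration;
    person traits are summarised online (posterior mean and SD over all
    chains) with a thinned subsample of full trait draws kept for posterior
    predictive checks.  ``deviance`` is -2 x log-likelihood per retained
    draw.
    """

    mu: np.ndarray                  # (C, K, G, D)
    sigma2: np.ndarray              # (C, K, G, D)
    lam: np.ndarray                 # (C, K, G, D)
    rho: np.ndarray                 # (C, K, G, H, H)
    alpha: np.ndarray               # (C, K, J)
    beta: np.ndarray                # (C, K, J)
    deviance: np.ndarray            # (C, K) item-conditional -2 log L(X|theta)
    deviance_complete: np.ndarray   # (C, K) incl. theta/omega prior layers
    theta_mean: np.ndarray          # (N, D)
    theta_sd: np.ndarray
    omega_mean: np.ndarray          # (N, H)
    omega_sd: np.ndarray
    theta_draws: np.ndarray         # (C, Kt, N, D) thinned subsample
    omega_draws: np.ndarray         # (C, Kt, N, H)
    trait_draw_idx: np.ndarray      # (Kt,) indices into retained draws
    acceptance: dict                # block -> per-chain acceptance rate list
    config: MCMCConfig
    dims: DimensionMap
    group_labels: list[str]
    item_ids: list[str]
    anchor_index: int

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_kept(self) -> int:
        return self.mu.shape[1]

    def parameter_dict(self, include_items: bool = True) -> dict[str, np.ndarray]:
        """Named (chains x draws) arrays for every scalar model parameter.

        Constants (anchor mu/sigma2; sigma2 under the common-covariance
        variant) are excluded.  Under the common-covariance variant the
        shared lam and rho_omega appear once instead of per group.
        """
        out: dict[str, np.ndarray] = {}
        common = self.config.model_variant in ("common_covariance", "pooled")
        pooled = self.config.model_variant == "pooled"
        G, D = self.mu.shape[2], self.mu.shape[3]
        H = self.rho.shape[3]
        labels = self.group_labels
        for g in range(G):
            if g == self.anchor_index or pooled:
                continue
            for d in range(D):
                out[f"mu[{labels[g]},{d + 1}]"] = self.mu[:, :, g, d]
        if not common:
            for g in range(G):
                if g != self.anchor_index:
                    for d in range(D):
                        out[f"sigma2[{labels[g]},{d + 1}]"] = self.sigma2[:, :, g, d]
        lam_groups = [0] if common else range(G)
        for g in lam_groups:
            tag = "common" if common else labels[g]
            for d in range(D):
                out[f"lam[{tag},{d + 1}]"] = self.lam[:, :, g, d]
        rho_groups = [0] if common else range(G)
        for g in rho_groups:
            tag = "common" if common else labels[g]
            for h1 in range(H):
                for h2 in range(h1 + 1, H):
                    out[f"rho_omega[{tag},{h1 + 1}{h2 + 1}]"] = \
                        self.rho[:, :, g, h1, h2]
        if include_items:
            for j, iid in enumerate(self.item_ids):
                out[f"alpha[{iid}]"] = self.alpha[:, :, j]
                out[f"beta[{iid}]"] = self.beta[:, :, j]
        return out

    def group_parameters(self, how: str = "mean") -> GroupParameters:
        """Posterior-mean structural parameters as a GroupParameters object."""
        if how != "mean":
            raise ParameterError("only posterior means are supported here")
        ax = (0, 1)
        rho = self.rho.mean(axis=ax)
        # posterior-mean correlation matrices can drift off unit diagonal
        for g in range(rho.shape[0]):
            d = np.sqrt(np.diag(rho[g]))
            rho[g] = rho[g] / np.outer(d, d)
            np.fill_diagonal(rho[g], 1.0)
        anchor = np.zeros(self.mu.shape[2], dtype=bool)
        anchor[self.anchor_index] = True
        return GroupParameters(mu=self.mu.mean(axis=ax),
                               sigma2=self.sigma2.mean(axis=ax),
                               lam=self.lam.mean(axis=ax),
                               rho_omega=rho, anchor=anchor)

    def item_bank(self) -> ItemBank:
        """Posterior-mean item parameters."""
        dim = np.asarray(self._item_dims)
        return ItemBank(item_id=list(self.item_ids), dimension=dim,
                        discrimination=self.alpha.mean(axis=(0, 1)),
                        difficulty=self.beta.mean(axis=(0, 1)))

    _item_dims: np.ndarray = None   # set by run_chains


def _initial_state(data: ResponseMatrix, items: ItemBank, dims: DimensionMap,
                   priors: PriorConfig, config: MCMCConfig, anchor_index: int,
                   rng: np.random.Generator) -> ChainState:
    lay = _Layout.build(data, items, dims)
    N, G, D, H = lay.n_persons, lay.G, dims.D, dims.H
    common = config.model_variant in ("common_covariance", "pooled")
    pooled = config.model_variant == "pooled"

    # theta: standardized per-person proportion-correct per dimension,
    # with chain-specific overdispersed jitter
    theta0 = np.zeros((N, D))
    for d in range(D):
        cols = lay.items_by_dim[d]
        nobs = lay.M[:, cols].sum(axis=1)
        p = np.divide(lay.Xf[:, cols].sum(axis=1), np.maximum(nobs, 1))
        sd = p.std() or 1.0
        theta0[:, d] = np.where(nobs > 0, (p - p.mean()) / sd, 0.0)
    theta0 += 0.5 * rng.standard_normal((N, D))
    omega0 = np.zeros((N, H))
    for h in range(H):
        block = theta0[:, lay.comp_of_dim == h].mean(axis=1)
        omega0[:, h] = (block - block.mean()) / (block.std() or 1.0)
    omega0 += 0.3 * rng.standard_normal((N, H))

    mu0 = 0.3 * rng.standard_normal((G, D))
    mu0 += np.array([[theta0[lay.persons_by_group[g], d].mean()
                      for d in range(D)] for g in range(G)])
    mu0[anchor_index] = 0.0
    if pooled:
        mu0[:] = 0.0
    sigma2 = np.ones((G, D)) if common else rng.uniform(0.6, 1.8, (G, D))
    sigma2[anchor_index] = 1.0
    lam_row = rng.uniform(0.3, 0.9, D)
    lam = np.tile(lam_row, (G, 1)) if common else rng.uniform(0.3, 0.9, (G, D))

    nu0 = priors.iw_nu0(D)
    Lam0 = priors.iw_scale(H)
    rho = np.empty((G, H, H))
    for g in range(G):
        if H == 1:
            rho[g] = np.ones((1, 1))
        else:
            S = np.atleast_2d(stats.invwishart.rvs(df=nu0 + 10, scale=Lam0 * 5,
                                                   random_state=rng))
            dd = np.sqrt(np.diag(S))
            rho[g] = S / np.outer(dd, dd)
            np.fill_diagonal(rho[g], 1.0)
    if common and H > 1:
        rho[:] = rho[0]

    a0, b0 = priors.alpha_4beta, priors.beta_4beta
    alpha = np.clip(a0.median + 0.1 * rng.standard_normal(items.n_items),
                    a0.a + 1e-3, a0.b - 1e-3)
    beta = np.clip(b0.median + 0.2 * rng.standard_normal(items.n_items),
                   b0.a + 1e-3, b0.b - 1e-3)

    anchor = np.zeros(G, dtype=bool)
    anchor[anchor_index] = True
    st = ChainState(theta=theta0, omega=omega0, mu=mu0, sigma2=sigma2,
                    lam=lam, rho=rho, alpha=alpha,
                    beta=beta, anchor=anchor, ll_cell=np.zeros_like(lay.Xf),
                    layout=lay, scales=dict(config.proposal_scales))
    st.ll_cell = st.recompute_ll_cell()
    _align_signs(st, common)
    return st


_ADAPT_WINDOW = 50


def _adapt_scales(st: ChainState, target: float) -> None:
    for block, key in (("theta", "theta"), ("omega", "omega"),
                       ("sigma2", "sigma2"), ("lam", "lam"), ("rho", "rho"),
                       ("shift", "shift"), ("scale", "scale"),
                       ("item", "alpha")):
        # the see-saw scale is deliberately not tuned: along a flat ridge
        # acceptance stays high at any step size, so acceptance-targeting
        # would shrink the step and stall mixing
        prop = st.proposed.get(block, 0)
        if prop == 0:
            continue
        rate = st.accepted.get(block, 0) / prop
        factor = float(np.exp(np.clip(rate - target, -0.5, 0.5)))
        if block == "item":
            st.scales["alpha"] = float(np.clip(st.scales["alpha"] * factor, 1e-3, 5))
            st.scales["beta"] = float(np.clip(st.scales["beta"] * factor, 1e-3, 5))
        else:
            st.scales[key] = float(np.clip(st.scales[key] * factor, 1e-3, 10))
    st.accepted.clear()
    st.proposed.clear()


def run_chains(data: ResponseMatrix, items: ItemBank, dims: DimensionMap,
               priors: PriorConfig | None = None,
               config: MCMCConfig | None = None,
               anchor_group: int | str = 0) -> PosteriorDraws:
    """Run independent MCMC chains and collect retained draws.

    Chains use seeds spawned deterministically from ``config.seed`` and
    dispersed chain-specific starting values; the same seed reproduces
    bit-identical output.  ``anchor_group`` selects (by label or 0-based
    index) the group whose mean is fixed at 0 and variances at 1.
    """
    priors = priors or PriorConfig()
    config = config or MCMCConfig()
    if isinstance(anchor_group, str):
        if anchor_group not in data.group_labels:
            raise ConfigurationError(
                f"anchor group {anchor_group!r} not among group labels "
                f"{data.group_labels}")
        anchor_index = data.group_labels.index(anchor_group)
    else:
        anchor_index = int(anchor_group)
    if not 0 <= anchor_index < data.n_groups:
        raise ConfigurationError("anchor group index out of range; at least "
                                 "one group must be flagged as anchor")

    C, K = config.n_chains, config.n_kept
    G, D, H, J, N = data.n_groups, dims.D, dims.H, data.n_items, data.n_persons
    draws = PosteriorDraws(
        mu=np.empty((C, K, G, D)), sigma2=np.empty((C, K, G, D)),
        lam=np.empty((C, K, G, D)), rho=np.empty((C, K, G, H, H)),
        alpha=np.empty((C, K, J)), beta=np.empty((C, K, J)),
        deviance=np.empty((C, K)), deviance_complete=np.empty((C, K)),
        theta_mean=np.zeros((N, D)), theta_sd=np.zeros((N, D)),
        omega_mean=np.zeros((N, H)), omega_sd=np.zeros((N, H)),
        theta_draws=None, omega_draws=None, trait_draw_idx=None,
        acceptance={}, config=config, dims=dims,
        group_labels=list(data.group_labels), item_ids=list(data.item_ids),
        anchor_index=anchor_index)
    draws._item_dims = items.dimension.copy()

    kt = min(K, config.save_trait_draws)
    trait_idx = np.unique(np.linspace(0, K - 1, kt).round().astype(int))
    kt = len(trait_idx)
    draws.trait_draw_idx = trait_idx
    draws.theta_draws = np.empty((C, kt, N, D))
    draws.omega_draws = np.empty((C, kt, N, H))
    trait_slot = {int(k): s for s, k in enumerate(trait_idx)}

    th_sum = np.zeros((N, D))
    th_sq = np.zeros((N, D))
    om_sum = np.zeros((N, H))
    om_sq = np.zeros((N, H))

    seeds = np.random.SeedSequence(config.seed).spawn(C)
    for c in range(C):
        rng = np.random.default_rng(seeds[c])
        st = _initial_state(data, items, dims, priors, config, anchor_index, rng)
        kept = 0
        total_acc: dict[str, list[int]] = {}
        for it in range(1, config.n_iter + 1):
            sweep(st, data, priors, config, rng)
            if config.adapt and it <= config.burn_in and it % _ADAPT_WINDOW == 0:
                _adapt_scales(st, config.target_accept)
            if it == config.burn_in:
                st.accepted.clear()
                st.proposed.clear()
            if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
                draws.mu[c, kept] = st.mu
                draws.sigma2[c, kept] = st.sigma2
                draws.lam[c, kept] = st.lam
                draws.rho[c, kept] = st.rho
                draws.alpha[c, kept] = st.alpha
                draws.beta[c, kept] = st.beta
                ll = st.log_likelihood()
                draws.deviance[c, kept] = -2.0 * ll
                draws.deviance_complete[c, kept] = -2.0 * (
                    ll + st.structural_loglik())
                th_sum += st.theta
                th_sq += st.theta ** 2
                om_sum += st.omega
                om_sq += st.omega ** 2
                if kept in trait_slot:
                    draws.theta_draws[c, trait_slot[kept]] = st.theta
                    draws.omega_draws[c, trait_slot[kept]] = st.omega
                kept += 1
        for block in set(st.proposed):
            draws.acceptance.setdefault(block, []).append(
                st.accepted.get(block, 0) / max(st.proposed[block], 1))

    n_tot = C * K
    draws.theta_mean = th_sum / n_tot
    draws.omega_mean = om_sum / n_tot
    draws.theta_sd = np.sqrt(np.maximum(th_sq / n_tot - draws.theta_mean ** 2, 0))
    draws.omega_sd = np.sqrt(np.maximum(om_sq / n_tot - draws.omega_mean ** 2, 0))
    return draws
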