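# Methods

## Model

`hoirt` fits a multi-group, multivariate higher-order item response model
to binary item data pooled from several studies ("groups"). The
measurement layer is the two-parameter logistic multi-unidimensional IRT
model: item *j*, assigned to exactly one of *D* first-order dimensions,
has

    P(X_ij = 1 | theta, alpha_j, beta_j)
        = logistic(alpha_j (theta_{i,d(j)} - beta_j)),

with discrimination `alpha_j > 0` and difficulty `beta_j` shared across
groups (the common-item assumption that makes linking possible). The
structural layer expresses each first-order trait as a regression on one
of *H* second-order traits:

    theta_{i(g)(d)} | omega ~ N( mu_{(g)(d)}
                                 + lam_{(g)(d)} sigma_{(g)(d)} omega_{i(g)(h(d))},
                                 sigma2_{(g)(d)} (1 - lam_{(g)(d)}^2) ),
    omega_{i(g)} ~ MVN(0, rho_omega_{(g)}),   unit variances.

Writing the conditional mean as `mu + lam*sigma*omega` and the conditional
variance as `sigma2(1 - lam^2)` makes the *marginal* variance of theta
exactly `sigma2` — the only parameterisation consistent with interpreting
`sigma2` as the group's trait variance. `H = 1` is the univariate model,
`H = 2` the bivariate one. Missing responses are skipped in the
likelihood (missing at random).

Marginalising omega gives the implied trait covariance per group:
`sigma2_d` on the diagonal, `sigma_d sigma_d' lam_d lam_d'` when two
dimensions share a component and `... * rho_omega(h,h')` when they do
not; the `structure` module reconstructs these matrices (per retained
draw and averaged, by default, since they are nonlinear in the
parameters; a plug-in mode exists for comparison).

**Identification.** The latent metric is pinned by an anchor group whose
means are fixed at 0 and variances at 1 (its second-order covariance is a
correlation matrix); all other groups' `mu`, `sigma2`, `lam`, `rho_omega`
are estimated relative to that metric. The remaining reflection symmetry
(flipping a loading block together with its omega column) is broken by a
sign policy: the first dimension of every component keeps a positive
loading, enforced by a likelihood-preserving relabeling after each sweep.

**Model variants.** `saturated` estimates group-specific `lam`, `sigma2`
and `rho_omega`. `common_covariance` shares one loading vector and one
`rho_omega` across groups and fixes `sigma2 = 1` everywhere — with the
anchor constraint the common covariance *is* a correlation matrix, so a
free shared `sigma2` would be redundant. Group means stay group-specific.
`pooled` additionally fixes every group mean at the anchor's 0 ("same
means and covariances across studies") — the baseline a multi-group
analysis is compared against when asking whether study differences
matter at all.

## Priors

- `mu_(g) ~ MVN(0, Sigma_H)`, `Sigma_H` a correlation matrix with 0.5
  off-diagonals;
- `sigma2 ~ U(0, 5)`. A U(0, 1) support would exclude groups more
  heterogeneous than the anchor (the benchmark design itself generates
  `sigma2 = 1.25`), so the wider default is used; configurable;
- `lam ~ U(-1, 1)`;
- `alpha_j, beta_j ~` four-parameter Beta; defaults
  `4Beta(1.5, 1.5, 0.2, 2.5)` and `4Beta(1.1, 1.1, -4, 4)` are weakly
  informative and cover typical 2PL item values; all four hyperparameters
  of each are configurable;
- `rho_omega`: the exact correlation-matrix marginal induced by an
  inverse-Wishart with `nu0 = D + 2` degrees of freedom and diagonal
  scale,

      pi(R) ∝ |R|^{-(nu0+H+1)/2} prod_h [(R^-1)_hh]^{-nu0/2},

  which for H = 2 is `(1 - rho^2)^{(nu0-H+1)/2 - 1}` — proper, symmetric
  and weakly informative. A non-diagonal inverse-Wishart scale has no
  tractable correlation marginal; its only effect would be a slight prior
  tilt, immaterial at the sample sizes the model targets. `nu0` is
  exposed in `PriorConfig` (`iw_df`); note it is defined from D, not H,
  following the convention this model family uses.

## Sampler

One sweep of the Metropolis-Hastings-within-Gibbs chain:

1. **theta** — element-wise random-walk MH against the item likelihood
   (cached per-cell log-likelihood terms) times the hierarchical normal
   prior.
2. **mu** — exact Gibbs draw from its MVN conditional under the marginal
   trait model `theta ~ MVN(mu, C)` with `C` the implied covariance:
   `Sigma1 = (Lambda0^-1 + N Sigma^-1)^-1`,
   `mu1 = Sigma1 (N Sigma^-1 thetabar)`. Skipped for the anchor group.
3. **sigma2, lam, rho_omega** — scalar random-walk MH against the same
   marginal MVN likelihood (omega integrated out analytically), plus a
   "see-saw" move that multiplies one loading by `e^v` and divides a
   same-component loading by it. Within-component products
   `lam_a lam_b` are strongly identified by the trait covariances while
   the ratio is weak; the see-saw walks that ridge directly (unit
   Jacobian, symmetric in `v`). Under `common_covariance`, `lam` and
   `rho_omega` conditionals pool (sum) over groups.
4. **omega** — exact conjugate MVN draw per person given theta and the
   structural parameters (precision `rho^-1 + diag_h sum_d lam^2/(1-lam^2)`).
   Regenerating omega from its exact conditional immediately after the
   marginalised structural updates makes steps 2–4 a valid partially
   collapsed Gibbs block. Updating the structural parameters against the
   omega-*conditional* densities instead is formally correct but mixes
   pathologically: the loading-ratio mode then has to drag the whole
   realized omega column with it (measured ESS ≈ 5 per 7,000 draws
   versus ≈ 300 after collapsing).
5. **items** — joint per-item random-walk MH on (alpha, beta) with the
   4Beta priors; out-of-support proposals are automatic rejections.
6. **shift** — a per-dimension translation move: `theta[:, d]`, that
   dimension's difficulties and all non-anchor means shift by one common
   delta. The item likelihood and the non-anchor residuals are invariant
   under this map, so only the anchor group's prior and the item/mean
   priors restore location — a soft ridge that element-wise updates
   cross very slowly (it dominated the Gelman-Rubin statistic before the
   move was added).
7. **scale** — the multiplicative analogue: `theta[:, d]` and the
   difficulties scale by `e^v`, discriminations by `e^-v`, non-anchor
   means by `e^v` and variances by `e^{2v}` (Jacobian
   `exp(v (N_anchor + 3 G_free))`); the anchor group's unit variance is
   the restoring force. Skipped when `sigma2` is fixed (common-variance
   variants).
8. **sign alignment** as above.

A historical note on the correlation step: the classical
parameter-expansion move (inverse-Wishart Gibbs draw of an expanded
covariance, rescaled to a correlation matrix and Metropolis-corrected) is
stationary-correct here but practically non-ergodic, because omega's
scale is pinned by the `lam*sigma*omega` regression and cannot be
rescaled along with the expanded covariance. The expanded target then
concentrates the redundant scales near the prior while the
inverse-Wishart conditional proposes them near omega's sample variances;
the independence sampler's importance weights differ by factors of ~e^10
and the chain traps (observed acceptance → 0). The entry-wise walk with
the induced prior above targets the identical correlation posterior
without redundant scales. `draw_rho_omega` implements it; candidates
that are not positive definite have zero prior density and are rejected,
so the state is always a valid correlation matrix.

**Proposal scales** adapt during burn-in toward 35% acceptance per block
(windows of 50 sweeps) and are frozen afterwards to preserve detailed
balance. The see-saw scale is deliberately *not* tuned: along a flat
ridge acceptance stays high at any step size, so acceptance-targeting
would shrink the step and stall mixing.

**Initialisation.** Item parameters start at their prior medians with
small jitter; theta at standardized per-person proportion-correct scores
(omega at standardized component averages) plus chain-specific
overdispersed noise; structural parameters at dispersed draws restricted
to a plausible region (`sigma2 ~ U(0.6, 1.8)`, `lam ~ U(0.3, 0.9)`,
`mu ~` group score means + N(0, 0.3²) noise, `rho` from a rescaled
inverse-Wishart draw). Raw prior draws (e.g. `sigma2 ≈ 4.9`) make short
burn-ins needlessly fragile while contributing nothing to dispersion
that the Gelman-Rubin check needs.

**Reproducibility.** Chains use seeds spawned from `MCMCConfig.seed`
via `numpy.random.SeedSequence`; identical configuration and seed give
bit-identical draws.

## Diagnostics

- **Gelman-Rubin**: the original between/within-chain formulation (a
  split-half variant covers single-chain runs); values below 1.1 are
  taken as convergence evidence. All-constant chains return a NaN
  sentinel rather than raising.
- **ESS**: Geyer initial-positive-sequence truncation of the FFT
  autocorrelation sum, computed per chain and summed.
- **DIC**: `Dbar + pD` with `pD = var(deviance)/2`; the deviance is
  `-2 log L(X | theta, alpha, beta)` recorded at every retained draw,
  and the variance uses the n-1 denominator. Two caveats follow from the
  deviance being *conditional on theta*. First, `pD` is of the order of
  the trait count and its estimate is noisy (the deviance series is
  highly autocorrelated): model comparisons need chains long enough for
  a stable deviance variance, and burn-in transients inflate `pD`
  directly. Second, the conditional deviance is nearly blind to the
  structural layer: the person traits absorb structural misfit, so on
  data that satisfy the measurement model, reduced variants (common
  covariance, or even all means pooled to zero) differ from the
  saturated model by only tens of deviance units out of tens of
  thousands — well inside `pD` estimation noise. `PosteriorDraws`
  therefore also records a complete-data deviance (item likelihood plus
  the theta/omega prior layers), which does register structure, but its
  variance-based `pD` is unstable whenever a loading ridge is weakly
  identified. Model choice between latent-structure variants should
  lean on the estimated structural parameters and posterior predictive
  checks rather than on this DIC alone; real-data applications, where
  the measurement model itself is misspecified, are where DIC contrasts
  become large.
- **PPMC**: per-item endorsement proportions as the discrepancy;
  replicate matrices honour the observed missingness mask; ties between
  replicate and observed discrepancy count one half (mid-p) by default
  since a binary discrepancy on finite data ties often — configurable to
  the strict `>=` convention. Items flagged outside [0.025, 0.975].

## Synthetic data

`benchmark_design()` is the built-in recovery study: three groups of
1,000 (the anchor with `mu = 0`, `sigma2 = 1`; the others at
`mu = ±(0.3..0.7)` with `sigma2 = 0.75 / 1.25`), all loadings 0.837,
second-order correlation 0.5 in every group, and a fixed bank of 30 2PL
items repeated over the five dimensions (dimensions 1–3 on the first
component, 4–5 on the second — the component split mirrors a
two-construct instrument; it is configurable through `DimensionMap`).
The 30 item parameters are a fixed printed set, not re-drawn, so results
are comparable across runs. `application_like_design()` emulates a
three-study integrative-data scenario (49 items split 15/6/13/5/10,
studies of 115/263/287 persons, 7% missingness, strongly study-specific
covariance structure) for model-comparison experiments.
`apply_study_sparsity` and `dichotomize` emulate study-level item
unavailability and polytomous-to-binary harmonisation.

What the generator does *not* emulate: differential item functioning
(item parameters are identical across groups by construction), non-MAR
missingness, local dependence among items, and polytomous measurement
models. Passing recovery tests therefore shows the estimator is correct
under the model's own assumptions, not that those assumptions hold in
any particular application.

## Problem sizes and expected precision

The full-scale study (`full_scale_study()`: 25 replications, 1,000 per
group, 4 chains × 25,000 iterations) reproduces the reference recovery
bands in `FULL_SCALE_EXPECTATIONS` and is an overnight run. The desk
check used by the test-suite and the acceptance script scales this to
500 persons per group, one to three datasets, and 4,000-iteration chains
(1,000 burn-in), which runs in minutes.

At that reduced scale, *single-dataset* estimates carry irreducible
trait-sampling noise that dwarfs estimator error: the relative group
mean has standard deviation `sqrt((0.75 + 1)/500) ≈ 0.059`, and the
loading ratio within the two-dimension component about 0.04 (the product
`lam_4 lam_5` is tight, the ratio is not). A fixture-based check of
per-cell errors against the generating values at this scale therefore
fails for roughly half of all random datasets even for an oracle
estimator — an observation verified directly by moment-fitting the true
simulated traits, whose per-dataset values the posterior means track
closely. Quantities averaged over cells, groups or replications (as the
acceptance script reports) are robust to this noise.

## Numerical choices

- Bernoulli log-likelihoods via the stable softplus form
  `x z - max(z,0) - log1p(exp(-|z|))`; no probability ever reaches an
  exact 0/1 log term (clamping at 1e-12 applies where probabilities are
  materialised).
- The cached per-cell log-likelihood is updated incrementally by the
  theta and item blocks and verified against recomputation in tests.
- Implied-matrix positive semidefiniteness is asserted with an eigenvalue
  floor of -1e-10.
- Posterior trait summaries are accumulated online (mean and SD across
  every retained draw of every chain); a thinned subsample of full trait
  draws (default ≤ 200 per chain) is kept for posterior predictive
  checks.

## Known limitations

- No differential item functioning: items must measure equivalently in
  every group, as assumed.
- The deviance-based `pD` can be noisy for short chains (see above).
- `common_covariance` fixes `sigma2 = 1` rather than estimating a shared
  free variance; a shared free variance is unidentified next to the
  anchor constraint.
- Third- and higher-order trait structures, 3PL guessing and polytomous
  response models are out of scope.
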