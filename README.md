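# hoirt

Multi-group, multivariate **h**igher-**o**rder **IRT** models estimated by
Markov chain Monte Carlo — for placing binary item responses from multiple
studies on a common latent metric.

## The problem

Integrative data analysis and individual-participant-data meta-analysis
pool item-level responses from studies that used different instruments.
Before any pooled analysis, participants from all studies must be scored
on one metric. When the construct of interest is hierarchical — several
domain-specific traits driven by one or more broader constructs — the
measurement model needs both a multidimensional first-order layer and a
higher-order structural layer, with study-specific latent distributions.

`hoirt` implements that model. Each binary item *j* measures exactly one
of *D* first-order traits through a two-parameter logistic response
function,

$$P(X_{i(g)j}=1)=\frac{\exp[\alpha_j(\theta_{i(g)(d)}-\beta_j)]}{1+\exp[\alpha_j(\theta_{i(g)(d)}-\beta_j)]},$$

with item parameters shared across the *G* groups (studies). The
first-order traits are regressions on *H* correlated second-order traits:

$$\theta_{i(g)(d)}\mid\boldsymbol\omega \sim N\!\big(\mu_{(g)(d)}+\lambda_{(g)(d)}\sigma_{(g)(d)}\,\omega_{i(g)(h)},\;\sigma^2_{(g)(d)}(1-\lambda^2_{(g)(d)})\big),\qquad \boldsymbol\omega_{i(g)}\sim \mathrm{MVN}(\mathbf 0,\boldsymbol\rho_{\omega(g)}).$$

One anchor group (mean **0**, unit variances) identifies the metric; the
other groups' means, variances, loadings and second-order correlations
are estimated relative to it. *H* = 1 or 2 gives the univariate /
bivariate variants; a reduced `common_covariance` variant shares one
loading vector and second-order correlation across groups, and a
`pooled` variant additionally equates the group means. The implied
trait covariance between two dimensions is
$\sigma_d\sigma_{d'}\lambda_d\lambda_{d'}$ within a second-order
component and $\sigma_d\sigma_{d'}\lambda_d\lambda_{d'}\rho_\omega$
across components.

Estimation is Metropolis-Hastings-within-Gibbs with conjugate draws for
the group means and the second-order traits, marginalised (omega
integrated out) Metropolis updates for the structural block, and
tailored ridge moves; see `docs/methods.md` for the full algorithm,
priors, and design decisions. Diagnostics include the Gelman-Rubin
statistic, autocorrelation-based effective sample sizes, DIC (with half
the deviance variance as the effective parameter count) and posterior
predictive checks on per-item endorsement rates.

## Worked example

```python
import numpy as np, hoirt

design = hoirt.benchmark_design(150, seed=42)   # 3 groups x 150 persons,
rng = np.random.default_rng(42)                 # 150 items, 5 dimensions
data, traits = hoirt.simulate_dataset(design, rng)

cfg = hoirt.MCMCConfig(n_chains=2, n_iter=1500, burn_in=500, seed=7)
draws = hoirt.run_chains(data, design.items, design.dims, config=cfg)
print(np.round(draws.lam.mean(axis=(0, 1)), 3))
print(np.round(draws.rho.mean(axis=(0, 1))[:, 0, 1], 3))
```

prints (`examples/01_simulate_and_fit.py` runs this end to end):

```
simulated 450 persons x 150 items, groups of [150, 150, 150]

posterior means vs generating values
  lambda (all true 0.837):
    group 1: [0.816 0.796 0.866 0.803 0.914]
    group 2: [0.853 0.832 0.845 0.843 0.883]
    group 3: [0.855 0.878 0.901 0.873 0.789]
  rho_omega (true 0.5 everywhere): [0.554 0.526 0.591]
  group-2 means (true 0.3..0.7):   [0.198 0.415 0.413 0.623 0.739]
```

Every loading couples a first-order trait to its second-order construct;
`rho_omega` is the correlation between the two constructs in each study;
the group-2 means locate that study relative to the anchor. At 150
persons per group the posterior means scatter around the generating
values by a few hundredths — sharpening as the sample grows.

The other example scripts cover the implied covariance matrices
(`02`), convergence/DIC/posterior-predictive diagnostics (`03`), sparse
multi-study data with polytomous harmonisation (`04`) and the full-scale
overnight recovery study (`05`).

A thin CLI wraps the same pipeline for shell use:

```bash
hoirt simulate -c run.yaml     # write a synthetic dataset
hoirt fit      -c run.yaml     # draws, fit summary, PPMC, implied matrices
hoirt diagnose -c run.yaml     # G-R / ESS / DIC report from stored draws
hoirt summarize -c run.yaml    # structural tables + implied matrices
```

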