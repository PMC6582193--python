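"""Convergence diagnostics, model comparison and posterior predictive checks.

* Gelman-Rubin potential scale reduction factor, in its original
  between/within-chain form (a split-chain fallback covers single-chain
  runs);
* effective sample size via Geyer's initial-positive-sequence truncation of
  the autocorrelation sum;
* DIC with the effective number of parameters taken as half the variance of
  the deviance trace (sample variance, n-1 denominator);
* posterior predictive model checking with the per-item endorsement
  proportion ("proportion correct") as the discrepancy measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .model import ResponseMatrix

__all__ = ["FitSummary", "gelman_rubin", "effective_sample_size", "dic",
           "ppmc_proportion_correct", "summarize_fit"]


def gelman_rubin(draws_per_chain: np.ndarray) -> float:
    """Potential scale reduction factor for one parameter.

    ``draws_per_chain`` is (chains, draws).  A single chain is split in half
    (split-chain variant).  If every chain has zero within-chain variance
    the statistic is undefined: returns ``inf`` when the chain means still
    disagree and ``nan`` (the degenerate-constant sentinel) when they also
    coincide; no exception is raised.
    """
    x = np.atleast_2d(np.asarray(draws_per_chain, dtype=float))
    if x.shape[0] == 1:
        n2 = x.shape[1] // 2
        x = np.stack([x[0, :n2], x[0, n2:2 * n2]])
    m, n = x.shape
    if n < 10:
        raise ParameterError("need at least 10 draws per chain")
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = x.mean(axis=1).var(ddof=1)
    if W == 0:
        return float("inf") if B_over_n > 0 else float("nan")
    var_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_hat / W))


def effective_sample_size(draws: np.ndarray) -> float:
    """Autocorrelation-adjusted effective sample size of one ordered series.

    Uses Geyer's initial positive sequence: autocovariances are summed in
    adjacent pairs until a pair sum turns non-positive, giving the
    integrated autocorrelation time tau; ESS = n / tau, capped at n.
    A constant series returns 0.0.
    """
    x = np.asarray(draws, dtype=float).ravel()
    n = x.size
    if n < 100:
        raise ParameterError("need at least 100 draws for an ESS estimate")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return 0.0
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    tau = 1.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        k += 2
    return float(min(n, n / tau))


def dic(deviance_trace: np.ndarray) -> tuple[float, float, float]:
    """(Dbar, pD, DIC) from a trace of -2 log-likelihood values.

    Dbar is the posterior mean deviance; the effective number of parameters
    pD is half the deviance variance (sample variance, n-1 denominator);
    DIC = Dbar + pD.
    """
    dev = np.asarray(deviance_trace, dtype=float).ravel()
    if dev.size < 2:
        raise ParameterError("need at least 2 deviance draws")
    dbar = float(dev.mean())
    p_d = float(dev.var(ddof=1) / 2.0)
    return dbar, p_d, dbar + p_d


def ppmc_proportion_correct(draws, data: ResponseMatrix, n_rep: int,
                            rng: np.random.Generator,
                            ties: str = "midp") -> pd.Series:
    """Posterior predictive p-values with per-item endorsement proportions.

    For ``n_rep`` retained draws (subsampled from the stored trait-draw
    subsample and their matching item-parameter draws) a replicate response
    matrix is simulated honouring the observed missingness mask; the
    discrepancy is each item's proportion of 1s among observed entries.
    The ppp is the fraction of replicates whose discrepancy exceeds the
    observed one, with ties counted as one half by default (``ties="midp"``)
    or fully (``ties="ge"``).  Items with no observed entries are excluded
    with a warning.
    """
    if n_rep < 100:
        raise ParameterError("n_rep must be at least 100")
    if ties not in ("midp", "ge"):
        raise ParameterError(f"unknown tie policy {ties!r}")
    M = data.observed
    nobs = M.sum(axis=0)
    keep = nobs > 0
    if not keep.all():
        excluded = [data.item_ids[j] for j in np.flatnonzero(~keep)]
        warnings.warn(f"items with no observed responses excluded from "
                      f"PPMC: {excluded}")
    obs_prop = np.where(keep, np.where(M, data.X, 0).sum(axis=0)
                        / np.maximum(nobs, 1), np.nan)

    C, Kt = draws.theta_draws.shape[:2]
    pairs = [(c, s) for c in range(C) for s in range(Kt)]
    idx = rng.choice(len(pairs), size=n_rep, replace=len(pairs) < n_rep)
    dim = draws._item_dims
    greater = np.zeros(data.n_items)
    equal = np.zeros(data.n_items)
    for t in idx:
        c, s = pairs[t]
        k = int(draws.trait_draw_idx[s])
        th = draws.theta_draws[c, s][:, dim]
        z = draws.alpha[c, k] * (th - draws.beta[c, k])
        p = 1.0 / (1.0 + np.exp(-z))
        rep = (rng.random(p.shape) < p) & M
        rep_prop = rep.sum(axis=0) / np.maximum(nobs, 1)
        greater += rep_prop > obs_prop
        equal += rep_prop == obs_prop
    ppp = (greater + (0.5 if ties == "midp" else 1.0) * equal) / n_rep
    ids = [data.item_ids[j] for j in np.flatnonzero(keep)]
    return pd.Series(ppp[keep], index=ids, name="ppp")


@dataclass
class FitSummary:
    """Posterior summaries, convergence diagnostics and fit indices.

    ``table`` has one row per scalar parameter: posterior mean, SD, 95%
    credible interval, Gelman-Rubin statistic and effective sample size
    (summed over chains).  ``ppp`` is present when observed data were given.
    """

    table: pd.DataFrame
    dbar: float
    p_d: float
    dic: float
    ppp: pd.Series | None = None
    gr_threshold: float = 1.1
    ppp_bounds: tuple[float, float] = (0.025, 0.975)

    @property
    def max_gelman_rubin(self) -> float:
        return float(np.nanmax(self.table["rhat"].to_numpy()))

    @property
    def converged(self) -> bool:
        return self.max_gelman_rubin < self.gr_threshold

    def flagged_items(self) -> list[str]:
        """Items whose ppp falls outside the calibration bounds."""
        if self.ppp is None:
            return []
        lo, hi = self.ppp_bounds
        return list(self.ppp.index[(self.ppp < lo) | (self.ppp > hi)])


def summarize_fit(draws, data: ResponseMatrix | None = None,
                  n_rep: int = 500, rng: np.random.Generator | None = None,
                  include_items: bool = True, gr_threshold: float = 1.1,
                  ppp_bounds: tuple[float, float] = (0.025, 0.975)) -> FitSummary:
    """Build a FitSummary from posterior draws (and optionally the data)."""
    rows = []
    for name, arr in draws.parameter_dict(include_items=include_items).items():
        flat = arr.ravel()
        if arr.shape[1] >= 100:
            ess = sum(effective_sample_size(chain) for chain in arr)
        else:
            ess = float("nan")
        rows.append({
            "parameter": name,
            "mean": float(flat.mean()),
            "sd": float(flat.std(ddof=1)),
            "ci_2.5%": float(np.percentile(flat, 2.5)),
            "ci_97.5%": float(np.percentile(flat, 97.5)),
            "rhat": gelman_rubin(arr),
            "ess": ess,
        })
    table = pd.DataFrame(rows).set_index("parameter")
    dbar, p_d, d = dic(draws.deviance)
    ppp = None
    if data is not None:
        rng = rng or np.random.default_rng(draws.config.seed + 1)
        ppp = ppmc_proportion_correct(draws, data, n_rep=n_rep, rng=rng)
    return FitSummary(table=table, dbar=dbar, p_d=p_d, dic=d, ppp=ppp,
                      gr_threshold=gr_threshold, ppp_bounds=ppp_bounds)
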