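"""Bounded-uniform-prior Bayesian machinery: adaptive random-walk Metropolis,
split Gelman-Rubin diagnostics, equal-tailed credible intervals and DIC.

The sampler is a component-wise Gaussian random-walk Metropolis targeting the
posterior ``log_likelihood + log_prior`` with independent U(lower, upper)
priors. Per-parameter step sizes adapt during burn-in toward a 20-45%
acceptance rate and are frozen afterwards, so the retained draws come from a
valid (non-adaptive) Markov chain. Parameters are sampled on their natural
scale; proposals outside the prior box are rejected outright.

These posteriors are low-dimensional (2-4 parameters) and cheap, so robustness
and reproducibility were preferred over sampler sophistication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .records import IntervalEstimate

__all__ = [
    "PriorSpec",
    "PosteriorChains",
    "run_mcmc",
    "gelman_rubin",
    "credible_interval",
    "dic",
]

#: acceptance-rate window the burn-in adaptation steers toward
_ACC_TARGET = 0.3
_STAGNATION_WINDOW = 1000


@dataclass(frozen=True)
class PriorSpec:
    """Independent bounded-uniform priors over an ordered parameter vector."""

    names: Sequence[str]
    lower: Sequence[float]
    upper: Sequence[float]

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if not (len(self.names) == lo.size == hi.size):
            raise ValueError("names, lower, upper must have equal length")
        if not np.all(lo < hi):
            raise ValueError("prior bounds require lower < upper elementwise")

    @property
    def n_params(self) -> int:
        return len(self.names)

    def bounds(self):
        return np.asarray(self.lower, float), np.asarray(self.upper, float)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.bounds()
        return rng.uniform(lo, hi)

    def contains(self, theta: np.ndarray) -> bool:
        lo, hi = self.bounds()
        return bool(np.all(theta >= lo) & np.all(theta <= hi))


@dataclass
class PosteriorChains:
    """Post-burn-in MCMC draws with convergence diagnostics.

    ``draws`` has shape (chains, iterations, parameters). ``pd_`` and ``dic``
    are filled in by :func:`dic` when a log-likelihood is supplied.
    """

    names: Sequence[str]
    draws: np.ndarray
    rhat: Dict[str, float]
    acceptance_rates: Sequence[float]
    seed: int
    pd_: Optional[float] = None
    dic: Optional[float] = None
    degenerate: bool = False

    @property
    def flat(self) -> np.ndarray:
        """All chains pooled: (chains * iterations, parameters)."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def posterior_mean(self) -> np.ndarray:
        return self.flat.mean(axis=0)

    def posterior_median(self) -> np.ndarray:
        return np.median(self.flat, axis=0)

    def posterior_sd(self) -> np.ndarray:
        return self.flat.std(axis=0, ddof=1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long export: chain, iteration, one column per parameter."""
        n_chains, n_iter, _ = self.draws.shape
        frames = []
        for c in range(n_chains):
            df = pd.DataFrame(self.draws[c], columns=list(self.names))
            df.insert(0, "iteration", np.arange(n_iter))
            df.insert(0, "chain", c)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        ci = credible_interval(self, level=level)
        rows = []
        mean = self.posterior_mean()
        sd = self.posterior_sd()
        for j, name in enumerate(self.names):
            rows.append(
                {
                    "parameter": name,
                    "mean": mean[j],
                    "sd": sd[j],
                    "median": ci[name].point,
                    "ci_lower": ci[name].lower,
                    "ci_upper": ci[name].upper,
                    "rhat": self.rhat[name],
                }
            )
        return pd.DataFrame(rows)


def _find_start(log_likelihood, prior, rng, max_tries: int = 200) -> np.ndarray:
    for _ in range(max_tries):
        theta = prior.sample(rng)
        ll = log_likelihood(theta)
        if np.isnan(ll):
            raise ValueError(f"log_likelihood returned NaN at {theta}")
        if np.isfinite(ll):
            return theta
    raise RuntimeError("could not find a starting point with finite log-likelihood")


def run_mcmc(
    log_likelihood: Callable[[np.ndarray], float],
    prior: PriorSpec,
    n_chains: int = 3,
    n_iter: int = 30_000,
    burn_in: int = 15_000,
    seed: int = 0,
) -> PosteriorChains:
    """Sample the posterior implied by ``log_likelihood`` and uniform priors.

    Runs ``n_chains`` chains of ``n_iter`` iterations each from random starts
    (chain ``c`` is seeded with ``seed + c``) and retains the draws after
    ``burn_in``. A NaN log-likelihood raises immediately, naming the offending
    parameter vector; 1000 consecutive all-rejected iterations trigger a
    stagnation warning.
    """
    if burn_in >= n_iter:
        raise ValueError("burn_in must be < n_iter")
    if n_chains < 1:
        raise ValueError("need at least one chain")
    lo, hi = prior.bounds()
    p = prior.n_params
    kept = np.empty((n_chains, n_iter - burn_in, p))
    acc_rates = []
    for c in range(n_chains):
        rng = np.random.default_rng(seed + c)
        theta = _find_start(log_likelihood, prior, rng)
        ll = log_likelihood(theta)
        step = 0.1 * (hi - lo)
        acc_win = np.zeros(p)
        n_win = 0
        accepted_post = 0
        stagnant = 0
        for t in range(n_iter):
            any_accept = False
            z = rng.standard_normal(p)
            u = rng.random(p)
            for j in range(p):
                prop = theta[j] + step[j] * z[j]
                if prop < lo[j] or prop > hi[j]:
                    continue  # outside prior support: reject
                theta_prop = theta.copy()
                theta_prop[j] = prop
                ll_prop = log_likelihood(theta_prop)
                if np.isnan(ll_prop):
                    raise ValueError(f"log_likelihood returned NaN at {theta_prop}")
                if ll_prop - ll > np.log(u[j]):
                    theta = theta_prop
                    ll = ll_prop
                    acc_win[j] += 1
                    any_accept = True
            n_win += 1
            if t < burn_in:
                if n_win == 50:  # adapt every 50 iterations, burn-in only
                    rate = acc_win / n_win
                    step *= np.exp(rate - _ACC_TARGET)
                    np.clip(step, 1e-6 * (hi - lo), hi - lo, out=step)
                    acc_win[:] = 0.0
                    n_win = 0
            else:
                if t == burn_in:
                    acc_win[:] = 0.0
                    n_win = 1
                accepted_post += int(any_accept)
                kept[c, t - burn_in] = theta
            stagnant = 0 if any_accept else stagnant + 1
            if stagnant == _STAGNATION_WINDOW:
                warnings.warn(
                    f"chain {c}: no proposal accepted for {_STAGNATION_WINDOW} "
                    "consecutive iterations; the sampler may be stuck",
                    RuntimeWarning,
                )
        acc_rates.append(accepted_post / (n_iter - burn_in))
    rhat_vals, degenerate = gelman_rubin(kept, return_degeneracy=True)
    rhat = {name: float(rhat_vals[j]) for j, name in enumerate(prior.names)}
    return PosteriorChains(
        names=list(prior.names),
        draws=kept,
        rhat=rhat,
        acceptance_rates=acc_rates,
        seed=seed,
        degenerate=degenerate,
    )


def gelman_rubin(draws: np.ndarray, return_degeneracy: bool = False):
    """Split-R-hat per parameter for draws of shape (chains, iterations, params).

    Each chain is split in half, doubling the chain count, and the classic
    between/within variance ratio is computed. Values near 1 indicate
    convergence. If every (split) chain has zero within-chain variance the
    statistic is 1 by convention and the degeneracy flag is set.
    """
    draws = np.asarray(draws, float)
    if draws.ndim == 2:
        draws = draws[:, :, None]
    n_chains, n_iter, n_params = draws.shape
    if n_chains < 2 and n_iter < 20:
        raise ValueError("need >= 2 chains or enough draws to split")
    half = n_iter // 2
    split = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    m, n = split.shape[0], split.shape[1]
    if n < 5:
        raise ValueError("too few post-burn-in draws for split R-hat")
    means = split.mean(axis=1)  # (m, params)
    variances = split.var(axis=1, ddof=1)
    w = variances.mean(axis=0)
    b = n * means.var(axis=0, ddof=1)
    rhat = np.ones(n_params)
    degenerate = False
    for j in range(n_params):
        if w[j] <= 0:
            degenerate = True  # all chains constant: R-hat 1 by convention
            continue
        var_plus = (n - 1) / n * w[j] + b[j] / n
        rhat[j] = np.sqrt(var_plus / w[j])
    if return_degeneracy:
        return rhat, degenerate
    return rhat


def credible_interval(
    chains: "PosteriorChains | np.ndarray",
    level: float = 0.95,
    names: Optional[Sequence[str]] = None,
) -> Dict[str, IntervalEstimate]:
    """Equal-tailed posterior quantile interval per parameter (point = median)."""
    if isinstance(chains, PosteriorChains):
        flat, names = chains.flat, list(chains.names)
    else:
        flat = np.asarray(chains, float)
        if flat.ndim == 1:
            flat = flat[:, None]
        flat = flat.reshape(-1, flat.shape[-1])
        if names is None:
            names = [f"p{j}" for j in range(flat.shape[1])]
    if flat.shape[0] < 100:
        raise ValueError("need >= 100 draws for a credible interval")
    alpha = 1.0 - level
    out = {}
    for j, name in enumerate(names):
        col = flat[:, j]
        lower, med, upper = np.quantile(col, [alpha / 2, 0.5, 1 - alpha / 2])
        out[name] = IntervalEstimate(
            point=float(med),
            lower=float(lower),
            upper=float(upper),
            level=level,
            method="posterior_quantile",
        )
    return out


def dic(chains: PosteriorChains, log_likelihood: Callable[[np.ndarray], float]):
    """Deviance information criterion with the posterior-mean plug-in.

    D(theta) = -2 log L(theta); pD = mean(D) - D(theta_bar);
    DIC = D(theta_bar) + 2 pD. Falls back to the posterior median with a
    warning if the likelihood is undefined at the posterior mean. The computed
    (pD, DIC) pair is also stored on ``chains``.
    """
    flat = chains.flat
    dev = np.array([-2.0 * log_likelihood(theta) for theta in flat])
    theta_hat = chains.posterior_mean()
    d_hat = -2.0 * log_likelihood(theta_hat)
    if not np.isfinite(d_hat):
        warnings.warn(
            "deviance undefined at the posterior mean; using the posterior median",
            RuntimeWarning,
        )
        d_hat = -2.0 * log_likelihood(chains.posterior_median())
    p_d = float(dev.mean() - d_hat)
    dic_val = float(d_hat + 2.0 * p_d)
    chains.pd_ = p_d
    chains.dic = dic_val
    return p_d, dic_val
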