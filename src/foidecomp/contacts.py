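"""Holling Type II contact-rate functional response and its normal likelihood.

The expected number of contacts a focal snail makes with partner hosts over an
observation window of T minutes at partner density N is

    contacts(N) = (e * T * N) / (1 + e * H * (N - 1)),

where e is the encounter rate (encounters min^-1 per unit density) and H the
contact handling time (minutes a contact lasts, during which no new contact
begins). The (N - 1) term reflects that the focal individual's first partner
does not compete with itself for handling time; as N grows the curve saturates
at the ceiling T / H. Container means are modelled as normal around this curve
with constant residual SD sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Sequence

import numpy as np
import pandas as pd

from .mcmc import PosteriorChains, PriorSpec, credible_interval
from .records import ContactTrial

__all__ = [
    "HollingParams",
    "holling_mean_contacts",
    "contacts_loglik",
    "make_contacts_loglik",
    "compare_functional_responses",
    "fitted_curve_table",
    "CONTACT_PRIOR",
]

#: uniform prior supports: e in [0, 1] min^-1, H in [0, 44] min, sigma in (0, 20]
CONTACT_PRIOR = PriorSpec(
    names=("encounter_rate", "handling_time", "sigma"),
    lower=(0.0, 0.0, 1e-6),
    upper=(1.0, 44.0, 20.0),
)


@dataclass(frozen=True)
class HollingParams:
    encounter_rate: float  # e, encounters min^-1 per unit density
    handling_time: float  # H, minutes per contact
    sigma: float = 1.0  # residual SD of container mean contacts

    def __post_init__(self) -> None:
        if not 0 <= self.encounter_rate <= 1:
            raise ValueError("encounter_rate must lie in [0, 1] (prior support)")
        if not 0 <= self.handling_time <= 44:
            raise ValueError("handling_time must lie in [0, 44] min (prior support)")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def as_vector(self) -> np.ndarray:
        return np.array([self.encounter_rate, self.handling_time, self.sigma])


def holling_mean_contacts(
    params: HollingParams,
    density: float,
    obs_minutes: float = 45.0,
    minus_one: bool = True,
) -> float:
    """Expected contacts per focal individual over the observation window.

    ``minus_one`` keeps the (N - 1) denominator term of the original
    intraspecific formulation (the default); setting it False uses N instead,
    for sensitivity analysis.
    """
    if density < 1:
        raise ValueError(f"density must be >= 1, got {density}")
    if obs_minutes <= 0:
        raise ValueError("obs_minutes must be > 0")
    e, h = params.encounter_rate, params.handling_time
    n_eff = density - 1 if minus_one else density
    return (e * obs_minutes * density) / (1.0 + e * h * n_eff)


def make_contacts_loglik(
    trials: Sequence[ContactTrial], minus_one: bool = True
) -> Callable[[np.ndarray], float]:
    """Vectorised normal log-likelihood of container means as a callable on
    (encounter_rate, handling_time, sigma) for the MCMC engine."""
    if not trials:
        raise ValueError("trials must be non-empty")
    dens = np.array([t.alt_density for t in trials], float)
    obs = np.array([t.mean_contacts for t in trials], float)
    t_min = np.array([t.obs_minutes for t in trials], float)
    n_eff = dens - 1 if minus_one else dens

    def loglik(theta: np.ndarray) -> float:
        e, h, sigma = theta
        if sigma <= 0:
            return -np.inf
        mu = (e * t_min * dens) / (1.0 + e * h * n_eff)
        resid = obs - mu
        return float(
            -0.5 * dens.size * math.log(2 * math.pi)
            - dens.size * math.log(sigma)
            - 0.5 * np.sum(resid**2) / sigma**2
        )

    return loglik


def contacts_loglik(params: HollingParams, trials: Sequence[ContactTrial]) -> float:
    """Normal log-likelihood of the container means at fixed parameters."""
    if params.sigma <= 0:
        raise ValueError("sigma must be > 0")
    return make_contacts_loglik(trials)(params.as_vector())


def compare_functional_responses(
    fit_a: PosteriorChains, fit_b: PosteriorChains, level: float = 0.95
) -> pd.DataFrame:
    """Compare two fitted functional responses parameter by parameter.

    For each shared parameter, reports both credible intervals, whether they
    overlap, and the posterior probability P(a > b) computed by pairing pooled
    draws (ties count half).
    """
    if list(fit_a.names) != list(fit_b.names):
        raise ValueError(
            f"mismatched parameterizations: {list(fit_a.names)} vs {list(fit_b.names)}"
        )
    ci_a = credible_interval(fit_a, level=level)
    ci_b = credible_interval(fit_b, level=level)
    flat_a, flat_b = fit_a.flat, fit_b.flat
    m = min(flat_a.shape[0], flat_b.shape[0])
    rows = []
    for j, name in enumerate(fit_a.names):
        a, b = ci_a[name], ci_b[name]
        overlap = (a.lower <= b.upper) and (b.lower <= a.upper)
        da, db = flat_a[:m, j], flat_b[:m, j]
        p_gt = float(np.mean(da > db) + 0.5 * np.mean(da == db))
        rows.append(
            {
                "parameter": name,
                "a_median": a.point,
                "a_lower": a.lower,
                "a_upper": a.upper,
                "b_median": b.point,
                "b_lower": b.lower,
                "b_upper": b.upper,
                "overlap": overlap,
                "p_a_gt_b": p_gt,
            }
        )
    return pd.DataFrame(rows)


def fitted_curve_table(
    chains: PosteriorChains,
    densities: Sequence[int],
    obs_minutes: float = 45.0,
    level: float = 0.95,
    minus_one: bool = True,
) -> pd.DataFrame:
    """Posterior predicted mean-contact curve with a credible band.

    One row per density: posterior median of the Holling mean and equal-tailed
    band quantiles over the pooled draws.
    """
    flat = chains.flat
    e = flat[:, list(chains.names).index("encounter_rate")]
    h = flat[:, list(chains.names).index("handling_time")]
    alpha = 1 - level
    rows = []
    for n in densities:
        n_eff = n - 1 if minus_one else n
        mu = (e * obs_minutes * n) / (1.0 + e * h * n_eff)
        lo, med, hi = np.quantile(mu, [alpha / 2, 0.5, 1 - alpha / 2])
        rows.append(
            {"density": n, "predicted_mean": med, "band_lower": lo, "band_upper": hi}
        )
    return pd.DataFrame(rows)
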