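"""Multi-host force of infection (FOI) for a focal snail host.

The focal host's FOI sums an intraspecific and an interspecific term,

    FOI_F = beta_FF * N_F^k_FF * (I_F / N_F) + beta_FA * N_A^k_FA * (I_A / N_A),

where N and I are total and infested densities (snails per 0.1 m^2) of the
focal (F) and alternative (A) host, beta are transmission rates and the
unitless exponents k interpolate between frequency-dependent (k = 0, FOI
scales with prevalence I/N) and density-dependent (k = 1, FOI scales with
infested density I) transmission. A sentinel host caged for t days becomes
infested with probability 1 - exp(-FOI_F * t), which turns enclosure-trial
counts into a binomial likelihood for (beta, k).

The same FOI can be assembled mechanistically from per-species components,
contact rate x transmission success x prevalence, which is how the laboratory
experiments decompose the field estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln

from .mcmc import PriorSpec
from .records import FieldObservation, SentinelTrial

__all__ = [
    "FOIParams",
    "FOIComponents",
    "foi_multi_host",
    "prob_infested",
    "pair_trials_to_fields",
    "sentinel_loglik",
    "foi_from_components",
    "make_sentinel_loglik",
    "FOI_PRIOR",
    "SINGLE_HOST_PRIOR",
]

#: clamp for infestation probabilities inside the likelihood (MCMC stability)
_P_EPS = 1e-12

#: prior support for transmission rates and density-dependence exponents
FOI_PRIOR = PriorSpec(
    names=("beta_FF", "k_FF", "beta_FA", "k_FA"),
    lower=(0.0, 0.0, 0.0, 0.0),
    upper=(2.0, 1.0, 2.0, 1.0),
)

#: nested focal-only model (beta_FA fixed at 0)
SINGLE_HOST_PRIOR = PriorSpec(names=("beta_FF", "k_FF"), lower=(0.0, 0.0), upper=(2.0, 1.0))


@dataclass(frozen=True)
class FOIParams:
    """Transmission rates and density-dependence exponents of the FOI model."""

    beta_FF: float
    k_FF: float
    beta_FA: float = 0.0
    k_FA: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.beta_FF <= 2 and 0 <= self.beta_FA <= 2):
            raise ValueError("transmission rates must lie in [0, 2] (prior support)")
        if not (0 <= self.k_FF <= 1 and 0 <= self.k_FA <= 1):
            raise ValueError("density-dependence exponents must lie in [0, 1]")

    def as_vector(self) -> np.ndarray:
        return np.array([self.beta_FF, self.k_FF, self.beta_FA, self.k_FA])

    @classmethod
    def from_vector(cls, theta: Sequence[float]) -> "FOIParams":
        theta = list(theta)
        if len(theta) == 2:
            return cls(beta_FF=theta[0], k_FF=theta[1])
        return cls(beta_FF=theta[0], k_FF=theta[1], beta_FA=theta[2], k_FA=theta[3])


@dataclass(frozen=True)
class FOIComponents:
    """One species' mechanistic FOI contribution: contact x success x prevalence."""

    contact_rate: float  # c(N), contacts per susceptible per day
    success_prob: float  # v, transmission probability per infectious contact
    prevalence: float  # I/N, probability a contact is with an infested host

    def __post_init__(self) -> None:
        if self.contact_rate < 0:
            raise ValueError("contact_rate must be >= 0")
        if not 0 <= self.success_prob <= 1:
            raise ValueError("success_prob must lie in [0, 1]")
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must lie in [0, 1]")


def _species_term(beta: float, k: float, n: float, i: float) -> float:
    # N = 0 implies I = 0; the term is defined as 0 (avoids 0^0 and 0/0)
    if n == 0:
        return 0.0
    return beta * n**k * (i / n)


def foi_multi_host(params: FOIParams, n_f: float, i_f: float, n_a: float, i_a: float) -> float:
    """Focal-host force of infection (day^-1) from both host species.

    Densities are snails per 0.1 m^2; a species contributes 0 whenever its
    density is 0.
    """
    for n, i, label in ((n_f, i_f, "focal"), (n_a, i_a, "alternative")):
        if n < 0 or i < 0:
            raise ValueError(f"{label} densities must be >= 0")
        if i > n:
            raise ValueError(f"{label} infested density {i} exceeds total density {n}")
    return _species_term(params.beta_FF, params.k_FF, n_f, i_f) + _species_term(
        params.beta_FA, params.k_FA, n_a, i_a
    )


def prob_infested(foi: float, t: float) -> float:
    """Probability a sentinel is infested after t days of exposure: 1 - e^(-FOI t)."""
    if foi < 0 or t < 0:
        raise ValueError("foi and t must be >= 0")
    return -math.expm1(-foi * t)


def foi_from_components(
    components: Sequence[FOIComponents], susceptibles: Optional[float] = None
) -> float:
    """Sum the per-species contact x success x prevalence products.

    Returns the per-susceptible rate, or population incidence when the number
    of susceptible focal hosts is supplied.
    """
    rate = sum(c.contact_rate * c.success_prob * c.prevalence for c in components)
    return rate * susceptibles if susceptibles is not None else rate


class PairingError(ValueError):
    """A sentinel trial has no matching field observations for its week."""


def pair_trials_to_fields(
    trials: Sequence[SentinelTrial], fields: Sequence[FieldObservation]
) -> Dict[int, Tuple[float, float, float, float]]:
    """Week -> (N_F, I_F, N_A, I_A) covariates for each trial week.

    Site-level observations within a week are aggregated by the mean, so the
    FOI is held constant within a trial.
    """
    by_week: Dict[int, Dict[str, list]] = {}
    for obs in fields:
        by_week.setdefault(obs.week_index, {"focal": [], "alternative": []})[obs.species].append(obs)
    out = {}
    missing = []
    for trial in trials:
        wk = trial.week_index
        week_obs = by_week.get(wk, {"focal": [], "alternative": []})
        if not week_obs["focal"] or not week_obs["alternative"]:
            missing.append(wk)
            continue
        n_f = float(np.mean([o.density for o in week_obs["focal"]]))
        i_f = float(np.mean([o.infested_density for o in week_obs["focal"]]))
        n_a = float(np.mean([o.density for o in week_obs["alternative"]]))
        i_a = float(np.mean([o.infested_density for o in week_obs["alternative"]]))
        out[wk] = (n_f, i_f, n_a, i_a)
    if missing:
        raise PairingError(
            f"no focal+alternative field observations for trial week(s) {sorted(set(missing))}"
        )
    return out


def _trial_arrays(trials, fields):
    cov = pair_trials_to_fields(trials, fields)
    n_exp = np.array([t.n_exposed for t in trials], float)
    n_inf = np.array([t.n_infested for t in trials], float)
    t_days = np.array([t.duration_days for t in trials], float)
    nf, if_, na, ia = (np.array(v, float) for v in zip(*(cov[t.week_index] for t in trials)))
    # binomial coefficient term, constant in the parameters
    log_choose = gammaln(n_exp + 1) - gammaln(n_inf + 1) - gammaln(n_exp - n_inf + 1)
    return n_exp, n_inf, t_days, nf, if_, na, ia, log_choose


def make_sentinel_loglik(
    trials: Sequence[SentinelTrial],
    fields: Sequence[FieldObservation],
    single_host: bool = False,
) -> Callable[[np.ndarray], float]:
    """Vectorised binomial log-likelihood over trials, as a callable on the
    parameter vector (beta_FF, k_FF[, beta_FA, k_FA]) for the MCMC engine.

    Each trial contributes Binomial(n_exposed, p) mass at n_infested with
    p = 1 - exp(-FOI * duration); p is clamped to [1e-12, 1 - 1e-12] so the
    log stays finite when the data contradict a boundary parameter.
    """
    n_exp, n_inf, t_days, nf, if_, na, ia, log_choose = _trial_arrays(trials, fields)
    prev_f = np.divide(if_, nf, out=np.zeros_like(if_), where=nf > 0)
    prev_a = np.divide(ia, na, out=np.zeros_like(ia), where=na > 0)
    const = float(log_choose.sum())

    def loglik(theta: np.ndarray) -> float:
        beta_ff, k_ff = theta[0], theta[1]
        foi = beta_ff * np.where(nf > 0, nf, 1.0) ** k_ff * prev_f
        if not single_host:
            beta_fa, k_fa = theta[2], theta[3]
            foi = foi + beta_fa * np.where(na > 0, na, 1.0) ** k_fa * prev_a
        p = -np.expm1(-foi * t_days)
        p = np.clip(p, _P_EPS, 1.0 - _P_EPS)
        return const + float(np.sum(n_inf * np.log(p) + (n_exp - n_inf) * np.log1p(-p)))

    return loglik


def sentinel_loglik(
    params: FOIParams,
    trials: Sequence[SentinelTrial],
    fields: Sequence[FieldObservation],
) -> float:
    """Binomial log-likelihood of the sentinel data at a fixed parameter set."""
    return make_sentinel_loglik(trials, fields)(params.as_vector())
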