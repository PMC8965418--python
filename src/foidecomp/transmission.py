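"""Laboratory transmission-success analysis.

Each replicate pairs an infested donor snail with an uninfested receiver for
18 h; the response is the proportion of snail-attached symbionts found on the
receiver at dissection. Worms recovered loose in cups or missing entirely are
excluded from that denominator (they never had the donor-to-receiver choice)
but are tracked by the fate-accounting table. Dispersal is analysed with a
binomial GLM (logit link) with a treatment (intraspecific vs interspecific
pairing) x source (wild host species the worms came from) interaction, and
total surviving symbionts with a Poisson GLM (log link). Reference levels are
fixed at treatment = intraspecific and source = alternative_sourced so
coefficient signs are reproducible; ``source_reference`` flips the source
baseline for the parameterization in which the interspecific effect is read
within focal-sourced replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .intervals import binom_ci
from .records import SOURCES, TREATMENTS, TransmissionReplicate

__all__ = [
    "GLMFit",
    "dispersal_summary",
    "fit_binomial_glm",
    "fit_poisson_glm",
    "worm_accounting",
    "model_replicates",
]

#: |coefficient| beyond this on the link scale is flagged as separation/divergence
_DIVERGENCE_LIMIT = 15.0
#: replicates shorter than this (the early 1 h batch) are excluded from model fits
FULL_TRIAL_HOURS = 18.0


@dataclass
class GLMFit:
    """A fitted GLM on the link scale: named coefficients with Wald z-tests."""

    coefficients: Dict[str, float]
    standard_errors: Dict[str, float]
    z_values: Dict[str, float]
    p_values: Dict[str, float]
    residual_df: int
    deviance: float
    link: str
    diverged: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.link not in ("logit", "log"):
            raise ValueError(f"link must be 'logit' or 'log', got {self.link!r}")
        if self.residual_df < 0:
            raise ValueError("residual_df must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coefficients,
                "std_error": self.standard_errors,
                "z": self.z_values,
                "p_value": self.p_values,
            }
        ).rename_axis("term")


def model_replicates(
    replicates: Sequence[TransmissionReplicate],
    full_trials_only: bool = True,
    require_attached: bool = True,
) -> List[TransmissionReplicate]:
    """Apply the model-fitting exclusions: drop the early short (1 h)
    replicates and, optionally, replicates with no snail-attached worms."""
    out = []
    for r in replicates:
        if full_trials_only and r.duration_hours < FULL_TRIAL_HOURS:
            continue
        if require_attached and r.attached_total < 1:
            continue
        out.append(r)
    return out


def dispersal_summary(
    replicates: Sequence[TransmissionReplicate], level: float = 0.95
) -> pd.DataFrame:
    """Pooled dispersal proportion per treatment x source cell, with an exact
    binomial interval.

    The proportion is sum(on_receiver) / sum(on_donor + on_receiver) over
    contributing replicates; replicates with zero attached worms are counted
    in ``n_excluded``. Empty cells are flagged, not raised.
    """
    rows = []
    for treatment in TREATMENTS:
        for source in SOURCES:
            cell = [r for r in replicates if r.treatment == treatment and r.source == source]
            contributing = [r for r in cell if r.attached_total >= 1]
            dispersed = sum(r.on_receiver for r in contributing)
            attached = sum(r.attached_total for r in contributing)
            row = {
                "treatment": treatment,
                "source": source,
                "n_replicates": len(cell),
                "n_excluded": len(cell) - len(contributing),
                "dispersed": dispersed,
                "attached": attached,
                "empty": attached == 0,
            }
            if attached > 0:
                ci = binom_ci(dispersed, attached, level=level)
                row.update(proportion=ci.point, ci_lower=ci.lower, ci_upper=ci.upper)
            else:
                row.update(proportion=np.nan, ci_lower=np.nan, ci_upper=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def _design_matrix(
    replicates: Sequence[TransmissionReplicate],
    include_interaction: bool,
    source_reference: str,
) -> Tuple[np.ndarray, List[str]]:
    if source_reference not in SOURCES:
        raise ValueError(f"source_reference must be one of {SOURCES}")
    other_source = [s for s in SOURCES if s != source_reference][0]
    treat = np.array([1.0 if r.treatment == "interspecific" else 0.0 for r in replicates])
    src = np.array([1.0 if r.source == other_source else 0.0 for r in replicates])
    cols = [np.ones(len(replicates)), treat, src]
    names = ["intercept", "treatment[interspecific]", f"source[{other_source}]"]
    if include_interaction:
        cols.append(treat * src)
        names.append(f"treatment[interspecific]:source[{other_source}]")
    return np.column_stack(cols), names


def _wrap_fit(res, names: List[str], link: str) -> GLMFit:
    coefs = dict(zip(names, np.asarray(res.params, float)))
    ses = dict(zip(names, np.asarray(res.bse, float)))
    zs = dict(zip(names, np.asarray(res.tvalues, float)))
    ps = dict(zip(names, np.asarray(res.pvalues, float)))
    diverged = [n for n, c in coefs.items() if abs(c) > _DIVERGENCE_LIMIT]
    return GLMFit(
        coefficients=coefs,
        standard_errors=ses,
        z_values=zs,
        p_values=ps,
        residual_df=int(res.df_resid),
        deviance=float(res.deviance),
        link=link,
        diverged=diverged,
    )


def fit_binomial_glm(
    replicates: Sequence[TransmissionReplicate],
    include_interaction: bool = True,
    source_reference: str = "alternative_sourced",
    apply_exclusions: bool = True,
) -> GLMFit:
    """Binomial GLM (logit link) of dispersed/attached ~ treatment * source.

    The replicate-level response is (on_receiver successes out of attached
    trials), fitted by IRLS. By default the early 1 h replicates and
    replicates with no attached worms are excluded. Coefficients whose
    magnitude exceeds 15 on the logit scale are flagged in ``diverged``
    (complete separation).
    """
    if apply_exclusions:
        replicates = model_replicates(replicates)
    cells = {(r.treatment, r.source) for r in replicates}
    if len(cells) < 3:
        raise ValueError(
            f"need replicates in >= 3 of the 4 treatment x source cells, got {len(cells)}"
        )
    x, names = _design_matrix(replicates, include_interaction, source_reference)
    endog = np.column_stack(
        [
            [r.on_receiver for r in replicates],
            [r.on_donor for r in replicates],
        ]
    ).astype(float)
    model = sm.GLM(endog, x, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-10)
    if not res.converged:
        raise RuntimeError(f"IRLS did not converge in 100 iterations (deviance {res.deviance})")
    return _wrap_fit(res, names, "logit")


def fit_poisson_glm(
    replicates: Sequence[TransmissionReplicate],
    apply_exclusions: bool = True,
) -> GLMFit:
    """Poisson GLM (log link) of recovered_total ~ treatment.

    For a single factor the exponentiated treatment coefficient equals the
    ratio of group mean counts. A group with all-zero counts drives the
    intercept or effect to -inf; that is surfaced via the ``diverged`` flag.
    """
    if apply_exclusions:
        replicates = model_replicates(replicates, require_attached=False)
    if not replicates:
        raise ValueError("no replicates to fit")
    y = np.array([r.recovered_total for r in replicates], float)
    treat = np.array([1.0 if r.treatment == "interspecific" else 0.0 for r in replicates])
    x = np.column_stack([np.ones(len(replicates)), treat])
    names = ["intercept", "treatment[interspecific]"]
    model = sm.GLM(y, x, family=sm.families.Poisson())
    res = model.fit(maxiter=100, tol=1e-10)
    if not res.converged:
        raise RuntimeError(f"IRLS did not converge in 100 iterations (deviance {res.deviance})")
    return _wrap_fit(res, names, "log")


def worm_accounting(replicates: Sequence[TransmissionReplicate]) -> pd.DataFrame:
    """Fate table per treatment x source cell.

    Sums worms by final location, with ``missing`` floored at zero per
    replicate (recovered totals can exceed additions through asexual
    reproduction; the surplus is reported as ``excess``). ``pct_*_cup``
    columns break the unattached (cup-recovered) worms down by cup, and
    ``pct_unattached`` is the unattached share of all recovered worms.
    """
    rows = []
    for treatment in TREATMENTS:
        for source in SOURCES:
            cell = [r for r in replicates if r.treatment == treatment and r.source == source]
            if not cell:
                continue
            added = sum(r.worms_added for r in cell)
            donor = sum(r.on_donor for r in cell)
            receiver = sum(r.on_receiver for r in cell)
            donor_cup = sum(r.in_donor_cup for r in cell)
            exp_cup = sum(r.in_experimental_cup for r in cell)
            recv_cup = sum(r.in_receiver_cup for r in cell)
            recovered = donor + receiver + donor_cup + exp_cup + recv_cup
            missing = sum(r.missing for r in cell)
            excess = sum(r.excess for r in cell)
            unattached = donor_cup + exp_cup + recv_cup
            rows.append(
                {
                    "treatment": treatment,
                    "source": source,
                    "n_replicates": len(cell),
                    "worms_added": added,
                    "on_donor": donor,
                    "on_receiver": receiver,
                    "donor_cup": donor_cup,
                    "experimental_cup": exp_cup,
                    "receiver_cup": recv_cup,
                    "recovered": recovered,
                    "unattached": unattached,
                    "missing": missing,
                    "excess": excess,
                    "pct_unattached": 100.0 * unattached / recovered if recovered else np.nan,
                    "pct_donor_cup": 100.0 * donor_cup / unattached if unattached else np.nan,
                    "pct_experimental_cup": 100.0 * exp_cup / unattached if unattached else np.nan,
                    "pct_receiver_cup": 100.0 * recv_cup / unattached if unattached else np.nan,
                    "pct_missing": 100.0 * missing / added if added else np.nan,
                }
            )
    return pd.DataFrame(rows)
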