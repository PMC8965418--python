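"""Orchestration of the full analysis: simulate -> fit -> compare -> report.

Each ``cmd_*`` function is a pure function of (inputs, settings, seed): it
reads CSVs through :mod:`foidecomp.io`, runs the corresponding fit, writes
machine-readable outputs (CSV/JSON) into an output directory and returns the
summary dictionary. A run log (config hash, seed, versions, wall time) is
appended to ``run.log``; results are never interleaved with logs.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .contacts import CONTACT_PRIOR, fitted_curve_table, make_contacts_loglik
from .foi import FOI_PRIOR, SINGLE_HOST_PRIOR, make_sentinel_loglik
from .io import read_table, write_table
from .mcmc import PosteriorChains, credible_interval, dic, run_mcmc
from .synth import SimulationConfig, simulate_all
from .transmission import (
    dispersal_summary,
    fit_binomial_glm,
    fit_poisson_glm,
    worm_accounting,
)

__all__ = [
    "MCMCSettings",
    "FAST_SETTINGS",
    "FULL_SETTINGS",
    "ConvergenceError",
    "cmd_simulate",
    "cmd_fit_foi",
    "cmd_fit_contacts",
    "cmd_fit_transmission",
    "cmd_report",
]

#: R-hat threshold below which all chains must sit for a fit to be accepted
RHAT_LIMIT = 1.01


@dataclass(frozen=True)
class MCMCSettings:
    n_chains: int = 3
    n_iter: int = 30_000
    burn_in: int = 15_000

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_iter <= self.burn_in or self.burn_in < 0:
            raise ValueError("need n_chains >= 1 and 0 <= burn_in < n_iter")


FULL_SETTINGS = MCMCSettings()
#: reduced profile for quick runs and repeated simulation studies
FAST_SETTINGS = MCMCSettings(n_chains=3, n_iter=4_000, burn_in=2_000)


class ConvergenceError(RuntimeError):
    """A fitted model failed the R-hat < 1.01 convergence criterion."""


def _log_run(out_dir: Path, command: str, config: dict, seed: Optional[int], t0: float) -> None:
    payload = json.dumps(config, sort_keys=True, default=str)
    digest = hashlib.sha256(payload.encode()).hexdigest()[:16]
    line = (
        f"{time.strftime('%Y-%m-%dT%H:%M:%S')} command={command} config_sha256={digest} "
        f"seed={seed} foidecomp={__version__} numpy={np.__version__} "
        f"wall_seconds={time.time() - t0:.1f}"
    )
    print(line, file=sys.stderr)
    with open(out_dir / "run.log", "a", encoding="utf-8") as fh:
        fh.write(line + "\n")


def _check_convergence(chains: PosteriorChains, label: str, allow_unconverged: bool) -> None:
    bad = {k: v for k, v in chains.rhat.items() if v >= RHAT_LIMIT}
    if bad and not allow_unconverged:
        raise ConvergenceError(f"{label}: R-hat >= {RHAT_LIMIT} for {bad}")


def _summary_dict(chains: PosteriorChains) -> dict:
    summ = chains.summary()
    return {
        "parameters": summ.to_dict(orient="records"),
        "acceptance_rates": list(map(float, chains.acceptance_rates)),
        "pd": chains.pd_,
        "dic": chains.dic,
        "seed": chains.seed,
    }


def cmd_simulate(config: SimulationConfig, out_dir, seed: Optional[int] = None) -> Dict[str, Path]:
    """Write all four synthetic CSVs plus truth.json; idempotent given seed."""
    t0 = time.time()
    if seed is not None:
        config = SimulationConfig(
            seed=seed,
            foi_truth=config.foi_truth,
            season=config.season,
            sentinel=config.sentinel,
            contact=config.contact,
            dispersal=config.dispersal,
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = simulate_all(config)
    paths = {}
    for kind in ("field_survey", "sentinel_trials", "contact_trials", "transmission"):
        path = out_dir / f"{kind}.csv"
        write_table(data[kind], path)
        paths[kind] = path
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(data["truth"], indent=2, sort_keys=True) + "\n")
    paths["truth"] = truth_path
    _log_run(out_dir, "simulate", data["truth"], config.seed, t0)
    return paths


def cmd_fit_foi(
    field_csv,
    sentinel_csv,
    out_dir,
    seed: int = 0,
    settings: MCMCSettings = FULL_SETTINGS,
    allow_unconverged: bool = False,
) -> dict:
    """Fit the multi-host FOI model and its nested single-host (focal-only)
    variant, then compare them by DIC.

    Writes posterior draws, per-model summaries with credible intervals and
    R-hat, and a DIC comparison table. Raises :class:`ConvergenceError` if any
    R-hat >= 1.01 unless ``allow_unconverged``.
    """
    t0 = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fields = read_table(field_csv, "field_survey")
    trials = read_table(sentinel_csv, "sentinel_trials")
    results = {}
    for label, prior, single in (
        ("multi_host", FOI_PRIOR, False),
        ("single_host", SINGLE_HOST_PRIOR, True),
    ):
        loglik = make_sentinel_loglik(trials, fields, single_host=single)
        chains = run_mcmc(
            loglik,
            prior,
            n_chains=settings.n_chains,
            n_iter=settings.n_iter,
            burn_in=settings.burn_in,
            seed=seed,
        )
        _check_convergence(chains, f"foi {label}", allow_unconverged)
        dic(chains, loglik)
        chains.to_dataframe().to_csv(out_dir / f"posterior_foi_{label}.csv", index=False)
        results[label] = _summary_dict(chains)
    comparison = pd.DataFrame(
        [
            {"model": label, "pd": res["pd"], "dic": res["dic"]}
            for label, res in results.items()
        ]
    )
    comparison["delta_dic"] = comparison["dic"] - comparison["dic"].min()
    comparison.to_csv(out_dir / "dic_comparison.csv", index=False)
    summary = {"models": results, "preferred_model": comparison.loc[comparison["dic"].idxmin(), "model"]}
    (out_dir / "foi_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    _log_run(out_dir, "fit-foi", {"settings": str(settings)}, seed, t0)
    return summary


def cmd_fit_contacts(
    contact_csv,
    out_dir,
    seed: int = 0,
    settings: MCMCSettings = FULL_SETTINGS,
    allow_unconverged: bool = False,
) -> dict:
    """Fit the Holling Type II contact model; write posterior, summary and a
    fitted-curve table (density, predicted mean, 95% band)."""
    t0 = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trials = read_table(contact_csv, "contact_trials")
    loglik = make_contacts_loglik(trials)
    chains = run_mcmc(
        loglik,
        CONTACT_PRIOR,
        n_chains=settings.n_chains,
        n_iter=settings.n_iter,
        burn_in=settings.burn_in,
        seed=seed,
    )
    _check_convergence(chains, "contacts", allow_unconverged)
    dic(chains, loglik)
    chains.to_dataframe().to_csv(out_dir / "posterior_contacts.csv", index=False)
    densities = sorted({t.alt_density for t in trials})
    obs_minutes = trials[0].obs_minutes
    fitted_curve_table(chains, densities, obs_minutes).to_csv(
        out_dir / "contact_curve.csv", index=False
    )
    summary = _summary_dict(chains)
    (out_dir / "contacts_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    _log_run(out_dir, "fit-contacts", {"settings": str(settings)}, seed, t0)
    return summary


def cmd_fit_transmission(transmission_csv, out_dir) -> dict:
    """Run the transmission-success analysis: dispersal proportions with exact
    intervals, binomial GLMs in both source parameterizations plus a
    main-effects fit, the Poisson survival GLM on the alternative-sourced
    experiment, and the worm-fate table."""
    t0 = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reps = read_table(transmission_csv, "transmission")
    disp = dispersal_summary(reps)
    disp.to_csv(out_dir / "dispersal_summary.csv", index=False)
    fate = worm_accounting(reps)
    fate.to_csv(out_dir / "fate_table.csv", index=False)
    fits = {
        "binomial_interaction_altref": fit_binomial_glm(reps, source_reference="alternative_sourced"),
        "binomial_interaction_focalref": fit_binomial_glm(reps, source_reference="focal_sourced"),
        "binomial_main_effects": fit_binomial_glm(reps, include_interaction=False),
    }
    alt_sourced = [r for r in reps if r.source == "alternative_sourced"]
    fits["poisson_survival_alt_sourced"] = fit_poisson_glm(alt_sourced)
    summary = {}
    for label, fit in fits.items():
        fit.to_frame().to_csv(out_dir / f"glm_{label}.csv")
        summary[label] = {
            "coefficients": fit.coefficients,
            "standard_errors": fit.standard_errors,
            "p_values": fit.p_values,
            "residual_df": fit.residual_df,
            "deviance": fit.deviance,
            "diverged": fit.diverged,
        }
    summary["dispersal"] = disp.to_dict(orient="records")
    (out_dir / "transmission_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    _log_run(out_dir, "fit-transmission", {}, None, t0)
    return summary


def _fmt_ci(row) -> str:
    return f"{row['median']:.4g} (95% CI {row['ci_lower']:.4g}-{row['ci_upper']:.4g}, R-hat {row['rhat']:.3f})"


def cmd_report(out_dir, report_name: str = "report.md") -> Path:
    """Assemble a single human-readable summary from whatever outputs exist
    in ``out_dir``; absent analyses are marked as such."""
    t0 = time.time()
    out_dir = Path(out_dir)
    lines = ["# Transmission decomposition report", ""]

    foi_path = out_dir / "foi_summary.json"
    lines.append("## Force of infection (field sentinel trials)")
    if foi_path.exists():
        foi = json.loads(foi_path.read_text())
        for label, res in foi["models"].items():
            lines.append(f"### {label.replace('_', ' ')} model")
            for p in res["parameters"]:
                lines.append(f"- {p['parameter']}: {_fmt_ci(p)}")
            lines.append(f"- pD = {res['pd']:.2f}, DIC = {res['dic']:.2f}")
        lines.append(f"Preferred by DIC: **{foi['preferred_model']}**")
    else:
        lines.append("_absent_")
    lines.append("")

    contacts_path = out_dir / "contacts_summary.json"
    lines.append("## Contact-rate functional response (laboratory)")
    if contacts_path.exists():
        res = json.loads(contacts_path.read_text())
        for p in res["parameters"]:
            lines.append(f"- {p['parameter']}: {_fmt_ci(p)}")
    else:
        lines.append("_absent_")
    lines.append("")

    trans_path = out_dir / "transmission_summary.json"
    lines.append("## Transmission success (laboratory)")
    if trans_path.exists():
        res = json.loads(trans_path.read_text())
        lines.append("Pooled dispersal proportions (dispersed / snail-attached):")
        for row in res["dispersal"]:
            if row.get("empty"):
                lines.append(f"- {row['treatment']} x {row['source']}: no attached worms")
            else:
                lines.append(
                    f"- {row['treatment']} x {row['source']}: "
                    f"{100 * row['proportion']:.1f}% "
                    f"(95% CI {100 * row['ci_lower']:.1f}-{100 * row['ci_upper']:.1f}%)"
                )
        glm = res["binomial_interaction_altref"]
        lines.append("Binomial GLM (logit; reference intraspecific, alternative-sourced):")
        for term, coef in glm["coefficients"].items():
            lines.append(
                f"- {term}: {coef:.2f} +/- {glm['standard_errors'][term]:.2f} "
                f"(p = {glm['p_values'][term]:.2g})"
            )
    else:
        lines.append("_absent_")
    lines.append("")

    report_path = out_dir / report_name
    report_path.write_text("\n".join(lines) + "\n")
    _log_run(out_dir, "report", {}, None, t0)
    return report_path
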