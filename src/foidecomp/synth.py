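"""Synthetic datasets with known ground truth for every analysis stage.

Each generator draws data with exactly the statistical structure the
corresponding fit assumes, so parameter-recovery tests close the loop without
any field data. Defaults reproduce the study designs: a 21-week season with
the alternative host peaking early and the focal host late, eight sentinel
enclosure trials of caged focal hosts, a 16-density x 3-replicate contact
experiment observed for 45 min, and a four-cell transmission-success
experiment with replicate counts (20, 21, 40, 49) and 10 worms added per
donor.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .contacts import HollingParams, holling_mean_contacts
from .foi import FOIParams, foi_multi_host, prob_infested
from .records import (
    SOURCES,
    TREATMENTS,
    ContactTrial,
    FieldObservation,
    SentinelTrial,
    TransmissionReplicate,
)

__all__ = [
    "SeasonConfig",
    "SentinelDesign",
    "ContactDesign",
    "DispersalTruth",
    "SimulationConfig",
    "gen_field_season",
    "gen_contact_experiment",
    "gen_transmission_experiment",
    "simulate_all",
]

_CELLS: Tuple[Tuple[str, str], ...] = tuple(
    (t, s) for s in SOURCES for t in TREATMENTS
)


def _gauss_bump(week: np.ndarray, peak: float, peak_week: float, width: float) -> np.ndarray:
    return peak * np.exp(-(((week - peak_week) / width) ** 2))


@dataclass(frozen=True)
class SeasonConfig:
    """Weekly mean density/prevalence trajectories for both host species.

    Defaults sketch the observed seasonal succession: alternative-host
    densities peak early (around week 5), focal-host densities late (around
    week 14), and infestation prevalence rises above 70% late in the season
    before declining. Densities are snails per 0.1 m^2; surveys draw Poisson
    counts per site around the weekly mean.
    """

    n_weeks: int = 21
    n_sites: int = 8
    focal_peak_density: float = 20.0
    focal_peak_week: float = 14.0
    focal_width: float = 5.0
    alt_peak_density: float = 18.0
    alt_peak_week: float = 5.0
    alt_width: float = 4.0
    alt_baseline_density: float = 1.5
    prevalence_peak: float = 0.75
    prevalence_peak_week: float = 16.0
    prevalence_width: float = 4.0

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence_peak <= 1:
            raise ValueError("prevalence_peak must lie in [0, 1]")
        if self.n_weeks < 1 or self.n_sites < 1:
            raise ValueError("n_weeks and n_sites must be >= 1")

    def trajectories(self):
        week = np.arange(self.n_weeks, dtype=float)
        focal = _gauss_bump(week, self.focal_peak_density, self.focal_peak_week, self.focal_width)
        # the alternative host persists at low density after its early peak,
        # which is what exposes sentinels to it during the high-prevalence weeks
        alt = self.alt_baseline_density + _gauss_bump(
            week, self.alt_peak_density - self.alt_baseline_density,
            self.alt_peak_week, self.alt_width,
        )
        prev = _gauss_bump(week, self.prevalence_peak, self.prevalence_peak_week, self.prevalence_width)
        return focal, alt, prev


@dataclass(frozen=True)
class SentinelDesign:
    """Enclosure-trial layout: which weeks, how many sentinels, how long."""

    weeks: Sequence[int] = (1, 4, 6, 8, 10, 12, 15, 19)
    n_exposed: int = 40
    duration_days: float = 7.0

    def __post_init__(self) -> None:
        if not self.weeks:
            raise ValueError("sentinel design needs at least one trial week")
        if self.n_exposed < 1 or self.duration_days <= 0:
            raise ValueError("n_exposed must be >= 1 and duration_days > 0")


@dataclass(frozen=True)
class ContactDesign:
    """Contact-experiment layout and generating Holling parameters."""

    truth: HollingParams = HollingParams(encounter_rate=0.012, handling_time=3.25, sigma=1.0)
    densities: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 16, 18)
    replicates: int = 3
    obs_minutes: float = 45.0
    n_focal: int = 3

    def __post_init__(self) -> None:
        if not self.densities or self.replicates < 1:
            raise ValueError("contact design needs densities and >= 1 replicate")


@dataclass(frozen=True)
class DispersalTruth:
    """Per-cell worm-fate probabilities for the transmission experiment.

    Keys are (treatment, source) pairs. Each added worm independently fails
    to attach to the donor (-> donor cup) with ``attachment_failure``,
    otherwise dies unobserved with ``mortality``, otherwise disperses to the
    receiver with the cell's dispersal probability (staying on the donor
    otherwise). Attachment failure defaults high only in cells where the
    donor species differs from the wild source species, mirroring the
    host-preference barrier; mortality reflects the large fraction of worms
    lost during 18 h trials. Reproduction adds Poisson offspring per
    snail-attached worm (default off).
    """

    dispersal: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: {
            ("intraspecific", "focal_sourced"): 0.32,
            ("interspecific", "focal_sourced"): 0.83,
            ("intraspecific", "alternative_sourced"): 0.08,
            ("interspecific", "alternative_sourced"): 0.03,
        }
    )
    attachment_failure: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: {
            ("intraspecific", "focal_sourced"): 0.01,
            ("interspecific", "focal_sourced"): 0.24,
            ("intraspecific", "alternative_sourced"): 0.24,
            ("interspecific", "alternative_sourced"): 0.01,
        }
    )
    mortality: float = 0.4
    reproduction_rate: float = 0.0
    replicate_counts: Dict[Tuple[str, str], int] = field(
        default_factory=lambda: {
            ("intraspecific", "focal_sourced"): 20,
            ("interspecific", "focal_sourced"): 21,
            ("intraspecific", "alternative_sourced"): 40,
            ("interspecific", "alternative_sourced"): 49,
        }
    )
    worms_added: int = 10
    duration_hours: float = 18.0

    def __post_init__(self) -> None:
        for d in (self.dispersal, self.attachment_failure):
            for cell, p in d.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"probability for cell {cell} out of [0, 1]: {p}")
        if not 0 <= self.mortality <= 1:
            raise ValueError("mortality must lie in [0, 1]")
        if self.reproduction_rate < 0:
            raise ValueError("reproduction_rate must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and designs for a full synthetic study."""

    seed: int = 0
    foi_truth: FOIParams = FOIParams(beta_FF=0.10, k_FF=1.0, beta_FA=0.01, k_FA=0.5)
    season: SeasonConfig = SeasonConfig()
    sentinel: SentinelDesign = SentinelDesign()
    contact: ContactDesign = ContactDesign()
    dispersal: DispersalTruth = DispersalTruth()

    def truth_dict(self) -> dict:
        """JSON-serialisable record of every generating parameter."""

        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {"|".join(k) if isinstance(k, tuple) else k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        return enc(self)


def gen_field_season(
    config: SimulationConfig, seed: int | None = None
) -> Tuple[List[FieldObservation], List[SentinelTrial]]:
    """Simulate one season of surveys plus the sentinel enclosure trials.

    Per week and site, total snail counts are Poisson around the trajectory
    mean and infested counts Binomial(N, prevalence). Sentinel infestations
    are Binomial(n_exposed, 1 - exp(-FOI t)) with the FOI evaluated at the
    week's site-averaged simulated densities -- the same covariates the fit
    later uses.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    focal_mu, alt_mu, prev = config.season.trajectories()
    n_sites = config.season.n_sites
    fields: List[FieldObservation] = []
    week_cov: Dict[int, Tuple[float, float, float, float]] = {}
    for wk in range(config.season.n_weeks):
        sums = {"focal": [0, 0], "alternative": [0, 0]}
        for site in range(n_sites):
            for species, mu in (("focal", focal_mu[wk]), ("alternative", alt_mu[wk])):
                n = int(rng.poisson(mu))
                i = int(rng.binomial(n, prev[wk])) if n > 0 else 0
                sums[species][0] += n
                sums[species][1] += i
                fields.append(
                    FieldObservation(
                        week_index=wk,
                        site_id=f"site{site}",
                        species=species,
                        density=float(n),
                        infested_density=float(i),
                    )
                )
        week_cov[wk] = (
            sums["focal"][0] / n_sites,
            sums["focal"][1] / n_sites,
            sums["alternative"][0] / n_sites,
            sums["alternative"][1] / n_sites,
        )
    trials: List[SentinelTrial] = []
    for idx, wk in enumerate(config.sentinel.weeks):
        if wk not in week_cov:
            raise ValueError(f"sentinel trial week {wk} lies outside the simulated season")
        n_f, i_f, n_a, i_a = week_cov[wk]
        foi = foi_multi_host(config.foi_truth, n_f, i_f, n_a, i_a)
        p = prob_infested(foi, config.sentinel.duration_days)
        n_infested = int(rng.binomial(config.sentinel.n_exposed, p))
        trials.append(
            SentinelTrial(
                trial_id=f"trial{idx}",
                week_index=wk,
                n_exposed=config.sentinel.n_exposed,
                n_infested=n_infested,
                duration_days=config.sentinel.duration_days,
            )
        )
    return fields, trials


def gen_contact_experiment(design: ContactDesign, seed: int = 0) -> List[ContactTrial]:
    """Simulate container-mean contact counts around the Holling curve.

    Observations are normal about the functional response, truncated at zero
    (a container mean cannot be negative).
    """
    rng = np.random.default_rng(seed)
    truth = design.truth
    trials: List[ContactTrial] = []
    containers_per_day = 8
    idx = 0
    for rep in range(design.replicates):
        for n in design.densities:
            mu = holling_mean_contacts(truth, n, design.obs_minutes)
            if truth.sigma < 1e-12:
                obs = mu
            else:
                a = -mu / truth.sigma  # truncate the normal at zero contacts
                obs = float(
                    stats.truncnorm.rvs(a, np.inf, loc=mu, scale=truth.sigma, random_state=rng)
                )
            trials.append(
                ContactTrial(
                    container_id=f"tank{idx}",
                    trial_day=idx // containers_per_day,
                    alt_density=int(n),
                    n_focal=design.n_focal,
                    mean_contacts=obs,
                    obs_minutes=design.obs_minutes,
                )
            )
            idx += 1
    return trials


def gen_transmission_experiment(
    truth: DispersalTruth, seed: int = 0
) -> List[TransmissionReplicate]:
    """Simulate the four-cell donor/receiver experiment worm by worm.

    Worm fate per added worm: donor cup (attachment failure), missing
    (mortality), receiver snail (dispersal) or donor snail. Reproduction, if
    enabled, adds Poisson(rate) clonal worms per snail-attached worm to the
    same snail.
    """
    rng = np.random.default_rng(seed)
    reps: List[TransmissionReplicate] = []
    idx = 0
    for treatment, source in _CELLS:
        cell = (treatment, source)
        n_reps = truth.replicate_counts.get(cell, 0)
        if n_reps == 0:
            continue
        p_disp = truth.dispersal[cell]
        p_fail = truth.attachment_failure.get(cell, 0.0)
        for _ in range(n_reps):
            on_donor = on_receiver = donor_cup = 0
            for _w in range(truth.worms_added):
                if rng.random() < p_fail:
                    donor_cup += 1
                elif rng.random() < truth.mortality:
                    continue  # died and degraded: missing
                elif rng.random() < p_disp:
                    on_receiver += 1
                else:
                    on_donor += 1
            if truth.reproduction_rate > 0:
                on_donor += int(rng.poisson(truth.reproduction_rate * on_donor))
                on_receiver += int(rng.poisson(truth.reproduction_rate * on_receiver))
            reps.append(
                TransmissionReplicate(
                    replicate_id=f"rep{idx}",
                    treatment=treatment,
                    source=source,
                    worms_added=truth.worms_added,
                    on_donor=on_donor,
                    on_receiver=on_receiver,
                    in_donor_cup=donor_cup,
                    in_experimental_cup=0,
                    in_receiver_cup=0,
                    duration_hours=truth.duration_hours,
                )
            )
            idx += 1
    return reps


def simulate_all(config: SimulationConfig) -> dict:
    """Generate all four datasets from one config (seeds derived per stage)."""
    fields, trials = gen_field_season(config, seed=config.seed)
    contacts = gen_contact_experiment(config.contact, seed=config.seed + 1)
    transmission = gen_transmission_experiment(config.dispersal, seed=config.seed + 2)
    return {
        "field_survey": fields,
        "sentinel_trials": trials,
        "contact_trials": contacts,
        "transmission": transmission,
        "truth": config.truth_dict(),
    }
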