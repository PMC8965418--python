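"""Domain records for field surveys, sentinel trials, contact trials and
transmission-success replicates.

Densities are expressed package-wide in snails per 0.1 m^2 (the unit of the
field quadrat surveys); :func:`per_m2` / :func:`per_01m2` convert. Each record
validates its own invariants on construction so that malformed rows are caught
at the I/O boundary rather than deep inside a likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "FieldObservation",
    "SentinelTrial",
    "ContactTrial",
    "TransmissionReplicate",
    "IntervalEstimate",
    "SPECIES",
    "TREATMENTS",
    "SOURCES",
    "per_m2",
    "per_01m2",
]

SPECIES = ("focal", "alternative")
TREATMENTS = ("intraspecific", "interspecific")
SOURCES = ("focal_sourced", "alternative_sourced")


def per_m2(density_01m2: float) -> float:
    """Convert snails per 0.1 m^2 to snails per m^2."""
    return density_01m2 * 10.0


def per_01m2(density_m2: float) -> float:
    """Convert snails per m^2 to the package-wide snails per 0.1 m^2."""
    return density_m2 / 10.0


@dataclass(frozen=True)
class FieldObservation:
    """One week x site x species record from the cross-sectional snail survey.

    ``density`` and ``infested_density`` are the N and I covariates of the
    force-of-infection model, in snails per 0.1 m^2. ``worm_counts`` optionally
    holds per-snail symbiont counts (infestation intensity); it is not used by
    the FOI fit.
    """

    week_index: int
    site_id: str
    species: str
    density: float
    infested_density: float
    worm_counts: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}, got {self.species!r}")
        if self.density < 0:
            raise ValueError(f"density must be >= 0, got {self.density}")
        if not 0 <= self.infested_density <= self.density:
            raise ValueError(
                "infested_density must lie in [0, density], got "
                f"{self.infested_density} with density {self.density}"
            )
        if self.worm_counts is not None and any(c < 0 for c in self.worm_counts):
            raise ValueError("worm_counts entries must be >= 0")


@dataclass(frozen=True)
class SentinelTrial:
    """One field enclosure trial of laboratory-reared, uninfested sentinels."""

    trial_id: str
    week_index: int
    n_exposed: int
    n_infested: int
    duration_days: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_infested <= self.n_exposed:
            raise ValueError(
                f"need 0 <= n_infested <= n_exposed, got {self.n_infested}/{self.n_exposed}"
            )
        if self.duration_days <= 0:
            raise ValueError(f"duration_days must be > 0, got {self.duration_days}")


@dataclass(frozen=True)
class ContactTrial:
    """One container of the laboratory contact-rate experiment.

    ``mean_contacts`` is the mean number of interspecific contacts per focal
    snail over ``obs_minutes`` (snails within a container are not independent,
    so the container mean is the unit of analysis).
    """

    container_id: str
    trial_day: int
    alt_density: int
    n_focal: int
    mean_contacts: float
    obs_minutes: float

    def __post_init__(self) -> None:
        if self.alt_density < 1:
            raise ValueError(f"alt_density must be >= 1, got {self.alt_density}")
        if self.mean_contacts < 0:
            raise ValueError(f"mean_contacts must be >= 0, got {self.mean_contacts}")
        if self.obs_minutes <= 0:
            raise ValueError(f"obs_minutes must be > 0, got {self.obs_minutes}")
        if self.n_focal < 1:
            raise ValueError(f"n_focal must be >= 1, got {self.n_focal}")


@dataclass(frozen=True)
class TransmissionReplicate:
    """One donor-receiver pairing of the transmission-success experiment.

    Worms are counted by final location at dissection: attached to the donor
    or receiver snail, or unattached in one of the three cups (donor cup =
    never added, receiver cup = fell off after dispersal, experimental cup =
    fell off during pairing). ``recovered_total`` may exceed ``worms_added``
    (asexual reproduction) or undershoot it (mortality/degradation).
    """

    replicate_id: str
    treatment: str
    source: str
    worms_added: int
    on_donor: int
    on_receiver: int
    in_donor_cup: int
    in_experimental_cup: int
    in_receiver_cup: int
    duration_hours: float

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")
        for name in (
            "worms_added",
            "on_donor",
            "on_receiver",
            "in_donor_cup",
            "in_experimental_cup",
            "in_receiver_cup",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.duration_hours <= 0:
            raise ValueError(f"duration_hours must be > 0, got {self.duration_hours}")

    @property
    def recovered_total(self) -> int:
        return (
            self.on_donor
            + self.on_receiver
            + self.in_donor_cup
            + self.in_experimental_cup
            + self.in_receiver_cup
        )

    @property
    def attached_total(self) -> int:
        """Worms that had the donor-vs-receiver choice (snail-attached)."""
        return self.on_donor + self.on_receiver

    @property
    def missing(self) -> int:
        return max(0, self.worms_added - self.recovered_total)

    @property
    def excess(self) -> int:
        """Worms beyond those added (asexual reproduction during the trial)."""
        return max(0, self.recovered_total - self.worms_added)


@dataclass(frozen=True)
class IntervalEstimate:
    """A point estimate with an asymmetric interval (exact or posterior)."""

    point: float
    lower: float
    upper: float
    level: float = 0.95
    method: str = "binomial_exact"

    _METHODS = ("binomial_exact", "poisson_exact", "posterior_quantile")

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if not self.lower <= self.point <= self.upper:
            raise ValueError(
                f"need lower <= point <= upper, got ({self.lower}, {self.point}, {self.upper})"
            )
        if self.method not in self._METHODS:
            raise ValueError(f"method must be one of {self._METHODS}, got {self.method!r}")

    @property
    def width(self) -> float:
        return self.upper - self.lower
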