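"""Shared domain types for the urban-gradient variance pipeline.

The analysis concerns two hole-nesting passerines, great tits (*Parus major*)
and blue tits (*Cyanistes caeruleus*), monitored in nest boxes along urban
gradients. Nest boxes are the atoms: they are grouped into *clusters*
(subpopulations) by proximity, and individual trait records (tarsus length,
lay date) hang off boxes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "Species",
    "Trait",
    "Habitat",
    "Sex",
    "FemaleAge",
    "NestBox",
    "TraitObservation",
    "MCMCSettings",
    "RunConfig",
]


class Species(str, enum.Enum):
    GREAT_TIT = "great_tit"
    BLUE_TIT = "blue_tit"


class Trait(str, enum.Enum):
    ADULT_TARSUS = "adult_tarsus"
    NESTLING_TARSUS = "nestling_tarsus"
    LAY_DATE = "lay_date"


class Habitat(str, enum.Enum):
    FOREST = "forest"
    URBAN = "urban"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class FemaleAge(str, enum.Enum):
    YEARLING = "yearling"
    OLDER = "older"
    UNKNOWN = "unknown"


#: Latin binomials for the two study species, keyed by enum.
SPECIES_BINOMIAL = {
    Species.GREAT_TIT: "Parus major",
    Species.BLUE_TIT: "Cyanistes caeruleus",
}

#: Accepted input tokens per species (case-insensitive).
SPECIES_TOKENS = {
    "great_tit": Species.GREAT_TIT,
    "great tit": Species.GREAT_TIT,
    "parus major": Species.GREAT_TIT,
    "parmaj": Species.GREAT_TIT,
    "blue_tit": Species.BLUE_TIT,
    "blue tit": Species.BLUE_TIT,
    "cyanistes caeruleus": Species.BLUE_TIT,
    "cyacae": Species.BLUE_TIT,
}


@dataclass(frozen=True)
class NestBox:
    """One monitoring site (nest box) with owner-assigned habitat label."""

    box_id: str
    system_id: str
    lon: float
    lat: float
    habitat_label: Habitat

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range for box {self.box_id}: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range for box {self.box_id}: {self.lon}")


@dataclass
class TraitObservation:
    """One individual-level trait record (one row per capture/clutch).

    ``value`` is in mm for tarsus traits and day-of-year (1 Jan = 1) for lay
    date. Nestling records must carry a ``brood_id``; ``chick_age`` is days
    since hatching (13-17 for the measurement window used here).
    """

    individual_id: str
    species: Species
    trait: Trait
    value: float
    year: int
    box_id: str
    brood_id: str = ""
    sex: Sex = Sex.UNKNOWN
    female_age: FemaleAge = FemaleAge.UNKNOWN
    chick_age: float = float("nan")
    measurement_method: str = "svensson_alternative"


@dataclass
class MCMCSettings:
    """Sampler run lengths. Defaults give 4000 retained draws
    (4 chains x (10000 - 6000) / 4)."""

    chains: int = 4
    iterations: int = 10_000
    warmup: int = 6_000
    thin: int = 4
    target_accept: float = 0.9
    max_treedepth: int = 10

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def retained(self) -> int:
        return self.chains * ((self.iterations - self.warmup) // self.thin)


@dataclass
class RunConfig:
    """Configuration for one species x trait model run."""

    species: Species = Species.GREAT_TIT
    trait: Trait = Trait.ADULT_TARSUS
    urbanisation_mode: str = "categorical"  # categorical | isa_100 | isa_1000 | isa_both
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    seed: int = 0
    nestling_seed: int = 1
    sim_seed: int = 2
    boxes_path: str = ""
    observations_path: str = ""
    out_dir: str = "artifacts"
    standardise_response: bool = True
    max_link_m: float = 300.0
    min_cluster_size: int = 5
    hull_buffer_m: float = 150.0

    VALID_MODES = ("categorical", "isa_100", "isa_1000", "isa_both")

    def __post_init__(self) -> None:
        if isinstance(self.species, str):
            self.species = Species(self.species)
        if isinstance(self.trait, str):
            self.trait = Trait(self.trait)
        if isinstance(self.mcmc, dict):
            self.mcmc = MCMCSettings(**self.mcmc)
        if self.urbanisation_mode not in self.VALID_MODES:
            raise ValueError(
                f"urbanisation_mode must be one of {self.VALID_MODES}, "
                f"got {self.urbanisation_mode!r}"
            )
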