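"""Trait-record preprocessing: conversion, outlier windows, first-clutch
selection, deduplication to one row per analysis unit, and Z-standardisation.

The fixed filter order is: convert -> outlier window -> first-clutch
selection (lay date only) -> dedupe -> standardise. Every step emits a
FilterReport so the chain is auditable (input rows = final rows + removed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .types import Trait, TraitObservation, Species

logger = logging.getLogger("urbanvar")

__all__ = [
    "FilterReport",
    "OUTLIER_WINDOWS",
    "convert_tarsus",
    "filter_outliers",
    "select_first_clutches",
    "dedupe_individuals",
    "standardize",
    "unstandardize",
]


@dataclass
class FilterReport:
    rule: str
    rows_removed: int
    rows_remaining: int


#: Closed retention windows per (trait, species); None key = both species.
#: Tarsus in mm, lay date in day-of-year.
OUTLIER_WINDOWS: dict = {
    (Trait.ADULT_TARSUS, None): (12.70, 25.49),
    (Trait.NESTLING_TARSUS, Species.GREAT_TIT): (10.2, 25.9),
    (Trait.NESTLING_TARSUS, Species.BLUE_TIT): (12.11, 21.0),
    (Trait.LAY_DATE, None): (75.0, 152.0),
}

#: Linear calibrations (slope, intercept) mapping other tarsus measurement
#: methods onto Svensson's Alternative. The native method is the identity;
#: further entries are configuration supplied per data set.
DEFAULT_CALIBRATIONS: dict[str, tuple[float, float]] = {
    "svensson_alternative": (1.0, 0.0),
}


def convert_tarsus(
    value: float,
    method: str,
    calibrations: Mapping[str, tuple[float, float]] | None = None,
) -> float:
    """Map a tarsus measurement onto Svensson's Alternative method scale."""
    cal = dict(DEFAULT_CALIBRATIONS)
    if calibrations:
        cal.update(calibrations)
    if method not in cal:
        raise ValueError(f"no calibration for tarsus measurement method {method!r}")
    a, b = cal[method]
    return a * value + b


def apply_conversions(
    obs: Sequence[TraitObservation],
    calibrations: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[list[TraitObservation], FilterReport]:
    """Convert all tarsus records; records with unknown methods are dropped."""
    out: list[TraitObservation] = []
    removed = 0
    for o in obs:
        if o.trait is Trait.LAY_DATE:
            out.append(o)
            continue
        try:
            v = convert_tarsus(o.value, o.measurement_method, calibrations)
        except ValueError as exc:
            removed += 1
            logger.warning("dropped record %s: %s", o.individual_id, exc)
            continue
        out.append(replace(o, value=v, measurement_method="svensson_alternative"))
    return out, FilterReport("convert_tarsus", removed, len(out))


def filter_outliers(
    obs: Sequence[TraitObservation],
    species: Species,
    trait: Trait,
    windows: Mapping | None = None,
) -> tuple[list[TraitObservation], FilterReport]:
    """Keep only values inside the closed trait-specific retention window."""
    w = dict(OUTLIER_WINDOWS)
    if windows:
        w.update(windows)
    key = (trait, species) if (trait, species) in w else (trait, None)
    if key not in w:
        raise KeyError(f"no outlier window configured for {trait.value}/{species.value}")
    lo, hi = w[key]
    kept = [o for o in obs if lo <= o.value <= hi]
    report = FilterReport(f"outlier_window[{lo},{hi}]", len(obs) - len(kept), len(kept))
    if report.rows_removed:
        logger.info("outlier filter removed %d rows outside [%s, %s]", report.rows_removed, lo, hi)
    return kept, report


def select_first_clutches(
    obs: Sequence[TraitObservation],
    cluster_of_box: Mapping[str, str],
    window_days: int = 30,
) -> tuple[list[TraitObservation], FilterReport]:
    """Keep first clutches: lay dates within 30 days of the earliest lay date
    of the species in that year and cluster, then each female's first clutch
    of the season (earliest date per female per year)."""
    groups: dict[tuple, list[TraitObservation]] = {}
    dropped_unclustered = 0
    for o in obs:
        cl = cluster_of_box.get(o.box_id)
        if cl is None:
            dropped_unclustered += 1
            continue
        groups.setdefault((o.species, o.year, cl), []).append(o)

    kept: list[TraitObservation] = []
    for rows in groups.values():
        first = min(r.value for r in rows)
        in_window = [r for r in rows if r.value <= first + window_days]
        # one clutch per female per season: earliest date wins
        per_female: dict[str, TraitObservation] = {}
        for r in sorted(in_window, key=lambda r: (r.individual_id, r.value)):
            per_female.setdefault(r.individual_id, r)
        kept.extend(per_female.values())
    removed = len(obs) - len(kept)
    return kept, FilterReport(f"first_clutches[min+{window_days}d]", removed, len(kept))


def dedupe_individuals(
    obs: Sequence[TraitObservation], trait: Trait, seed: int = 0
) -> tuple[list[TraitObservation], FilterReport]:
    """Reduce to one row per analysis unit.

    adult tarsus: mean of an individual's repeated measures;
    nestling tarsus: one uniformly random nestling per brood (seeded);
    lay date: each female's first appearance (earliest year, then date).
    """
    out: list[TraitObservation] = []
    if trait is Trait.ADULT_TARSUS:
        by_ind: dict[str, list[TraitObservation]] = {}
        for o in obs:
            by_ind.setdefault(o.individual_id, []).append(o)
        for ind in sorted(by_ind):
            rows = by_ind[ind]
            mean_val = float(np.mean([r.value for r in rows]))
            out.append(replace(rows[0], value=mean_val))
    elif trait is Trait.NESTLING_TARSUS:
        rng = np.random.default_rng(seed)
        by_brood: dict[tuple, list[TraitObservation]] = {}
        for o in obs:
            if not o.brood_id:
                raise ValueError(f"nestling record {o.individual_id} lacks brood_id")
            by_brood.setdefault((o.year, o.box_id, o.brood_id), []).append(o)
        for key in sorted(by_brood):
            rows = sorted(by_brood[key], key=lambda r: r.individual_id)
            out.append(rows[int(rng.integers(len(rows)))])
    elif trait is Trait.LAY_DATE:
        by_female: dict[str, TraitObservation] = {}
        for o in sorted(obs, key=lambda r: (r.individual_id, r.year, r.value)):
            by_female.setdefault(o.individual_id, o)
        out = [by_female[k] for k in sorted(by_female)]
    else:  # pragma: no cover
        raise ValueError(trait)
    return out, FilterReport(f"dedupe[{trait.value}]", len(obs) - len(out), len(out))


def standardize(values, name: str = "variable") -> tuple[np.ndarray, float, float]:
    """Z-transform: returns (z, mean, sd) with the n-1 sample SD.

    The (mean, sd) pair back-transforms model output to original units.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"standardize({name}): need at least 2 values")
    mu = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd <= 0:
        raise ValueError(f"standardize({name}): zero variance")
    return (x - mu) / sd, mu, sd


def unstandardize(z, mean: float, sd: float) -> np.ndarray:
    return np.asarray(z, dtype=float) * sd + mean
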