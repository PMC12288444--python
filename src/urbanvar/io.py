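"""Reading and writing the flat CSV tables the pipeline consumes and emits.

Dialect: comma-separated, UTF-8, mandatory header row, empty string for
missing values. Readers never silently drop rows: every rejected row is
counted and logged, so input rows = accepted + rejected.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import (
    SPECIES_TOKENS,
    FemaleAge,
    Habitat,
    NestBox,
    Sex,
    Species,
    Trait,
    TraitObservation,
)

logger = logging.getLogger("urbanvar")

__all__ = [
    "SchemaError",
    "read_boxes",
    "write_boxes",
    "read_observations",
    "write_observations",
    "write_summary_table",
    "read_summary_table",
    "write_json",
]


class SchemaError(ValueError):
    """An input table is missing required columns."""


BOX_COLUMNS = ["box_id", "system_id", "lon", "lat", "habitat_label"]

OBS_REQUIRED = ["individual_id", "species", "trait", "value", "year", "box_id"]
OBS_OPTIONAL = ["brood_id", "sex", "female_age", "chick_age", "measurement_method"]

#: Columns that must be present (beyond OBS_REQUIRED) for each trait.
TRAIT_REQUIRED = {
    Trait.ADULT_TARSUS: ["sex"],
    Trait.NESTLING_TARSUS: ["brood_id", "chick_age"],
    Trait.LAY_DATE: [],
}


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_species(token: str) -> Species:
    key = str(token).strip().lower()
    if key in SPECIES_TOKENS:
        return SPECIES_TOKENS[key]
    raise ValueError(f"unknown species token: {token!r}")


def read_boxes(path: str | Path) -> list[NestBox]:
    """Read a nest-box table; duplicate box_id within a system is an error."""
    df = pd.read_csv(path, dtype={"box_id": str, "system_id": str})
    _require_columns(df, BOX_COLUMNS, str(path))
    dup = df.duplicated(subset=["system_id", "box_id"])
    if dup.any():
        dups = df.loc[dup, "box_id"].tolist()
        raise ValueError(f"duplicate box_id within system: {dups[:5]}")
    boxes = [
        NestBox(
            box_id=str(r.box_id),
            system_id=str(r.system_id),
            lon=float(r.lon),
            lat=float(r.lat),
            habitat_label=Habitat(str(r.habitat_label).strip().lower()),
        )
        for r in df.itertuples(index=False)
    ]
    logger.info("read %d nest boxes from %s", len(boxes), path)
    return boxes


def write_boxes(boxes: Iterable[NestBox], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "box_id": b.box_id,
                "system_id": b.system_id,
                "lon": b.lon,
                "lat": b.lat,
                "habitat_label": b.habitat_label.value,
            }
            for b in boxes
        ],
        columns=BOX_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_observations(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    trait: Trait | None = None,
) -> list[TraitObservation]:
    """Read individual trait records.

    ``schema`` optionally maps our canonical column names to the file's
    column names (deposited archives differ in their headers). Rows that
    fail type coercion are dropped with a logged count; unknown species or
    trait tokens raise.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        rename = {src: canon for canon, src in schema.items() if src in df.columns}
        df = df.rename(columns=rename)
    _require_columns(df, OBS_REQUIRED, str(path))
    if trait is not None:
        _require_columns(df, TRAIT_REQUIRED[trait], str(path))

    records: list[TraitObservation] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:
            species = _parse_species(d["species"])
            row_trait = Trait(str(d["trait"]).strip().lower())
            value = float(d["value"])
            year = int(float(d["year"]))
            if not math.isfinite(value):
                raise ValueError("non-finite value")
        except (ValueError, KeyError) as exc:
            if isinstance(exc, ValueError) and "unknown species token" in str(exc):
                raise
            n_rejected += 1
            logger.warning("rejected row (%s): %s", exc, dict(list(d.items())[:6]))
            continue
        chick_age = d.get("chick_age", "")
        records.append(
            TraitObservation(
                individual_id=str(d["individual_id"]),
                species=species,
                trait=row_trait,
                value=value,
                year=year,
                box_id=str(d["box_id"]),
                brood_id=str(d.get("brood_id", "") or ""),
                sex=Sex(str(d.get("sex") or "unknown").strip().lower()),
                female_age=FemaleAge(str(d.get("female_age") or "unknown").strip().lower()),
                chick_age=float(chick_age) if str(chick_age).strip() else float("nan"),
                measurement_method=str(d.get("measurement_method") or "svensson_alternative"),
            )
        )
    logger.info(
        "read %d observations from %s (%d rejected)", len(records), path, n_rejected
    )
    return records


def write_observations(obs: Iterable[TraitObservation], path: str | Path) -> None:
    rows = []
    for o in obs:
        rows.append(
            {
                "individual_id": o.individual_id,
                "species": o.species.value,
                "trait": o.trait.value,
                "value": o.value,
                "year": o.year,
                "box_id": o.box_id,
                "brood_id": o.brood_id,
                "sex": o.sex.value,
                "female_age": o.female_age.value,
                "chick_age": "" if math.isnan(o.chick_age) else o.chick_age,
                "measurement_method": o.measurement_method,
            }
        )
    df = pd.DataFrame(rows, columns=OBS_REQUIRED + OBS_OPTIONAL)
    df.to_csv(path, index=False)


SUMMARY_COLUMNS = [
    "term",
    "part",
    "kind",
    "estimate",
    "hpdi95_lo",
    "hpdi95_hi",
    "hpdi50_lo",
    "hpdi50_hi",
    "pd",
    "evidence",
]


def write_summary_table(rows: Sequence, path: str | Path) -> None:
    """Write a model-summary table (one row per term, Table-1 shaped).

    Floats are serialised with repr-level precision so a written file
    round-trips bit-stably.
    """
    if not rows:
        raise ValueError("write_summary_table: rows must be non-empty")
    df = pd.DataFrame([r.as_dict() if hasattr(r, "as_dict") else dict(r) for r in rows])
    df = df[[c for c in SUMMARY_COLUMNS if c in df.columns]]
    df.to_csv(path, index=False, float_format="%.17g")


def read_summary_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
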