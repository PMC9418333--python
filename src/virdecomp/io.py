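"""Tidy per-fly table schemas, validation, CSV round-trip and dose arithmetic.

The pipeline works on three tidy tables, one row per fly:

* **survival table** -- the survival cohort, checked daily until death or the
  study horizon (``death_day``, ``event``).
* **load table** -- destructively homogenised flies with their back-calculated
  colony-forming-unit (CFU) load and censoring flags.
* **dead-fly table** -- flies retrieved dead during the chronic phase and
  scored for infection status only (CFUs grew / did not grow).

Tables are plain :class:`pandas.DataFrame` objects with fixed headers; every
reader validates row-level invariants and reports violations with the row
index and the rule that failed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "SPECIES",
    "TREATMENTS",
    "SURVIVAL_COLUMNS",
    "LOAD_COLUMNS",
    "DEAD_COLUMNS",
    "SchemaError",
    "ValidationError",
    "SurvivalRecord",
    "LoadRecord",
    "DeadFlyRecord",
    "dose_from_concentration",
    "read_survival_table",
    "read_load_table",
    "read_dead_table",
    "write_table",
    "validate_survival",
    "validate_load",
    "validate_dead",
    "load_config",
]

#: Bacterial species used in the study design (plus ``none`` for flies that
#: belong to no species block).
SPECIES = ("E_cloacae", "Pr_burhodogranariea", "L_lactis", "Ps_entomophila", "none")

TREATMENTS = ("bacterial", "ringer", "naive")

PERSONS = ("A", "B")

SURVIVAL_COLUMNS = [
    "fly_id", "species", "treatment", "dose_cfu", "replicate", "person",
    "death_day", "event",
]
LOAD_COLUMNS = [
    "fly_id", "species", "dose_cfu", "replicate", "day_sampled", "load_cfu",
    "below_detection", "at_max_censored", "contaminated",
]
DEAD_COLUMNS = [
    "fly_id", "species", "dose_cfu", "replicate", "person", "day_found",
    "infected_at_death",
]


class SchemaError(ValueError):
    """A table is missing a required column or has a malformed header."""


class ValidationError(ValueError):
    """A row violates a table invariant; carries the row index and rule."""

    def __init__(self, row: int, rule: str):
        self.row = row
        self.rule = rule
        super().__init__(f"row {row}: {rule}")


@dataclass(frozen=True)
class SurvivalRecord:
    """One fly of the survival cohort (checked daily until death/horizon)."""

    fly_id: str
    species: str
    treatment: str
    dose_cfu: int
    replicate: int
    person: str
    death_day: float
    event: int


@dataclass(frozen=True)
class LoadRecord:
    """One homogenised fly with its back-calculated CFU load."""

    fly_id: str
    species: str
    dose_cfu: int
    replicate: int
    day_sampled: int
    load_cfu: float
    below_detection: int
    at_max_censored: int
    contaminated: int


@dataclass(frozen=True)
class DeadFlyRecord:
    """One fly found dead and scored for infection presence/absence."""

    fly_id: str
    species: str
    dose_cfu: int
    replicate: int
    person: str
    day_found: int
    infected_at_death: int


def dose_from_concentration(concentration_cfu_per_ml: float, volume_nl: float) -> float:
    """Injected dose (CFU per fly) from a culture concentration and volume.

    Parameters
    ----------
    concentration_cfu_per_ml
        Bacterial concentration of the injected suspension, CFU/mL.
    volume_nl
        Injected volume in nanolitres (1 mL = 10**6 nL).
    """
    if concentration_cfu_per_ml < 0 or volume_nl < 0:
        raise ValueError("concentration and volume must be nonnegative")
    return concentration_cfu_per_ml * volume_nl / 1e6


def _require_columns(df: pd.DataFrame, columns: Iterable[str]) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")


def _is_flag(x) -> bool:
    try:
        return float(x) in (0.0, 1.0)
    except (TypeError, ValueError):
        return False


def validate_survival(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a survival table in place and return it.

    Rules: known species/treatment/person levels; ``dose_cfu == 0`` exactly for
    non-bacterial treatments; ``death_day > 0``; ``event`` in {0, 1}.
    """
    _require_columns(df, SURVIVAL_COLUMNS)
    for i, row in enumerate(df.itertuples(index=False)):
        if row.species not in SPECIES:
            raise ValidationError(i, f"unknown species {row.species!r}")
        if row.treatment not in TREATMENTS:
            raise ValidationError(i, f"unknown treatment {row.treatment!r}")
        if row.person not in PERSONS:
            raise ValidationError(i, f"unknown person {row.person!r}")
        dose = float(row.dose_cfu)
        if dose < 0 or dose != int(dose):
            raise ValidationError(i, "dose_cfu must be a nonnegative integer")
        if (dose == 0) != (row.treatment != "bacterial"):
            raise ValidationError(
                i, "dose_cfu must be 0 exactly for non-bacterial treatments"
            )
        if int(row.replicate) < 1:
            raise ValidationError(i, "replicate must be >= 1")
        if not float(row.death_day) > 0:
            raise ValidationError(i, "death_day must be > 0")
        if not _is_flag(row.event):
            raise ValidationError(i, "event must be 0 or 1")
    return df


def validate_load(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a load table in place and return it.

    Rules: flags are 0/1; ``below_detection`` implies ``load_cfu == 0``;
    ``below_detection`` and ``at_max_censored`` are mutually exclusive;
    loads nonnegative.
    """
    _require_columns(df, LOAD_COLUMNS)
    for i, row in enumerate(df.itertuples(index=False)):
        if row.species not in SPECIES:
            raise ValidationError(i, f"unknown species {row.species!r}")
        if float(row.dose_cfu) < 0:
            raise ValidationError(i, "dose_cfu must be nonnegative")
        if int(row.day_sampled) < 1:
            raise ValidationError(i, "day_sampled must be >= 1")
        for flag in ("below_detection", "at_max_censored", "contaminated"):
            if not _is_flag(getattr(row, flag)):
                raise ValidationError(i, f"{flag} must be 0 or 1")
        if float(row.load_cfu) < 0:
            raise ValidationError(i, "load_cfu must be nonnegative")
        if int(row.below_detection) and float(row.load_cfu) != 0:
            raise ValidationError(i, "below_detection implies load_cfu == 0")
        if int(row.below_detection) and int(row.at_max_censored):
            raise ValidationError(
                i, "below_detection and at_max_censored are mutually exclusive"
            )
    return df


def validate_dead(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a dead-fly table in place and return it."""
    _require_columns(df, DEAD_COLUMNS)
    for i, row in enumerate(df.itertuples(index=False)):
        if row.species not in SPECIES:
            raise ValidationError(i, f"unknown species {row.species!r}")
        if int(row.day_found) < 1:
            raise ValidationError(i, "day_found must be >= 1")
        if not _is_flag(row.infected_at_death):
            raise ValidationError(i, "infected_at_death must be 0 or 1")
    return df


_SURVIVAL_DTYPES = {
    "fly_id": str, "species": str, "treatment": str, "dose_cfu": "int64",
    "replicate": "int64", "person": str, "death_day": "float64", "event": "int64",
}
_LOAD_DTYPES = {
    "fly_id": str, "species": str, "dose_cfu": "int64", "replicate": "int64",
    "day_sampled": "int64", "load_cfu": "float64", "below_detection": "int64",
    "at_max_censored": "int64", "contaminated": "int64",
}
_DEAD_DTYPES = {
    "fly_id": str, "species": str, "dose_cfu": "int64", "replicate": "int64",
    "person": str, "day_found": "int64", "infected_at_death": "int64",
}


def _read(path, columns, dtypes, validator) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, columns)
    df = df[columns].astype(dtypes)
    return validator(df)


def read_survival_table(path) -> pd.DataFrame:
    """Read and validate a survival table (one row per survival-cohort fly)."""
    return _read(path, SURVIVAL_COLUMNS, _SURVIVAL_DTYPES, validate_survival)


def read_load_table(path) -> pd.DataFrame:
    """Read and validate a load table (one row per homogenised fly)."""
    return _read(path, LOAD_COLUMNS, _LOAD_DTYPES, validate_load)


def read_dead_table(path) -> pd.DataFrame:
    """Read and validate a dead-fly infection-status table."""
    return _read(path, DEAD_COLUMNS, _DEAD_DTYPES, validate_dead)


def write_table(df: pd.DataFrame, path) -> None:
    """Write any of the tidy tables as comma-separated UTF-8 with header."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a TOML configuration file (e.g. a ``[simulate]`` block)."""
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)
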