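"""Studbook data model and delimited-table input/output.

A studbook is the complete demographic registry of a managed (zoo)
population: one row per individual with sex, birth/death dates, parentage
links and provenance flags.  This module defines the in-memory record
types, the CSV reader/writer (UTF-8, ISO-8601 dates) and the YAML species
configuration, plus the regional population filter.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

__all__ = [
    "Sex",
    "Status",
    "IndividualRecord",
    "SpeciesConfig",
    "Studbook",
    "StudbookFormatError",
    "read_studbook",
    "write_studbook",
    "read_species_config",
    "write_species_config",
    "filter_population",
]

# Sexes and statuses are plain strings; the canonical vocabularies are
# exposed as frozensets so callers can validate without importing enums.
FEMALE = "female"
MALE = "male"
UNKNOWN = "unknown"
Sex = frozenset({FEMALE, MALE, UNKNOWN})

DEAD = "dead"
ALIVE = "alive"
LOST = "lost"
Status = frozenset({DEAD, ALIVE, LOST})

REGIONS = frozenset({"Europe", "NorthAmerica", "other"})

_COLUMNS = [
    "individual_id",
    "sex",
    "birth_date",
    "birth_estimated",
    "death_date",
    "status",
    "dam_id",
    "sire_id",
    "dam_probability",
    "sire_probability",
    "wild_born",
    "region",
]


class StudbookFormatError(ValueError):
    """Raised when a studbook table violates the format contract."""


@dataclass
class IndividualRecord:
    """One animal's life history and parentage links.

    ``dam_probability`` / ``sire_probability`` are the recorded certainty
    of the parentage link in percent (0-100); curation only trusts links
    at 100.  ``status`` is ``lost`` for animals lost to follow-up: they
    keep their record but have no death date.
    """

    individual_id: str
    sex: str = UNKNOWN
    birth_date: Optional[datetime.date] = None
    birth_estimated: bool = False
    death_date: Optional[datetime.date] = None
    status: str = ALIVE
    dam_id: Optional[str] = None
    sire_id: Optional[str] = None
    dam_probability: float = 100.0
    sire_probability: float = 100.0
    wild_born: bool = False
    region: str = "other"

    def __post_init__(self) -> None:
        if self.sex not in Sex:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.status not in Status:
            raise ValueError(f"unknown status {self.status!r}")
        if (
            self.birth_date is not None
            and self.death_date is not None
            and self.death_date < self.birth_date
        ):
            raise ValueError(
                f"{self.individual_id}: death date {self.death_date} precedes "
                f"birth date {self.birth_date}"
            )

    def age_years_at(self, when: datetime.date) -> float:
        """Age in fractional years at a given date (365.25-day year)."""
        if self.birth_date is None:
            raise ValueError(f"{self.individual_id} has no birth date")
        return (when - self.birth_date).days / 365.25

    def is_alive_on(self, when: datetime.date) -> bool:
        """Alive on a date under the half-open convention birth <= d < death."""
        if self.birth_date is None or self.birth_date > when:
            return False
        return self.death_date is None or self.death_date > when


@dataclass
class SpeciesConfig:
    """Per-species biological parameters and algorithm thresholds.

    Parameters
    ----------
    gestation_days:
        Average gestation length in days; the interbirth plausibility
        threshold is ``interbirth_fraction`` times this (plus pouch
        eviction for marsupials).
    max_litter_size:
        Largest biologically plausible litter; recorded litters above it
        are treated as duplications and halved.
    afr_override, senescence_override:
        Manual life-stage thresholds (whole years, per sex) that take
        precedence over data-driven estimates, mirroring the option to
        use literature values.
    min_population_for_shape:
        A sex-year pyramid is only classified when its total is strictly
        greater than this (default 10).
    min_individuals_ever:
        Regional populations with fewer individuals ever recorded are
        flagged ineligible (default 150).
    """

    species_name: str = "unnamed"
    gestation_days: float = 120.0
    is_marsupial: bool = False
    pouch_eviction_min_days: Optional[float] = None
    max_litter_size: int = 4
    afr_override: dict[str, int] = field(default_factory=dict)
    senescence_override: dict[str, int] = field(default_factory=dict)
    max_longevity_override: Optional[int] = None
    min_population_for_shape: int = 10
    min_individuals_ever: int = 150
    litter_window_days: int = 3
    interbirth_fraction: float = 0.90
    sem_factor: float = 0.5
    gamma_tail_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.gestation_days <= 0:
            raise ValueError("gestation_days must be positive")
        if self.max_litter_size < 1:
            raise ValueError("max_litter_size must be a positive integer")
        if self.is_marsupial and self.pouch_eviction_min_days is None:
            raise ValueError(
                "marsupial species require pouch_eviction_min_days"
            )
        for name in ("min_population_for_shape", "min_individuals_ever",
                     "litter_window_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("interbirth_fraction", "sem_factor",
                     "gamma_tail_fraction"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")

    @property
    def effective_gestation_days(self) -> float:
        """Gestation, plus minimum pouch-eviction age for marsupials."""
        if self.is_marsupial:
            return self.gestation_days + float(self.pouch_eviction_min_days)
        return self.gestation_days


@dataclass
class Studbook:
    """A collection of individual records plus the species parameters."""

    records: list[IndividualRecord]
    species: SpeciesConfig = field(default_factory=SpeciesConfig)
    region_filtered: bool = False
    eligible: bool = True

    def __post_init__(self) -> None:
        ids = [r.individual_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1} if len(ids) != len(set(ids)) else set()
        if dupes:
            raise StudbookFormatError(
                f"duplicate individual_id values: {sorted(dupes)}"
            )
        self._index = {r.individual_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, individual_id: Optional[str]) -> Optional[IndividualRecord]:
        if individual_id is None:
            return None
        return self._index.get(individual_id)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._index

    def copy(self) -> "Studbook":
        return Studbook(
            records=[dataclasses.replace(r) for r in self.records],
            species=self.species,
            region_filtered=self.region_filtered,
            eligible=self.eligible,
        )

    def remove(self, individual_ids: Iterable[str]) -> None:
        doomed = set(individual_ids)
        self.records = [r for r in self.records if r.individual_id not in doomed]
        self._index = {r.individual_id: r for r in self.records}


def _parse_date(value) -> Optional[datetime.date]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if not text:
        return None
    return datetime.date.fromisoformat(text)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    return text in {"true", "1", "yes", "y"}


def read_studbook(path, config: Optional[SpeciesConfig] = None) -> Studbook:
    """Read a CSV studbook table into a :class:`Studbook`.

    The file must carry a header naming the record fields; dates are
    ISO-8601; empty cells mean "absent".  Missing mandatory columns and
    duplicate identifiers are hard errors naming the offenders.
    """
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in table.columns]
    if missing:
        raise StudbookFormatError(
            f"studbook {path} is missing mandatory column(s): {', '.join(missing)}"
        )
    counts = table["individual_id"].value_counts()
    dupes = sorted(counts[counts > 1].index)
    if dupes:
        raise StudbookFormatError(
            f"studbook {path} has duplicate individual_id values: {dupes}"
        )
    records = []
    for row in table.itertuples(index=False):
        sex = row.sex.strip().lower() or UNKNOWN
        records.append(
            IndividualRecord(
                individual_id=row.individual_id,
                sex=sex if sex in Sex else UNKNOWN,
                birth_date=_parse_date(row.birth_date),
                birth_estimated=_parse_bool(row.birth_estimated),
                death_date=_parse_date(row.death_date),
                status=row.status.strip().lower() or ALIVE,
                dam_id=row.dam_id.strip() or None,
                sire_id=row.sire_id.strip() or None,
                dam_probability=float(row.dam_probability or 100.0),
                sire_probability=float(row.sire_probability or 100.0),
                wild_born=_parse_bool(row.wild_born),
                region=row.region.strip() or "other",
            )
        )
    return Studbook(records=records, species=config or SpeciesConfig())


def write_studbook(studbook: Studbook, path) -> None:
    """Write a studbook as CSV; ``read_studbook`` round-trips it exactly."""
    rows = []
    for r in studbook.records:
        rows.append({
            "individual_id": r.individual_id,
            "sex": r.sex,
            "birth_date": r.birth_date.isoformat() if r.birth_date else "",
            "birth_estimated": str(r.birth_estimated).lower(),
            "death_date": r.death_date.isoformat() if r.death_date else "",
            "status": r.status,
            "dam_id": r.dam_id or "",
            "sire_id": r.sire_id or "",
            "dam_probability": r.dam_probability,
            "sire_probability": r.sire_probability,
            "wild_born": str(r.wild_born).lower(),
            "region": r.region,
        })
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_species_config(path) -> SpeciesConfig:
    """Load a species configuration from YAML."""
    with open(path, "r", encoding="utf-8") as handle:
        data = yaml.safe_load(handle) or {}
    return SpeciesConfig(**data)


def write_species_config(config: SpeciesConfig, path) -> None:
    data = dataclasses.asdict(config)
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(data, handle, sort_keys=False)


def filter_population(
    studbook: Studbook,
    region: str,
    min_ever: Optional[int] = None,
) -> Studbook:
    """Restrict a studbook to one holding region.

    The result keeps only the region's records; when fewer than
    ``min_ever`` individuals were ever recorded there, the returned
    studbook is flagged ineligible for shape analysis (records are kept
    so curation and inspection remain possible).
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {sorted(REGIONS)}")
    if min_ever is None:
        min_ever = studbook.species.min_individuals_ever
    if min_ever < 1:
        raise ValueError("min_ever must be >= 1")
    kept = [dataclasses.replace(r) for r in studbook.records if r.region == region]
    return Studbook(
        records=kept,
        species=studbook.species,
        region_filtered=True,
        eligible=len(kept) >= min_ever,
    )
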