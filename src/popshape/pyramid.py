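"""Yearly sex-specific age pyramids and their five-bucket reduction.

Individuals alive on December 31st of a year are counted per floored
integer age class; the resulting pyramid is normalised into five buckets
(juvenile, three adult blocks, senior), each summarised by the mean
number of individuals per age class.  Two buckets count as equal when
their means +/- ``sem_factor`` (default 0.5) times their standard errors
overlap; the four bottom-up comparisons form the step sequence that the
shape classifier consumes.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .life_stages import LifeStageThresholds
from .studbook_io import SpeciesConfig, Studbook

__all__ = [
    "AgePyramid",
    "Bucket",
    "BucketVector",
    "LT",
    "EQ",
    "GT",
    "build_pyramid",
    "reduce_to_buckets",
    "compare_buckets",
    "step_sequence",
]

LT, EQ, GT = -1, 0, 1

BUCKET_NAMES = ("juvenile", "adult_low", "adult_mid", "adult_high", "senior")


@dataclass
class AgePyramid:
    """Counts per integer age class for one population, sex and year."""

    population_id: str
    sex: str
    year: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("pyramid counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class Bucket:
    """Mean individuals per age class within one block of the pyramid."""

    mean: float
    sem: float
    n_classes: int
    total: int


@dataclass(frozen=True)
class BucketVector:
    """The five-bucket reduction of one pyramid, bottom (juvenile) up."""

    buckets: tuple[Bucket, Bucket, Bucket, Bucket, Bucket]
    total: int
    ascribable: bool

    def reversed(self) -> "BucketVector":
        return BucketVector(
            buckets=tuple(reversed(self.buckets)),
            total=self.total,
            ascribable=self.ascribable,
        )


def age_class_on_dec31(birth_date: datetime.date, year: int) -> int:
    """Floored age in whole years on December 31st of ``year``.

    On December 31st every individual has passed its birthday for the
    year, so the floored age equals the difference of calendar years: an
    individual aged 363 days is in age class 0, one aged 365 or 366 days
    is in age class 1.
    """
    return year - birth_date.year


def build_pyramid(
    studbook: Studbook,
    year: int,
    sex: str,
    thresholds: LifeStageThresholds,
    population_id: str = "population",
) -> AgePyramid:
    """Count individuals of one sex alive on December 31st per age class.

    Alive means born on or before December 31st with no death date or a
    death date strictly after it (a death on the 31st counts as dead).
    Ages above the curated maximum longevity — possible for live records
    that escaped curation — are clamped into the top class.
    """
    dec31 = datetime.date(year, 12, 31)
    n_classes = thresholds.max_longevity + 1
    counts = np.zeros(n_classes, dtype=int)
    for rec in studbook.records:
        if rec.sex != sex or rec.birth_date is None:
            continue
        if not rec.is_alive_on(dec31):
            continue
        age = age_class_on_dec31(rec.birth_date, year)
        counts[min(age, n_classes - 1)] += 1
    return AgePyramid(population_id=population_id, sex=sex, year=year,
                      counts=counts)


def _make_bucket(counts: np.ndarray) -> Bucket:
    n = counts.size
    total = int(counts.sum())
    mean = total / n
    # sample (n-1) standard deviation; a single-class bucket has SEM 0,
    # so its comparisons reduce to pure mean comparisons
    sem = float(np.std(counts, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return Bucket(mean=mean, sem=sem, n_classes=n, total=total)


def reduce_to_buckets(
    pyramid: AgePyramid,
    thresholds: LifeStageThresholds,
    config: Optional[SpeciesConfig] = None,
) -> BucketVector:
    """Reduce a pyramid to its five-bucket summary vector.

    Each bucket carries the mean count per age class in its range, the
    standard error of that mean, and the class count.  The vector is
    flagged not ascribable when the sex-specific population total is at
    or below ``min_population_for_shape`` (default 10).
    """
    config = config or SpeciesConfig()
    buckets = tuple(
        _make_bucket(pyramid.counts[lo:hi]) for lo, hi in thresholds.bucket_ranges
    )
    total = pyramid.total
    return BucketVector(
        buckets=buckets,
        total=total,
        ascribable=total > config.min_population_for_shape,
    )


def compare_buckets(a: Bucket, b: Bucket, sem_factor: float = 0.5) -> int:
    """Order two buckets under the SEM-overlap equality test.

    Returns ``EQ`` (0) when the intervals mean +/- sem_factor * SEM
    overlap, otherwise ``LT`` (-1) or ``GT`` (+1) by mean ordering
    (a relative to b).
    """
    if sem_factor <= 0:
        raise ValueError("sem_factor must be positive")
    a_lo, a_hi = a.mean - sem_factor * a.sem, a.mean + sem_factor * a.sem
    b_lo, b_hi = b.mean - sem_factor * b.sem, b.mean + sem_factor * b.sem
    if a_lo <= b_hi and b_lo <= a_hi:
        return EQ
    return LT if a.mean < b.mean else GT


def step_sequence(v: BucketVector, sem_factor: float = 0.5) -> tuple[int, int, int, int]:
    """Four bottom-up steps, each +1 / 0 / -1.

    Step n compares bucket n+1 against bucket n: +1 when the upper
    bucket is larger ('becoming larger'), 0 when the two are equal under
    the SEM-overlap test, -1 when it is smaller.
    """
    return tuple(
        compare_buckets(v.buckets[i + 1], v.buckets[i], sem_factor)
        for i in range(4)
    )


def pyramid_to_frame(pyramid: AgePyramid) -> pd.DataFrame:
    """Long-format export: one row per (year, sex, age_class)."""
    return pd.DataFrame({
        "population": pyramid.population_id,
        "year": pyramid.year,
        "sex": pyramid.sex,
        "age_class": np.arange(pyramid.counts.size),
        "count": pyramid.counts,
    })


def buckets_to_frame(v: BucketVector, year: int, sex: str) -> pd.DataFrame:
    """Export of one bucket vector: one row per bucket."""
    return pd.DataFrame({
        "year": year,
        "sex": sex,
        "bucket": BUCKET_NAMES,
        "mean": [b.mean for b in v.buckets],
        "sem": [b.sem for b in v.buckets],
        "n_classes": [b.n_classes for b in v.buckets],
        "total": [b.total for b in v.buckets],
    })
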