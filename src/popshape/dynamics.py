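"""Shape-sequence demographic statistics.

Once every sex-year pyramid of a population carries a shape label, the
time series itself becomes the object of study: how often one shape
follows another, how the population size changes across each transition,
the typical age-group composition of each shape, and which shape a
population shows at its historical peak size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .life_stages import LifeStageThresholds
from .pyramid import build_pyramid, reduce_to_buckets
from .shapes import NOT_ASCRIBED, SHAPES, classify
from .studbook_io import FEMALE, MALE, SpeciesConfig, Studbook

__all__ = [
    "SeriesEntry",
    "ShapeSeries",
    "TransitionStats",
    "build_series",
    "transitions",
    "aggregate_transitions",
    "age_group_proportions",
    "peak_analysis",
]


@dataclass(frozen=True)
class SeriesEntry:
    """One sex-year observation: shape plus group counts."""

    year: int
    shape: str
    total: int
    juveniles: int
    adults: int
    seniors: int


@dataclass
class ShapeSeries:
    """Yearly (shape, size) sequence for one population and sex."""

    population_id: str
    sex: str
    entries: list[SeriesEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        years = [e.year for e in self.entries]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("series years must be strictly increasing")

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "population": self.population_id,
                    "sex": self.sex,
                    "year": e.year,
                    "shape": e.shape,
                    "total": e.total,
                    "juveniles": e.juveniles,
                    "adults": e.adults,
                    "seniors": e.seniors,
                }
                for e in self.entries
            ],
            columns=["population", "sex", "year", "shape", "total",
                     "juveniles", "adults", "seniors"],
        )


def build_series(
    studbook: Studbook,
    thresholds: LifeStageThresholds,
    config: Optional[SpeciesConfig] = None,
    years: Optional[Iterable[int]] = None,
    population_id: str = "population",
    sexes: tuple[str, ...] = (FEMALE, MALE),
) -> dict[str, ShapeSeries]:
    """Classify every requested sex-year and assemble the series.

    Years default to the span from the earliest birth year to the last
    recorded event in the studbook.  Years with no individuals are kept
    in the grid as ``not_ascribed`` entries with total zero.
    """
    config = config or studbook.species
    if years is None:
        dates = [r.birth_date for r in studbook.records if r.birth_date]
        dates += [r.death_date for r in studbook.records if r.death_date]
        if not dates:
            raise ValueError("studbook holds no dated records; pass years")
        years = range(min(dates).year, max(dates).year + 1)
    years = list(years)

    out: dict[str, ShapeSeries] = {}
    for sex in sexes:
        entries = []
        for year in years:
            pyr = build_pyramid(studbook, year, sex, thresholds,
                                population_id=population_id)
            vec = reduce_to_buckets(pyr, thresholds, config)
            shape = classify(vec, config)
            groups = {"juvenile": 0, "adult": 0, "senior": 0}
            for age, count in enumerate(pyr.counts):
                groups[thresholds.age_group(age)] += int(count)
            entries.append(SeriesEntry(
                year=year,
                shape=shape,
                total=pyr.total,
                juveniles=groups["juvenile"],
                adults=groups["adult"],
                seniors=groups["senior"],
            ))
        out[sex] = ShapeSeries(population_id=population_id, sex=sex,
                               entries=entries)
    return out


def transitions(series: ShapeSeries) -> list[tuple[str, str, float]]:
    """Consecutive-year shape transitions with % population change.

    Only pairs of consecutive years where both shapes are ascribed count;
    a not-ascribed year breaks the chain rather than bridging it.  The
    change is 100 * (N_next - N_prev) / N_prev on the sex-specific total.
    """
    out = []
    for a, b in zip(series.entries, series.entries[1:]):
        if b.year != a.year + 1:
            continue
        if a.shape == NOT_ASCRIBED or b.shape == NOT_ASCRIBED:
            continue
        change = 100.0 * (b.total - a.total) / a.total
        out.append((a.shape, b.shape, change))
    return out


@dataclass
class TransitionStats:
    """Aggregated shape-to-shape transition statistics.

    ``counts`` / ``percentages`` / ``mean_change`` / ``sd_change`` are
    11x11 frames indexed (from shape, to shape); the SD is only defined
    for cells with at least two transitions.  Display thresholds are a
    rendering concern — every cell is stored.
    """

    counts: pd.DataFrame
    percentages: pd.DataFrame
    mean_change: pd.DataFrame
    sd_change: pd.DataFrame
    n_total: int


def aggregate_transitions(
    all_transitions: Iterable[tuple[str, str, float]],
) -> TransitionStats:
    """Counts, percentages of total, and per-cell change statistics."""
    idx = pd.Index(SHAPES, name="from_shape")
    cols = pd.Index(SHAPES, name="to_shape")
    counts = pd.DataFrame(0, index=idx, columns=cols, dtype=int)
    sums = pd.DataFrame(0.0, index=idx, columns=cols)
    sumsq = pd.DataFrame(0.0, index=idx, columns=cols)
    n = 0
    for src, dst, change in all_transitions:
        counts.loc[src, dst] += 1
        sums.loc[src, dst] += change
        sumsq.loc[src, dst] += change * change
        n += 1
    if n:
        percentages = 100.0 * counts / n
    else:
        percentages = counts.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts.where(counts > 0)
        var = (sumsq - counts * mean**2) / (counts - 1).where(counts > 1)
        sd = np.sqrt(var.clip(lower=0))
    return TransitionStats(
        counts=counts,
        percentages=percentages,
        mean_change=mean,
        sd_change=sd,
        n_total=n,
    )


def age_group_proportions(
    series_collection: Iterable[ShapeSeries],
) -> pd.DataFrame:
    """Mean age-group percentages per shape over all ascribed entries.

    Each ascribed entry with a positive total contributes its juvenile /
    adult / senior percentages (summing to 100); the result is the mean
    per shape with the entry count.
    """
    rows = []
    for series in series_collection:
        for e in series.entries:
            if e.shape == NOT_ASCRIBED or e.total <= 0:
                continue
            rows.append({
                "shape": e.shape,
                "juvenile_pct": 100.0 * e.juveniles / e.total,
                "adult_pct": 100.0 * e.adults / e.total,
                "senior_pct": 100.0 * e.seniors / e.total,
            })
    if not rows:
        return pd.DataFrame(
            columns=["juvenile_pct", "adult_pct", "senior_pct", "n"]
        )
    frame = pd.DataFrame(rows)
    out = frame.groupby("shape").mean()
    out["n"] = frame.groupby("shape").size()
    return out


def peak_analysis(
    series_collection: Iterable[ShapeSeries],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shape at peak size and mean relative size per shape.

    For every population-sex series the maximum total (earliest year on
    ties) names the peak shape; every ascribed occurrence of a shape
    contributes its size as a percentage of that series' maximum.
    Series with no ascribed entry are excluded.
    """
    peak_rows = []
    occ_rows = []
    for series in series_collection:
        ascribed = [e for e in series.entries if e.shape != NOT_ASCRIBED]
        if not ascribed:
            continue
        n_max = max(e.total for e in ascribed)
        peak_entry = next(e for e in ascribed if e.total == n_max)
        peak_rows.append({
            "population": series.population_id,
            "sex": series.sex,
            "peak_year": peak_entry.year,
            "peak_total": n_max,
            "peak_shape": peak_entry.shape,
        })
        for e in ascribed:
            occ_rows.append({
                "shape": e.shape,
                "pct_of_max": 100.0 * e.total / n_max,
            })
    peaks = pd.DataFrame(
        peak_rows,
        columns=["population", "sex", "peak_year", "peak_total", "peak_shape"],
    )
    if occ_rows:
        occ_frame = pd.DataFrame(occ_rows)
        by_shape = occ_frame.groupby("shape").agg(
            occurrences=("pct_of_max", "size"),
            mean_pct_of_max=("pct_of_max", "mean"),
        )
    else:
        by_shape = pd.DataFrame(columns=["occurrences", "mean_pct_of_max"])
    return by_shape, peaks
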