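"""Data-driven life-stage thresholds and the five-bucket age partition.

A sex-specific pyramid needs two age thresholds: the age of first
reproduction (AFR, start of the adult stage) and the onset of
reproductive senescence (start of the senior stage).  AFR is read
directly off the curated parentage links as the youngest recorded parent
age.  The senescence onset is estimated by a heuristic robust to single
outliers: the proportion of proven breeders reproducing in each age
class is computed, a gamma density with free amplitude is fitted to that
sequence by least squares, and the onset is the age class at which the
fitted curve has fallen to a configurable fraction (default 75 %) of its
peak on the right tail.

Both thresholds can be overridden manually (e.g. with literature
values) through :class:`~popshape.studbook_io.SpeciesConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .studbook_io import DEAD, FEMALE, MALE, SpeciesConfig, Studbook

__all__ = [
    "ReproductionProfile",
    "GammaFit",
    "LifeStageThresholds",
    "estimate_afr",
    "reproduction_profile",
    "fit_gamma",
    "senescence_onset",
    "bucket_boundaries",
]


@dataclass
class ReproductionProfile:
    """Per-age-class reproduction probabilities of proven breeders.

    ``probabilities[i]`` is the fraction of proven breeders (individuals
    with at least one offspring in their lifetime) that were alive during
    age class ``ages[i]`` and produced at least one offspring in it.
    """

    sex: str
    ages: np.ndarray
    probabilities: np.ndarray
    n_breeders: int

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.ages.size != self.probabilities.size:
            raise ValueError("ages and probabilities differ in length")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GammaFit:
    """Least-squares gamma fit A * pdf(x; k, scale=theta) to a profile."""

    shape: float
    scale: float
    amplitude: float
    rss: float

    @property
    def mode(self) -> float:
        return (self.shape - 1.0) * self.scale if self.shape > 1 else 0.0

    def density(self, x) -> np.ndarray:
        return self.amplitude * stats.gamma.pdf(x, self.shape, scale=self.scale)


@dataclass
class LifeStageThresholds:
    """Whole-year life-stage boundaries and the five bucket ranges.

    The five half-open ranges partition the age classes 0..max_longevity:
    juvenile [0, afr), three adult blocks covering [afr, onset) as evenly
    as possible (remainder years to the lower blocks), and senior
    [onset, max_longevity].
    """

    afr: int
    senescence_onset: int
    max_longevity: int
    bucket_ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not 0 <= self.afr < self.senescence_onset <= self.max_longevity:
            raise ValueError("need 0 <= afr < onset <= max_longevity")
        if self.senescence_onset - self.afr < 3:
            raise ValueError(
                "adult range must span at least three years "
                f"(afr={self.afr}, onset={self.senescence_onset})"
            )
        if len(self.bucket_ranges) != 5:
            raise ValueError("exactly five bucket ranges required")
        cursor = 0
        for lo, hi in self.bucket_ranges:
            if lo != cursor or hi <= lo:
                raise ValueError("bucket ranges must tile [0, max_longevity]")
            cursor = hi
        if cursor != self.max_longevity + 1:
            raise ValueError("bucket ranges must end at max_longevity + 1")

    def age_group(self, age_class: int) -> str:
        """juvenile / adult / senior membership of one age class."""
        if age_class < self.afr:
            return "juvenile"
        if age_class < self.senescence_onset:
            return "adult"
        return "senior"


def _offspring_births_by_parent(studbook: Studbook) -> dict[str, list]:
    births: dict[str, list] = {}
    for rec in studbook.records:
        if rec.birth_date is None:
            continue
        for parent_id in (rec.dam_id, rec.sire_id):
            if parent_id is not None:
                births.setdefault(parent_id, []).append(rec.birth_date)
    return births


def estimate_afr(studbook: Studbook, sex: str) -> int:
    """Age of first reproduction: floored youngest recorded parent age.

    A configured override for the sex wins over the data; with neither
    parentage links nor an override the estimate is undefined.
    """
    override = studbook.species.afr_override.get(sex)
    if override is not None:
        return int(override)
    births = _offspring_births_by_parent(studbook)
    youngest: Optional[float] = None
    for parent_id, dates in births.items():
        parent = studbook.get(parent_id)
        if parent is None or parent.sex != sex or parent.birth_date is None:
            continue
        age = (min(dates) - parent.birth_date).days / 365.25
        if youngest is None or age < youngest:
            youngest = age
    if youngest is None:
        raise ValueError(
            f"no curated parentage links for sex {sex!r}; "
            "configure afr_override"
        )
    return int(math.floor(youngest))


def reproduction_profile(studbook: Studbook, sex: str) -> ReproductionProfile:
    """Proportion of proven breeders reproducing in each age class.

    The denominator of each age class counts only the proven breeders
    alive during that class, so late-life reproductive decline is not
    conflated with mortality.  Living (censored) breeders count as alive
    up to their age at the last event date recorded in the studbook.
    """
    births = _offspring_births_by_parent(studbook)
    event_dates = [r.birth_date for r in studbook.records if r.birth_date] + [
        r.death_date for r in studbook.records if r.death_date
    ]
    census = max(event_dates) if event_dates else None

    breeders = []
    for parent_id, dates in births.items():
        parent = studbook.get(parent_id)
        if parent is None or parent.sex != sex or parent.birth_date is None:
            continue
        if parent.death_date is not None:
            last_age = math.floor(
                (parent.death_date - parent.birth_date).days / 365.25
            )
        else:
            last_age = math.floor((census - parent.birth_date).days / 365.25)
        repro_ages = {
            math.floor((d - parent.birth_date).days / 365.25) for d in dates
        }
        breeders.append((last_age, repro_ages))
    if not breeders:
        raise ValueError(f"no proven breeders of sex {sex!r}")

    max_age = max(last for last, _ in breeders)
    ages = np.arange(max_age + 1)
    numer = np.zeros(max_age + 1)
    denom = np.zeros(max_age + 1)
    for last_age, repro_ages in breeders:
        denom[: last_age + 1] += 1
        for a in repro_ages:
            if a <= max_age:
                numer[a] += 1
    mask = denom > 0
    return ReproductionProfile(
        sex=sex,
        ages=ages[mask],
        probabilities=numer[mask] / denom[mask],
        n_breeders=len(breeders),
    )


# Deterministic multi-start grid for the gamma fit: shape 0.5..16 by 0.5,
# scale 0.25..8 by 0.25.  The amplitude is profiled out in closed form.
_K_GRID = np.arange(0.5, 16.0 + 1e-9, 0.5)
_THETA_GRID = np.arange(0.25, 8.0 + 1e-9, 0.25)


def _profiled_amplitude(g: np.ndarray, p: np.ndarray) -> float:
    gg = float(g @ g)
    if gg <= 0 or not np.isfinite(gg):
        return 0.0
    return max(float(g @ p) / gg, 0.0)


def fit_gamma(profile: ReproductionProfile) -> GammaFit:
    """Fit A * gammaPDF(a + 0.5; k, theta) to the age-class probabilities.

    Least squares over the observed age classes, evaluated at class
    midpoints.  A coarse deterministic grid over (k, theta) with the
    amplitude profiled out in closed form seeds a local refinement, so
    the result is reproducible run to run.
    """
    x = profile.ages.astype(float) + 0.5
    p = profile.probabilities
    if np.count_nonzero(p > 0) < 4:
        raise ValueError(
            "fewer than four age classes with positive reproduction "
            "probability; set thresholds manually"
        )

    best = None
    for k in _K_GRID:
        for theta in _THETA_GRID:
            g = stats.gamma.pdf(x, k, scale=theta)
            a = _profiled_amplitude(g, p)
            rss = float(np.sum((p - a * g) ** 2))
            if best is None or rss < best[0]:
                best = (rss, k, theta, a)
    _, k0, theta0, a0 = best

    def residuals(params):
        log_k, log_theta, log_a = params
        return (
            np.exp(log_a)
            * stats.gamma.pdf(x, np.exp(log_k), scale=np.exp(log_theta))
            - p
        )

    a0 = max(a0, 1e-12)
    sol = optimize.least_squares(
        residuals,
        x0=np.log([k0, theta0, a0]),
        method="lm",
        xtol=1e-12,
        ftol=1e-12,
    )
    k, theta, a = np.exp(sol.x)
    rss = float(np.sum(sol.fun**2))
    # keep the grid solution when refinement runs away (near-flat
    # profiles push the scale to infinity without meaningful gain)
    sane = k <= 10 * _K_GRID[-1] and theta <= 10 * _THETA_GRID[-1]
    if sane and rss <= best[0] + 1e-12:
        return GammaFit(shape=float(k), scale=float(theta),
                        amplitude=float(a), rss=rss)
    return GammaFit(shape=float(k0), scale=float(theta0),
                    amplitude=float(a0), rss=float(best[0]))


def senescence_onset(
    fit: GammaFit,
    config: Optional[SpeciesConfig] = None,
    sex: Optional[str] = None,
) -> int:
    """Age class where the fitted curve drops to the tail fraction.

    The onset is the right-tail crossing of ``gamma_tail_fraction``
    (default 0.75) times the peak density, found by root bracketing past
    the mode and rounded up to the next whole age class: an individual
    counts as senior only once past the threshold.  A configured
    override for the sex wins.
    """
    config = config or SpeciesConfig()
    if sex is not None:
        override = config.senescence_override.get(sex)
        if override is not None:
            return int(override)
    frac = config.gamma_tail_fraction
    if not 0 < frac <= 1:
        raise ValueError("gamma_tail_fraction must lie in (0, 1]")
    mode = fit.mode
    peak = stats.gamma.pdf(max(mode, 1e-12), fit.shape, scale=fit.scale)
    if peak <= 0 or not np.isfinite(peak):
        raise ValueError("degenerate gamma fit")
    if frac >= 1.0:
        return int(math.ceil(mode))
    target = frac * peak

    def f(x):
        return stats.gamma.pdf(x, fit.shape, scale=fit.scale) - target

    lo = max(mode, 1e-12)
    hi = lo + fit.scale
    while f(hi) > 0:
        hi += fit.scale
        if hi > lo + 1e6 * fit.scale:
            raise RuntimeError("failed to bracket the right-tail crossing")
    root = optimize.brentq(f, lo, hi, xtol=1e-10)
    return int(math.ceil(root - 1e-9))


def bucket_boundaries(afr: int, onset: int, max_longevity: int) -> LifeStageThresholds:
    """Partition age classes into juvenile / 3 adult blocks / senior.

    The adult span [afr, onset) is split into three contiguous blocks of
    near-equal width; when not divisible by three the extra years go to
    the lower blocks.  The method requires an adult span of at least
    three years, otherwise the blocks are not well defined.
    """
    span = onset - afr
    if span < 3:
        raise ValueError(
            f"adult range spans {span} years; the five-bucket reduction "
            "requires an adult range of at least three years"
        )
    if max_longevity < onset:
        raise ValueError("max_longevity must be >= senescence onset")
    base, rem = divmod(span, 3)
    widths = [base + (1 if i < rem else 0) for i in range(3)]
    edges = [afr]
    for w in widths:
        edges.append(edges[-1] + w)
    ranges = (
        (0, afr),
        (edges[0], edges[1]),
        (edges[1], edges[2]),
        (edges[2], edges[3]),
        (onset, max_longevity + 1),
    )
    return LifeStageThresholds(
        afr=afr,
        senescence_onset=onset,
        max_longevity=max_longevity,
        bucket_ranges=ranges,
    )
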