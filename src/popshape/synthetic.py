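"""Seeded individual-based studbook simulator.

Generates studbooks with known age-specific fertility and mortality
schedules, known litter structure and fully certain parentage, so every
downstream procedure can be checked against ground truth.  Scenario
events (halting or scaling reproduction and mortality in given years)
emulate management interventions; a separate error injector corrupts
records in the exact ways registry data goes wrong — same-sex parents,
self-parentage, swapped dam/sire fields, implausibly short interbirth
intervals, duplicated (oversized) litters, never-closed "immortal"
records and underage parents — returning the truth list of corrupted
records so curation recall is measurable.

The default species is a generic mid-sized mammal: age of first
reproduction 3 y, gamma-shaped reproduction over age (shape 4, scale
2 y, peaking near age 6), onset of reproductive senescence in age class
10, maximum age 20 y, gestation 150 d, litters of 1-3.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .studbook_io import (
    ALIVE,
    DEAD,
    FEMALE,
    MALE,
    IndividualRecord,
    SpeciesConfig,
    Studbook,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "gamma_fertility",
    "default_survival",
    "simulate_studbook",
    "inject_errors",
    "scenario_library",
    "ERROR_TYPES",
]

HALT_REPRODUCTION = "halt_reproduction"
RESUME_REPRODUCTION = "resume_reproduction"
MORTALITY_MULTIPLIER = "mortality_multiplier"
FERTILITY_MULTIPLIER = "fertility_multiplier"

ERROR_TYPES = (
    "same_sex_parents",
    "self_parent",
    "swapped_dam_sire",
    "short_interbirth",
    "oversized_litter",
    "immortal_record",
    "underage_parent",
)

_MAX_AGE = 20
_AFR = 3
_GAMMA_K = 4.0
_GAMMA_THETA = 2.0
# Peak annual litter probability chosen so the default schedules give a
# near-stationary population (Leslie-matrix growth rate ~1.00).
_PEAK_RATE = 0.50


def gamma_fertility(
    peak_rate: float = _PEAK_RATE,
    k: float = _GAMMA_K,
    theta: float = _GAMMA_THETA,
    afr: int = _AFR,
    max_age: int = _MAX_AGE,
) -> np.ndarray:
    """Annual litter probability per age: gamma-shaped, zero below AFR.

    The curve is the gamma density at class midpoints rescaled so its
    maximum equals ``peak_rate``.
    """
    ages = np.arange(max_age + 1, dtype=float)
    mode = (k - 1.0) * theta if k > 1 else 1e-9
    curve = stats.gamma.pdf(ages + 0.5, k, scale=theta)
    curve = peak_rate * curve / stats.gamma.pdf(mode, k, scale=theta)
    curve[ages < afr] = 0.0
    return curve


def default_survival(max_age: int = _MAX_AGE) -> np.ndarray:
    """Annual survival per age: juvenile mortality, plateau, senescence."""
    surv = np.zeros(max_age + 1)
    surv[0] = 0.70
    surv[1] = 0.85
    surv[2] = 0.92
    surv[3:11] = 0.92
    for a in range(11, max_age):
        surv[a] = max(0.92 - 0.08 * (a - 10), 0.05)
    surv[max_age] = 0.0
    return surv


def analytic_senescence_onset(
    k: float = _GAMMA_K,
    theta: float = _GAMMA_THETA,
    tail_fraction: float = 0.75,
) -> int:
    """Right-tail crossing of the true gamma curve, ceiled to a class."""
    mode = (k - 1.0) * theta if k > 1 else 1e-9
    target = tail_fraction * stats.gamma.pdf(mode, k, scale=theta)
    hi = mode + theta
    while stats.gamma.pdf(hi, k, scale=theta) > target:
        hi += theta
    root = optimize.brentq(
        lambda x: stats.gamma.pdf(x, k, scale=theta) - target, mode, hi
    )
    return int(math.ceil(root - 1e-9))


@dataclass
class SimulationConfig:
    """Parameters of one simulated studbook."""

    seed: int = 0
    years: int = 60
    start_year: int = 1960
    initial_per_sex: int = 200
    fertility: np.ndarray = field(default_factory=gamma_fertility)
    survival: np.ndarray = field(default_factory=default_survival)
    birth_sex_ratio_female: float = 0.5
    litter_size_probs: tuple[float, ...] = (0.70, 0.25, 0.05)
    gestation_days: float = 150.0
    events: tuple[tuple[int, str, float], ...] = ()
    error_rates: dict[str, float] = field(default_factory=dict)
    region: str = "Europe"

    def __post_init__(self) -> None:
        self.fertility = np.asarray(self.fertility, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.fertility.shape != self.survival.shape:
            raise ValueError("fertility and survival must share an age range")
        if np.any(self.fertility < 0):
            raise ValueError("fertility must be non-negative")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise ValueError("survival must lie in [0, 1]")
        total = sum(self.litter_size_probs)
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            self.litter_size_probs = tuple(
                p / total for p in self.litter_size_probs
            )

    @property
    def max_age(self) -> int:
        return self.survival.size - 1

    def species_config(self, **overrides) -> SpeciesConfig:
        """Matching species parameters for the downstream pipeline."""
        defaults = dict(
            species_name="synthetic",
            gestation_days=self.gestation_days,
            max_litter_size=len(self.litter_size_probs),
        )
        defaults.update(overrides)
        return SpeciesConfig(**defaults)


@dataclass
class GroundTruth:
    """The generating schedules and implied life-stage thresholds."""

    fertility: np.ndarray
    survival: np.ndarray
    afr: int
    senescence_onset: Optional[int]
    max_age: int
    extinct_year: Optional[int] = None


def _random_day(rng: np.random.Generator, year: int) -> datetime.date:
    return datetime.date(year, 1, 1) + datetime.timedelta(
        days=int(rng.integers(0, 365))
    )


def simulate_studbook(
    config: SimulationConfig,
) -> tuple[Studbook, GroundTruth]:
    """Run the yearly birth-death simulation.

    Each year every living female produces a litter with probability
    ``fertility(age)`` (scaled by active scenario multipliers), litter
    sizes follow the configured distribution, sires are drawn uniformly
    among living reproductive-age males, and every individual then
    survives to the next year with probability ``survival(age)``.
    Litters are dated mid-year with a small seeded day jitter shared by
    litter mates; deaths get a date within their year.  All parentage is
    recorded as fully certain.  Identical seeds give identical output;
    extinction before the horizon is a valid outcome, noted in the
    ground truth.
    """
    rng = np.random.default_rng(config.seed)
    fert = config.fertility
    surv = config.survival
    max_age = config.max_age
    litter_sizes = np.arange(1, len(config.litter_size_probs) + 1)
    repro_ages = np.nonzero(fert > 0)[0]
    afr_true = int(repro_ages[0]) if repro_ages.size else max_age

    records: list[IndividualRecord] = []
    living: list[IndividualRecord] = []
    counter = 0

    def new_individual(sex, birth_date, dam_id=None, sire_id=None,
                       wild_born=False) -> IndividualRecord:
        nonlocal counter
        counter += 1
        rec = IndividualRecord(
            individual_id=f"S{counter:06d}",
            sex=sex,
            birth_date=birth_date,
            status=ALIVE,
            dam_id=dam_id,
            sire_id=sire_id,
            wild_born=wild_born,
            region=config.region,
        )
        records.append(rec)
        return rec

    # founders: ages from the survivorship-implied stable distribution
    lx = np.cumprod(np.concatenate([[1.0], surv[:-1]]))
    age_probs = lx / lx.sum()
    for sex in (FEMALE, MALE):
        founder_ages = rng.choice(
            np.arange(max_age + 1), size=config.initial_per_sex, p=age_probs
        )
        for age in founder_ages:
            birth = _random_day(rng, config.start_year - 1 - int(age))
            living.append(new_individual(sex, birth, wild_born=True))

    fert_mult = 1.0
    mort_mult = 1.0
    halted = False
    extinct_year = None

    events = sorted(config.events)
    for year in range(config.start_year, config.start_year + config.years):
        for ev_year, name, value in events:
            if ev_year == year:
                if name == HALT_REPRODUCTION:
                    halted = True
                elif name == RESUME_REPRODUCTION:
                    halted = False
                elif name == FERTILITY_MULTIPLIER:
                    fert_mult = float(value)
                elif name == MORTALITY_MULTIPLIER:
                    mort_mult = float(value)
                else:
                    raise ValueError(f"unknown scenario event {name!r}")

        males = [m for m in living
                 if m.sex == MALE and fert[min(year - m.birth_date.year, max_age)] > 0]
        if males:
            # sires follow the same age-fertility curve as dams, so male
            # reproduction also declines with age
            male_w = np.array(
                [fert[min(year - m.birth_date.year, max_age)] for m in males]
            )
            male_w = male_w / male_w.sum()
        births: list[IndividualRecord] = []
        if not halted and males:
            for female in living:
                if female.sex != FEMALE:
                    continue
                age = min(year - female.birth_date.year, max_age)
                p = min(fert[age] * fert_mult, 1.0)
                if p <= 0 or rng.random() >= p:
                    continue
                size = int(rng.choice(litter_sizes, p=config.litter_size_probs))
                sire = males[int(rng.choice(len(males), p=male_w))]
                # mid-year litter date; jitter within the litter window,
                # shared by litter mates
                date = datetime.date(year, 7, 1) + datetime.timedelta(
                    days=int(rng.integers(-3, 4))
                )
                for _ in range(size):
                    sex = FEMALE if rng.random() < config.birth_sex_ratio_female else MALE
                    births.append(new_individual(
                        sex, date,
                        dam_id=female.individual_id,
                        sire_id=sire.individual_id,
                    ))
        living.extend(births)

        survivors = []
        for rec in living:
            age = min(year - rec.birth_date.year, max_age)
            death_prob = min((1.0 - surv[age]) * mort_mult, 1.0)
            if rng.random() < death_prob:
                rec.status = DEAD
                start = max(datetime.date(year, 1, 1), rec.birth_date)
                span = (datetime.date(year, 12, 31) - start).days
                rec.death_date = start + datetime.timedelta(
                    days=int(rng.integers(0, span + 1)) if span > 0 else 0
                )
            else:
                survivors.append(rec)
        living = survivors
        if not living and extinct_year is None:
            extinct_year = year
            break

    truth = GroundTruth(
        fertility=fert.copy(),
        survival=surv.copy(),
        afr=afr_true,
        senescence_onset=analytic_senescence_onset(),
        max_age=max_age,
        extinct_year=extinct_year,
    )
    studbook = Studbook(records=records, species=config.species_config())
    return studbook, truth


def _eligible_offspring(studbook: Studbook) -> list[IndividualRecord]:
    return [
        r for r in studbook.records
        if r.dam_id is not None and r.sire_id is not None
        and studbook.get(r.dam_id) is not None
        and studbook.get(r.sire_id) is not None
        and r.birth_date is not None
    ]


def inject_errors(
    studbook: Studbook,
    config: Optional[SimulationConfig] = None,
    seed: int = 0,
    counts: Optional[dict[str, int]] = None,
) -> tuple[Studbook, dict[str, list]]:
    """Corrupt a clean studbook in known ways; return the truth lists.

    ``counts`` (or, as a fraction of eligible records, the rates in
    ``config.error_rates``) fixes how many records each error type hits.
    Targets of the parent-link error types are mutually disjoint so that
    every curation repair maps to exactly one injected error.  The truth
    entry formats are: offspring ids for link errors, member-id lists
    per litter for short interbirth, ``(dam_id, date, added_ids)`` for
    oversized litters, individual ids for immortal records.
    """
    rng = np.random.default_rng(seed)
    out = studbook.copy()
    species = out.species
    truth: dict[str, list] = {t: [] for t in ERROR_TYPES}

    rates = dict(config.error_rates) if config is not None else {}
    counts = dict(counts or {})

    def n_for(error_type: str, n_candidates: int) -> int:
        if error_type in counts:
            return min(counts[error_type], n_candidates)
        rate = rates.get(error_type, 0.0)
        return min(int(round(rate * n_candidates)), n_candidates)

    pool = _eligible_offspring(out)
    rng.shuffle(pool)
    pool = list(pool)

    def take(n: int) -> list[IndividualRecord]:
        taken, rest = pool[:n], pool[n:]
        pool[:] = rest
        return taken

    males = sorted(
        (r.individual_id for r in out.records if r.sex == MALE)
    )

    # same-sex parents: point the dam field at a male
    for rec in take(n_for("same_sex_parents", len(pool))):
        wrong = males[int(rng.integers(len(males)))]
        while wrong in (rec.sire_id, rec.individual_id):
            wrong = males[int(rng.integers(len(males)))]
        rec.dam_id = wrong
        truth["same_sex_parents"].append(rec.individual_id)

    # self-parentage
    for rec in take(n_for("self_parent", len(pool))):
        rec.sire_id = rec.individual_id
        truth["self_parent"].append(rec.individual_id)

    # dam and sire fields exchanged
    for rec in take(n_for("swapped_dam_sire", len(pool))):
        rec.dam_id, rec.sire_id = rec.sire_id, rec.dam_id
        truth["swapped_dam_sire"].append(rec.individual_id)

    # short interbirth: move a dam's second litter too close to her first
    by_dam: dict[str, dict] = {}
    for rec in out.records:
        if rec.dam_id is not None and rec.birth_date is not None:
            by_dam.setdefault(rec.dam_id, {}).setdefault(
                rec.birth_date, []
            ).append(rec.individual_id)
    gap = max(species.litter_window_days + 2,
              int(0.3 * species.effective_gestation_days))
    eligible_dams = []
    protected = set(truth["same_sex_parents"]) | set(
        truth["self_parent"]) | set(truth["swapped_dam_sire"])
    for dam_id in sorted(by_dam):
        litters = sorted(by_dam[dam_id].items())
        if len(litters) < 2:
            continue
        members = litters[1][1]
        if any(m in protected for m in members):
            continue
        if (litters[1][0] - litters[0][0]).days <= gap:
            continue
        eligible_dams.append((dam_id, litters[0][0], members))
    rng.shuffle(eligible_dams)
    for dam_id, first_date, members in eligible_dams[
        : n_for("short_interbirth", len(eligible_dams))
    ]:
        new_date = first_date + datetime.timedelta(days=gap)
        for iid in members:
            out.get(iid).birth_date = new_date
        truth["short_interbirth"].append(sorted(members))
        protected.update(members)

    # oversized litters: duplicate members beyond the species maximum
    target_size = 2 * species.max_litter_size
    candidates = []
    for dam_id in sorted(by_dam):
        for date, members in sorted(by_dam[dam_id].items()):
            if any(m in protected for m in members):
                continue
            if len(members) <= species.max_litter_size:
                candidates.append((dam_id, date, members))
    rng.shuffle(candidates)
    extra = 0
    for dam_id, date, members in candidates[
        : n_for("oversized_litter", len(candidates))
    ]:
        template = out.get(members[0])
        added = []
        for _ in range(target_size - len(members)):
            extra += 1
            dup = dataclasses.replace(
                template,
                individual_id=f"DUP{extra:05d}",
                sex=FEMALE if rng.random() < 0.5 else MALE,
            )
            out.records.append(dup)
            added.append(dup.individual_id)
        truth["oversized_litter"].append((dam_id, date, added))
    out.__post_init__()  # rebuild the id index after appends

    # immortal records: dead animals never marked dead
    dead = [r for r in out.records
            if r.status == DEAD and r.individual_id not in protected]
    rng.shuffle(dead)
    for rec in dead[: n_for("immortal_record", len(dead))]:
        rec.status = ALIVE
        rec.death_date = None
        truth["immortal_record"].append(rec.individual_id)

    # underage parent: re-link the sire to an implausibly young male
    remaining = [r for r in pool if r.individual_id not in protected]
    young_by_birth = sorted(
        (r for r in out.records if r.sex == MALE and r.birth_date),
        key=lambda r: r.birth_date,
    )
    n_under = n_for("underage_parent", len(remaining))
    for rec in remaining[:n_under]:
        young = [
            m for m in young_by_birth
            if 0 < (rec.birth_date - m.birth_date).days < 365
            and m.individual_id != rec.individual_id
        ]
        if not young:
            continue
        rec.sire_id = young[0].individual_id
        truth["underage_parent"].append(rec.individual_id)

    return out, truth


def scenario_library() -> dict[str, SimulationConfig]:
    """Named presets covering the qualitative regimes of interest.

    ``steady_state``: near-stationary growth, the pyramid regime.
    ``reproduction_halt``: breeding stops in year 40 of 60; the last
    juvenile cohort climbs through lower, middle and upper diamond.
    ``halt_then_resume``: an eight-year breeding gap then resumption,
    producing hourglass years.
    ``low_mortality_reduced_reproduction``: a long-lived, slow-breeding
    regime yielding bell / column / plunger profiles.
    ``high_resilience`` / ``low_resilience``: broad-based versus
    narrow-based populations (reduced fertility and mortality).
    """
    long_surv = np.full(_MAX_AGE + 1, 0.97)
    long_surv[_MAX_AGE] = 0.0
    return {
        "steady_state": SimulationConfig(),
        "reproduction_halt": SimulationConfig(
            initial_per_sex=2000,
            events=((2000, HALT_REPRODUCTION, 0.0),),
        ),
        "halt_then_resume": SimulationConfig(
            initial_per_sex=2000,
            events=(
                (1995, HALT_REPRODUCTION, 0.0),
                (2003, RESUME_REPRODUCTION, 0.0),
            ),
        ),
        "low_mortality_reduced_reproduction": SimulationConfig(
            survival=long_surv,
            fertility=gamma_fertility(peak_rate=0.25),
        ),
        "high_resilience": SimulationConfig(
            fertility=gamma_fertility(peak_rate=0.60),
        ),
        "low_resilience": SimulationConfig(
            survival=long_surv,
            fertility=gamma_fertility(peak_rate=0.30),
        ),
    }
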