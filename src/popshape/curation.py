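"""Studbook curation: parentage plausibility, longevity, litters, interbirth.

Registry data entered by many institutions over decades accumulates
characteristic errors: uncertain or impossible parentage (same-sex
parents, self-parentage, dam/sire fields swapped), implausibly short
interbirth intervals, oversized litters recorded through duplication, and
"immortal" animals never marked dead.  Each procedure here repairs one
class of error by a fixed deterministic rule and logs every mutation in
an audit report, so that curated output is fully traceable to the raw
records.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .studbook_io import (
    DEAD,
    FEMALE,
    MALE,
    IndividualRecord,
    SpeciesConfig,
    Studbook,
)

__all__ = [
    "CurationEntry",
    "CurationReport",
    "curate_parentage",
    "compute_max_longevity",
    "curate_litters",
    "curate_interbirth",
    "run_curation",
]

PARENT_LINK_REMOVED = "parent_link_removed"
PARENTS_SWAPPED = "parents_swapped"
DATES_MERGED = "dates_merged"
INDIVIDUALS_REMOVED = "individuals_removed"
RECORD_HOLDER_SET = "record_holder_set"


@dataclass
class CurationEntry:
    """One audited mutation of the studbook."""

    rule: str
    individual_ids: list[str]
    action: str
    detail: str = ""


@dataclass
class CurationReport:
    """Ordered list of mutations applied during curation."""

    entries: list[CurationEntry] = field(default_factory=list)

    def add(self, rule: str, ids, action: str, detail: str = "") -> None:
        self.entries.append(CurationEntry(rule, list(ids), action, detail))

    def extend(self, other: "CurationReport") -> None:
        self.entries.extend(other.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rule": e.rule,
                    "individual_id": ";".join(e.individual_ids),
                    "action": e.action,
                    "detail": e.detail,
                }
                for e in self.entries
            ],
            columns=["rule", "individual_id", "action", "detail"],
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _parent_age_years(parent: IndividualRecord, offspring: IndividualRecord) -> Optional[float]:
    if parent.birth_date is None or offspring.birth_date is None:
        return None
    return (offspring.birth_date - parent.birth_date).days / 365.25


def curate_parentage(
    studbook: Studbook,
    afr_by_sex: Optional[dict[str, float]] = None,
) -> tuple[Studbook, CurationReport]:
    """Repair implausible parentage links.

    In order: (a) links with recorded probability below 100 % are
    dropped; (b) self-parentage links are dropped; (c) a male recorded as
    dam together with a female recorded as sire is treated as a swapped
    pair and exchanged; (d) when both recorded parents share a sex, the
    wrongly-sexed parent's link is dropped (a male dam, a female sire);
    (e) when ``afr_by_sex`` is given, links whose parent was younger than
    the age of first reproduction for its sex at the offspring's birth
    are dropped.  Link removal never deletes individuals; parents not
    resolvable within the studbook are treated as external and exempt
    from the sex- and age-based rules.
    """
    out = studbook.copy()
    report = CurationReport()

    for rec in out.records:
        # (a) only fully certain parentage is trusted
        if rec.dam_id is not None and rec.dam_probability < 100:
            report.add(
                "parentage_probability", [rec.individual_id], PARENT_LINK_REMOVED,
                f"dam {rec.dam_id} probability {rec.dam_probability:g} < 100",
            )
            rec.dam_id = None
        if rec.sire_id is not None and rec.sire_probability < 100:
            report.add(
                "parentage_probability", [rec.individual_id], PARENT_LINK_REMOVED,
                f"sire {rec.sire_id} probability {rec.sire_probability:g} < 100",
            )
            rec.sire_id = None

        # (b) no individual is its own parent
        if rec.dam_id == rec.individual_id:
            report.add("self_parentage", [rec.individual_id],
                       PARENT_LINK_REMOVED, "individual recorded as its own dam")
            rec.dam_id = None
        if rec.sire_id == rec.individual_id:
            report.add("self_parentage", [rec.individual_id],
                       PARENT_LINK_REMOVED, "individual recorded as its own sire")
            rec.sire_id = None

        dam = out.get(rec.dam_id)
        sire = out.get(rec.sire_id)

        # (c) male dam together with female sire: the two fields were swapped
        if dam is not None and sire is not None and dam.sex == MALE and sire.sex == FEMALE:
            rec.dam_id, rec.sire_id = rec.sire_id, rec.dam_id
            report.add(
                "swapped_dam_sire", [rec.individual_id], PARENTS_SWAPPED,
                f"dam {sire.individual_id} and sire {dam.individual_id} exchanged",
            )
            dam, sire = sire, dam

        # (d) two parents of the same sex: the wrongly-sexed one is wrong
        if dam is not None and sire is not None and dam.sex == sire.sex:
            if dam.sex == MALE:
                report.add("same_sex_parents", [rec.individual_id],
                           PARENT_LINK_REMOVED,
                           f"dam {rec.dam_id} is male; dam link removed")
                rec.dam_id = None
            elif dam.sex == FEMALE:
                report.add("same_sex_parents", [rec.individual_id],
                           PARENT_LINK_REMOVED,
                           f"sire {rec.sire_id} is female; sire link removed")
                rec.sire_id = None

        # (e) parents below the age of first reproduction are implausible
        if afr_by_sex is not None:
            for attr, parent in (("dam_id", out.get(rec.dam_id)),
                                 ("sire_id", out.get(rec.sire_id))):
                if parent is None:
                    continue
                threshold = afr_by_sex.get(parent.sex)
                if threshold is None:
                    continue
                age = _parent_age_years(parent, rec)
                if age is not None and age < threshold:
                    report.add(
                        "underage_parent", [rec.individual_id],
                        PARENT_LINK_REMOVED,
                        f"{attr[:-3]} {parent.individual_id} aged {age:.2f} y "
                        f"< AFR {threshold:g} y",
                    )
                    setattr(rec, attr, None)

    return out, report


def compute_max_longevity(studbook: Studbook) -> int:
    """Maximum observed longevity in whole years.

    The record holder is the oldest zoo-born, dead individual: wild-born
    ages are estimates, and living animals at the top of the age range
    are often records never closed.  A configured manual override (e.g. a
    literature value) wins over the data.
    """
    override = studbook.species.max_longevity_override
    if override is not None:
        return int(override)
    ages = [
        (rec.death_date - rec.birth_date).days / 365.25
        for rec in studbook.records
        if not rec.wild_born
        and rec.status == DEAD
        and rec.birth_date is not None
        and rec.death_date is not None
    ]
    if not ages:
        raise ValueError(
            "no zoo-born dead individual found; supply "
            "max_longevity_override in the species configuration"
        )
    return int(math.floor(max(ages)))


def _litter_groups(dates_ids: list[tuple], window_days: int) -> list[list[tuple]]:
    """Single-linkage chaining of same-dam births with gaps <= window."""
    groups: list[list[tuple]] = []
    for item in sorted(dates_ids):
        if groups and (item[0] - groups[-1][-1][0]).days <= window_days:
            groups[-1].append(item)
        else:
            groups.append([item])
    return groups


def _median_date(dates):
    """Middle date; for even-sized litters the earlier central date."""
    ordered = sorted(dates)
    return ordered[(len(ordered) - 1) // 2]


def curate_litters(
    studbook: Studbook,
    config: Optional[SpeciesConfig] = None,
    seed: int = 0,
) -> tuple[Studbook, CurationReport]:
    """Group same-dam births into litters and repair oversized ones.

    Births of the same dam within the litter window (default 3 days,
    accommodating delayed detection in nesting species) form one litter
    and are re-dated to the litter's middle date.  Litters larger than
    the species maximum are treated as duplications and cut in half:
    ``floor(size/2)`` members are deleted uniformly at random under the
    seed.
    """
    config = config or studbook.species
    out = studbook.copy()
    report = CurationReport()
    rng = np.random.default_rng(seed)

    by_dam: dict[str, list[tuple]] = {}
    for rec in out.records:
        if rec.dam_id is not None and rec.birth_date is not None:
            by_dam.setdefault(rec.dam_id, []).append(
                (rec.birth_date, rec.individual_id)
            )

    doomed: list[str] = []
    for dam_id in sorted(by_dam):
        for litter in _litter_groups(by_dam[dam_id], config.litter_window_days):
            ids = [iid for _, iid in litter]
            target = _median_date([d for d, _ in litter])
            moved = [iid for d, iid in litter if d != target]
            if moved:
                for iid in moved:
                    out.get(iid).birth_date = target
                report.add(
                    "litter_grouping", ids, DATES_MERGED,
                    f"dam {dam_id}: litter of {len(ids)} re-dated to {target}",
                )
            if len(ids) > config.max_litter_size:
                n_remove = len(ids) // 2
                removed = sorted(
                    rng.choice(sorted(ids), size=n_remove, replace=False)
                )
                doomed.extend(removed)
                report.add(
                    "oversized_litter", removed, INDIVIDUALS_REMOVED,
                    f"dam {dam_id}: litter of {len(ids)} exceeds maximum "
                    f"{config.max_litter_size}; {n_remove} members removed",
                )
    if doomed:
        out.remove(doomed)
    return out, report


def curate_interbirth(
    studbook: Studbook,
    config: Optional[SpeciesConfig] = None,
) -> tuple[Studbook, CurationReport]:
    """Invalidate implausibly short interbirth intervals.

    Consecutive litters of the same dam must be at least
    ``interbirth_fraction`` (default 90 %) of the effective gestation
    apart; for marsupials the gestation plus the minimum age of first
    pouch eviction is used, since pouch young are often recorded at
    eviction rather than birth.  The later litter of a too-short pair
    loses its dam links; the earlier litter remains the reference.
    Litter grouping must already have been applied.
    """
    config = config or studbook.species
    out = studbook.copy()
    report = CurationReport()
    threshold = config.interbirth_fraction * config.effective_gestation_days

    by_dam: dict[str, dict] = {}
    for rec in out.records:
        if rec.dam_id is not None and rec.birth_date is not None:
            by_dam.setdefault(rec.dam_id, {}).setdefault(
                rec.birth_date, []
            ).append(rec.individual_id)

    for dam_id in sorted(by_dam):
        litters = sorted(by_dam[dam_id].items())
        reference = None
        for date, ids in litters:
            if reference is not None and (date - reference).days < threshold:
                for iid in sorted(ids):
                    out.get(iid).dam_id = None
                report.add(
                    "short_interbirth", sorted(ids), PARENT_LINK_REMOVED,
                    f"dam {dam_id}: interval {(date - reference).days} d "
                    f"< {threshold:.1f} d; dam links removed",
                )
            else:
                reference = date
    return out, report


def _provisional_afr(studbook: Studbook) -> dict[str, float]:
    """Floored minimum parent age at any offspring birth, per sex."""
    youngest: dict[str, float] = {}
    for rec in studbook.records:
        for parent_id in (rec.dam_id, rec.sire_id):
            parent = studbook.get(parent_id)
            if parent is None or parent.sex not in (FEMALE, MALE):
                continue
            age = _parent_age_years(parent, rec)
            if age is None:
                continue
            if parent.sex not in youngest or age < youngest[parent.sex]:
                youngest[parent.sex] = age
    return {sex: math.floor(age) for sex, age in youngest.items()}


def run_curation(
    studbook: Studbook,
    config: Optional[SpeciesConfig] = None,
    seed: int = 0,
) -> tuple[Studbook, CurationReport]:
    """Run the full curation pipeline and consolidate the audit report.

    Order: parentage plausibility (probability, self-parentage, swapped
    and same-sex parents), litter grouping, interbirth intervals, then a
    provisional age-of-first-reproduction estimate from the surviving
    links which drives the underage-parent rule in a single pass.
    Litters are grouped before interbirth checking because litter-mates
    share a birth date by construction and would otherwise trip any
    interbirth threshold.
    """
    config = config or studbook.species
    report = CurationReport()

    out, rep = curate_parentage(studbook, afr_by_sex=None)
    report.extend(rep)
    out, rep = curate_litters(out, config, seed=seed)
    report.extend(rep)
    out, rep = curate_interbirth(out, config)
    report.extend(rep)

    afr = dict(config.afr_override) or _provisional_afr(out)
    if afr:
        out, rep = curate_parentage(out, afr_by_sex=afr)
        report.extend(rep)
    return out, report
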