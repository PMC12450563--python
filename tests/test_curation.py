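import datetime

import pytest

from popshape.curation import (
    compute_max_longevity,
    curate_interbirth,
    curate_litters,
    curate_parentage,
    run_curation,
)
from popshape.studbook_io import SpeciesConfig, write_studbook

from conftest import record, studbook


def parents():
    return [
        record("DAM", sex="female", birth="1995-01-01"),
        record("SIRE", sex="male", birth="1995-01-01"),
        record("M2", sex="male", birth="1995-01-01"),
        record("F2", sex="female", birth="1995-01-01"),
    ]


class TestParentage:
    def test_uncertain_dam_link_is_removed(self):
        sb = studbook(parents() + [
            record("KID", dam="DAM", sire="SIRE", dam_p=80.0),
        ])
        out, report = curate_parentage(sb)
        kid = out.get("KID")
        assert kid.dam_id is None and kid.sire_id == "SIRE"
        assert len(report) == 1

    def test_self_parentage_link_is_removed(self):
        sb = studbook(parents() + [
            record("KID", dam="DAM", sire="KID"),
        ])
        out, _ = curate_parentage(sb)
        assert out.get("KID").sire_id is None
        assert out.get("KID").dam_id == "DAM"

    def test_male_dam_and_female_sire_are_exchanged(self):
        sb = studbook(parents() + [
            record("KID", dam="SIRE", sire="DAM"),
        ])
        out, report = curate_parentage(sb)
        kid = out.get("KID")
        assert kid.dam_id == "DAM" and kid.sire_id == "SIRE"
        assert report.entries[0].action == "parents_swapped"
        assert "KID" in out  # nobody deleted

    @pytest.mark.parametrize("dam,sire,removed_field", [
        ("SIRE", "M2", "dam_id"),    # two males: the dam is wrong
        ("DAM", "F2", "sire_id"),    # two females: the sire is wrong
    ])
    def test_same_sex_parents_lose_the_wrongly_sexed_link(
        self, dam, sire, removed_field
    ):
        sb = studbook(parents() + [record("KID", dam=dam, sire=sire)])
        out, _ = curate_parentage(sb)
        assert getattr(out.get("KID"), removed_field) is None

    def test_underage_parent_link_removed_when_afr_supplied(self):
        sb = studbook(parents() + [
            record("YOUNG", sex="female", birth="2003-01-01"),
            record("KID", birth="2004-07-01", dam="YOUNG", sire="SIRE"),
        ])
        out, _ = curate_parentage(sb, afr_by_sex={"female": 3, "male": 3})
        kid = out.get("KID")
        assert kid.dam_id is None       # dam aged ~1.5 y < 3
        assert kid.sire_id == "SIRE"    # sire aged ~9.5 y

    def test_external_parent_ids_are_kept(self):
        sb = studbook([record("KID", dam="ELSEWHERE", sire=None)])
        out, report = curate_parentage(sb, afr_by_sex={"female": 3})
        assert out.get("KID").dam_id == "ELSEWHERE"
        assert len(report) == 0


class TestMaxLongevity:
    def test_wild_born_and_living_never_hold_the_record(self):
        sb = studbook([
            record("A", birth="1990-01-01", death="2002-04-20"),   # 12.3 y
            record("B", birth="1990-01-01", death="2010-09-14"),   # 20.7 y
            record("C", birth="1990-01-01", death="2015-01-01", wild=True),
            record("D", birth="1980-01-01"),                       # alive
        ])
        assert compute_max_longevity(sb) == 20

    def test_no_zoo_born_dead_individual_raises(self):
        sb = studbook([record("A", birth="1990-01-01")])
        with pytest.raises(ValueError, match="override"):
            compute_max_longevity(sb)

    def test_config_override_wins(self):
        sb = studbook(
            [record("A", birth="1990-01-01", death="2002-04-20")],
            max_longevity_override=22,
        )
        assert compute_max_longevity(sb) == 22


class TestInterbirth:
    def litters_apart(self, days, **config):
        recs = [record("DAM", birth="1990-01-01")]
        recs.append(record("K1", birth="2000-01-01", dam="DAM"))
        second = datetime.date(2000, 1, 1) + datetime.timedelta(days=days)
        recs.append(record("K2", birth=second.isoformat(), dam="DAM"))
        return studbook(recs, **config)

    def test_short_interval_removes_later_litters_dam_link(self):
        out, report = curate_interbirth(self.litters_apart(60, gestation_days=100))
        assert out.get("K2").dam_id is None
        assert out.get("K1").dam_id == "DAM"
        assert len(report) == 1

    def test_interval_at_ninety_percent_is_valid(self):
        out, report = curate_interbirth(self.litters_apart(95, gestation_days=100))
        assert out.get("K2").dam_id == "DAM"
        assert len(report) == 0

    def test_marsupial_threshold_adds_pouch_eviction(self):
        sb = self.litters_apart(
            70, gestation_days=30, is_marsupial=True,
            pouch_eviction_min_days=60,
        )
        out, _ = curate_interbirth(sb)  # 70 < 0.9 * 90 = 81
        assert out.get("K2").dam_id is None

    def test_marsupial_without_pouch_age_is_a_config_error(self):
        with pytest.raises(ValueError, match="pouch_eviction"):
            SpeciesConfig(gestation_days=30, is_marsupial=True)


class TestLitters:
    def test_members_within_window_share_the_middle_date(self):
        sb = studbook([
            record("DAM", birth="1990-01-01"),
            record("K1", birth="2000-06-01", dam="DAM"),
            record("K2", birth="2000-06-02", dam="DAM"),
            record("K3", birth="2000-06-03", dam="DAM"),
        ])
        out, report = curate_litters(sb, seed=0)
        dates = {out.get(k).birth_date for k in ("K1", "K2", "K3")}
        assert dates == {datetime.date(2000, 6, 2)}
        assert len(report) == 1

    def test_births_outside_window_stay_separate(self):
        sb = studbook([
            record("DAM", birth="1990-01-01"),
            record("K1", birth="2000-06-01", dam="DAM"),
            record("K2", birth="2000-06-06", dam="DAM"),
        ])
        out, report = curate_litters(sb, seed=0)
        assert out.get("K1").birth_date == datetime.date(2000, 6, 1)
        assert out.get("K2").birth_date == datetime.date(2000, 6, 6)
        assert len(report) == 0

    def test_oversized_litter_is_cut_in_half(self):
        recs = [record("DAM", birth="1990-01-01")]
        recs += [record(f"K{i}", birth="2000-06-01", dam="DAM")
                 for i in range(8)]
        sb = studbook(recs, max_litter_size=4)
        out, report = curate_litters(sb, seed=5)
        remaining = [r for r in out.records if r.dam_id == "DAM"]
        assert len(remaining) == 4
        removed = next(e for e in report
                       if e.action == "individuals_removed")
        assert len(removed.individual_ids) == 4

    def test_same_seed_gives_identical_removals(self):
        recs = [record("DAM", birth="1990-01-01")]
        recs += [record(f"K{i}", birth="2000-06-01", dam="DAM")
                 for i in range(8)]
        sb = studbook(recs, max_litter_size=4)
        ids1 = {r.individual_id for r in curate_litters(sb, seed=9)[0].records}
        ids2 = {r.individual_id for r in curate_litters(sb, seed=9)[0].records}
        assert ids1 == ids2


class TestRunCuration:
    def test_clean_studbook_is_untouched(self, steady_small):
        sb, _ = steady_small
        out, report = run_curation(sb, sb.species, seed=0)
        assert len(report) == 0
        assert len(out) == len(sb)

    def test_known_violations_yield_matching_entries(self):
        sb = studbook(parents() + [
            record("KID1", dam="SIRE", sire="M2"),          # same-sex pair
            record("K1", birth="2000-01-01", dam="DAM"),
            record("K2", birth="2000-03-01", dam="DAM"),    # 60 d apart
        ], gestation_days=100)
        _, report = run_curation(sb, sb.species, seed=0)
        assert len(report) == 2
        assert {e.rule for e in report} == {
            "same_sex_parents", "short_interbirth",
        }

    def test_second_pass_reports_nothing(self):
        recs = [record("DAM", birth="1990-01-01"),
                record("SIRE", sex="male", birth="1990-01-01")]
        recs += [record(f"K{i}", birth="2000-06-0" + str(1 + i % 3),
                        dam="DAM", sire="SIRE") for i in range(8)]
        sb = studbook(recs, max_litter_size=4)
        once, report1 = run_curation(sb, sb.species, seed=3)
        twice, report2 = run_curation(once, once.species, seed=3)
        assert len(report1) > 0
        assert len(report2) == 0
        assert len(twice) == len(once)

    def test_identical_seed_reproduces_output_exactly(self, tmp_path):
        recs = [record("DAM", birth="1990-01-01")]
        recs += [record(f"K{i}", birth="2000-06-01", dam="DAM")
                 for i in range(9)]
        sb = studbook(recs, max_litter_size=4)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_studbook(run_curation(sb, sb.species, seed=7)[0], a)
        write_studbook(run_curation(sb, sb.species, seed=7)[0], b)
        assert a.read_bytes() == b.read_bytes()

    def test_curation_never_adds_links_or_individuals(self, steady_small):
        sb, _ = steady_small
        from popshape.synthetic import inject_errors
        bad, _ = inject_errors(
            sb, seed=1,
            counts={t: 10 for t in ("same_sex_parents", "self_parent",
                                    "swapped_dam_sire", "oversized_litter")},
        )
        out, _ = run_curation(bad, bad.species, seed=0)
        def n_links(s):
            return sum((r.dam_id is not None) + (r.sire_id is not None)
                       for r in s.records)
        assert len(out) <= len(bad)
        assert n_links(out) <= n_links(bad)
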