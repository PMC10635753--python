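"""Site classification, age exclusion, descriptive tables, death strata."""

import numpy as np
import pytest

from bymap import (
    RegistryRecord,
    Sex,
    SiteClass,
    VitalStatus,
    aggregate_counts,
    apply_age_exclusion,
    classify_site,
    cohort_summary,
    mortality_strata,
    read_registry_csv,
    write_registry_csv,
)


def make_record(i=0, age=60, sex=Sex.male, subsite="gingiva", area="A",
                status=VitalStatus.alive, months=12):
    return RegistryRecord(
        patient_id=f"p{i}", age_at_diagnosis=age, sex=sex, subsite=subsite,
        area_id=area, vital_status=status, survival_months=months,
    )


@pytest.mark.parametrize(
    "label,expected",
    [
        ("floor of the mouth", SiteClass.oral_cavity),
        ("anterior tongue", SiteClass.oral_cavity),
        ("hard palate", SiteClass.oral_cavity),
        ("tongue base", SiteClass.oropharynx),
        ("soft palate", SiteClass.oropharynx),
        ("Palatal Tonsil", SiteClass.oropharynx),  # case-insensitive
        ("unknown primary", SiteClass.not_specified),
    ],
)
def test_subsite_classification(label, expected):
    assert classify_site(label) == expected


class TestAgeExclusion:
    def test_threshold_inclusive_at_15(self):
        records = [make_record(i, age=a) for i, a in enumerate([14, 15, 62])]
        included, excluded = apply_age_exclusion(records)
        assert [r.age_at_diagnosis for r in included] == [15, 62]
        assert excluded[0][0].age_at_diagnosis == 14
        assert "14" in excluded[0][1]

    def test_no_exclusions_when_all_adults(self):
        included, excluded = apply_age_exclusion(
            [make_record(i, age=20 + i) for i in range(5)]
        )
        assert len(included) == 5 and excluded == []

    def test_large_cohort_with_two_minors(self):
        ages = [50] * 9885 + [10, 12]
        records = [make_record(i, age=a) for i, a in enumerate(ages)]
        included, excluded = apply_age_exclusion(records)
        assert len(included) == 9885
        assert len(excluded) == 2


def published_style_cohort():
    """9,885 records reproducing the printed category counts of a large
    oral/oropharyngeal cancer cohort table."""
    records = []
    i = 0

    def add(n, **kw):
        nonlocal i
        for _ in range(n):
            records.append(make_record(i, **kw))
            i += 1

    # age bands 283 / 4,036 / 5,566 crossed independently with the other
    # margins (only the margins matter for the summary percentages)
    ages = [30] * 283 + [50] * 4036 + [70] * 5566
    sexes = [Sex.female] * 2815 + [Sex.male] * 7070
    sites = (["gingiva"] * 5151 + ["tongue base"] * 4578
             + ["unspecified"] * 156)
    statuses = [VitalStatus.alive] * 4026 + [VitalStatus.dead] * 5859
    grades = (["well"] * 1140 + ["moderately_differentiated"] * 4888
              + ["poor"] * 2359 + ["undiff"] * 33 + ["unknown"] * 1465)
    for k in range(9885):
        records.append(
            RegistryRecord(
                patient_id=f"p{k}", age_at_diagnosis=ages[k], sex=sexes[k],
                subsite=sites[k], area_id="A", vital_status=statuses[k],
                survival_months=60, grade=grades[k],
            )
        )
    return records


class TestCohortSummary:
    def test_published_percentages_reproduced(self):
        summary = cohort_summary(published_style_cohort())
        assert summary.n_included == 9885
        assert summary.sex["male"] == (7070, 71.5)
        assert summary.sex["female"] == (2815, 28.5)
        assert summary.age_bands[">=65"] == (5566, 56.3)
        assert summary.age_bands["40-64"] == (4036, 40.8)
        assert summary.site["oral_cavity"] == (5151, 52.1)
        assert summary.site["oropharynx"] == (4578, 46.3)
        assert summary.vital_status["alive"] == (4026, 40.7)
        assert summary.grade["moderately_differentiated"] == (4888, 49.4)

    def test_partitions_sum_to_n_included(self):
        summary = cohort_summary(published_style_cohort())
        for table in (summary.age_bands, summary.sex, summary.site,
                      summary.vital_status):
            assert sum(c for c, _ in table.values()) == summary.n_included

    def test_single_record_is_100_percent(self):
        summary = cohort_summary([make_record()])
        assert summary.sex["male"] == (1, 100.0)
        assert summary.age_bands["40-64"] == (1, 100.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cohort_summary([])

    def test_rounding_is_half_up(self):
        # 1 of 16 = 6.25% -> 6.3 under half-up (banker's would give 6.2)
        records = [make_record(i, sex=Sex.female if i == 0 else Sex.male)
                   for i in range(16)]
        summary = cohort_summary(records)
        assert summary.sex["female"] == (1, 6.3)


class TestMortalityStrata:
    def test_boundary_placement(self):
        months = [1, 36, 37, 60, 61]
        records = [make_record(i, status=VitalStatus.dead, months=m)
                   for i, m in enumerate(months)]
        strata = mortality_strata(records)
        assert strata == {
            "deaths_within_36mo": 2, "deaths_37_to_60mo": 2,
            "deaths_after_60mo": 1, "total_deaths": 5,
        }

    def test_no_deaths(self):
        strata = mortality_strata([make_record()])
        assert strata["total_deaths"] == 0

    def test_published_strata_sum(self):
        # the printed partition 3,482 / 617 / 1,760 must reassemble exactly
        months = [12] * 3482 + [48] * 617 + [120] * 1760
        records = [make_record(i, status=VitalStatus.dead, months=m)
                   for i, m in enumerate(months)]
        strata = mortality_strata(records)
        assert strata["deaths_within_36mo"] == 3482
        assert strata["deaths_37_to_60mo"] == 617
        assert strata["deaths_after_60mo"] == 1760
        assert strata["total_deaths"] == 5859

    def test_strata_always_partition_deaths(self):
        rng = np.random.default_rng(0)
        records = [
            make_record(
                i,
                status=VitalStatus.dead if rng.random() < 0.6 else VitalStatus.alive,
                months=int(rng.integers(0, 479)),
            )
            for i in range(500)
        ]
        strata = mortality_strata(records)
        n_dead = sum(r.vital_status == VitalStatus.dead for r in records)
        assert (strata["deaths_within_36mo"] + strata["deaths_37_to_60mo"]
                + strata["deaths_after_60mo"]) == strata["total_deaths"] == n_dead


class TestAggregateCounts:
    AREAS = ["A", "B"]

    def fixture_records(self):
        # 20-record fixture: mixed areas, statuses and survival times
        spec = [
            ("A", VitalStatus.dead, 10), ("A", VitalStatus.dead, 40),
            ("A", VitalStatus.dead, 70), ("A", VitalStatus.alive, 5),
            ("A", VitalStatus.alive, 90), ("A", VitalStatus.dead, 36),
            ("A", VitalStatus.dead, 60), ("A", VitalStatus.alive, 61),
            ("A", VitalStatus.dead, 61), ("A", VitalStatus.alive, 12),
            ("B", VitalStatus.dead, 1), ("B", VitalStatus.alive, 400),
            ("B", VitalStatus.dead, 59), ("B", VitalStatus.dead, 37),
            ("B", VitalStatus.alive, 36), ("B", VitalStatus.dead, 100),
            ("B", VitalStatus.alive, 60), ("B", VitalStatus.dead, 0),
            ("B", VitalStatus.alive, 24), ("B", VitalStatus.dead, 478),
        ]
        return [make_record(i, area=a, status=s, months=m)
                for i, (a, s, m) in enumerate(spec)]

    def test_incidence_counts_everyone(self):
        counts = aggregate_counts(self.fixture_records(), self.AREAS)
        assert counts.tolist() == [10, 10]
        assert counts.sum() == 20

    def test_death_strata_match_brute_force_filter(self):
        records = self.fixture_records()
        brute = {
            "overall_death": [
                sum(1 for r in records
                    if r.area_id == a and r.vital_status == VitalStatus.dead)
                for a in self.AREAS
            ],
            "death_within_36mo": [
                sum(1 for r in records
                    if r.area_id == a and r.vital_status == VitalStatus.dead
                    and r.survival_months <= 36)
                for a in self.AREAS
            ],
            "death_within_60mo": [
                sum(1 for r in records
                    if r.area_id == a and r.vital_status == VitalStatus.dead
                    and r.survival_months <= 60)
                for a in self.AREAS
            ],
        }
        for stratum, expected in brute.items():
            counts = aggregate_counts(records, self.AREAS, stratum=stratum)
            assert counts.tolist() == expected

    def test_order_invariance(self):
        records = self.fixture_records()
        shuffled = list(reversed(records))
        a = aggregate_counts(records, self.AREAS, stratum="death_within_60mo")
        b = aggregate_counts(shuffled, self.AREAS, stratum="death_within_60mo")
        assert a.tolist() == b.tolist()

    def test_unknown_area_listed_in_error(self):
        records = [make_record(0, area="Z")]
        with pytest.raises(ValueError, match="Z"):
            aggregate_counts(records, self.AREAS)

    def test_zero_count_area_kept(self):
        records = [make_record(0, area="A")]
        counts = aggregate_counts(records, self.AREAS)
        assert counts["B"] == 0


def test_registry_csv_round_trip(tmp_path):
    records = [make_record(i, age=30 + i) for i in range(5)]
    path = tmp_path / "registry.csv"
    write_registry_csv(records, path)
    back = read_registry_csv(path)
    assert back == records
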