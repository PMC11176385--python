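"""Register data model: IO round trips, ICD mapping, filters, pedigree."""

import pandas as pd
import pytest

from regliab.registry import (CohortRules, DisorderCatalog, RowError,
                              SchemaError, apply_cohort_filters,
                              build_pedigree_index, default_catalog,
                              expand_code_range, load_registry,
                              map_icd_codes, write_registry)

PERSONS_TSV = (
    "person_id\tsex\tbirth_date\tdeath_date\temigration_date\tmother_id\t"
    "father_id\tborn_in_country\n"
    "1\tfemale\t1985-03-04\t\t\t\t\t1\n"
    "2\tmale\t1987-11-30\t2010-01-02\t\t\t\t1\n"
    "3\tfemale\t1990-06-15\t\t2005-07-01\t1\t2\t0\n"
)
DIAGNOSES_TSV = (
    "person_id\ticd_version\tcode\tdate\n"
    "1\t10\tF200\t2004-05-06\n"
    "3\t10\tE11\t2001-02-03\n"
)


@pytest.fixture
def registry_files(tmp_path):
    p = tmp_path / "persons.tsv"
    d = tmp_path / "diagnoses.tsv"
    p.write_text(PERSONS_TSV)
    d.write_text(DIAGNOSES_TSV)
    return p, d


class TestIO:
    def test_round_trip_is_byte_identical(self, registry_files, tmp_path):
        p, d = registry_files
        persons, diagnoses = load_registry(p, d)
        assert len(persons) == 3 and len(diagnoses) == 2
        p2, d2 = tmp_path / "p2.tsv", tmp_path / "d2.tsv"
        write_registry(persons, diagnoses, p2, d2)
        assert p2.read_bytes() == p.read_bytes()
        assert d2.read_bytes() == d.read_bytes()

    def test_missing_column_names_it(self, tmp_path, registry_files):
        _, d = registry_files
        bad = tmp_path / "bad.tsv"
        bad.write_text("person_id\tsex\n1\tfemale\n")
        with pytest.raises(SchemaError, match="birth_date"):
            load_registry(bad, d)

    def test_header_only_files_load_empty(self, tmp_path):
        p = tmp_path / "p.tsv"
        d = tmp_path / "d.tsv"
        p.write_text(PERSONS_TSV.splitlines()[0] + "\n")
        d.write_text(DIAGNOSES_TSV.splitlines()[0] + "\n")
        persons, diagnoses = load_registry(p, d)
        assert len(persons) == 0 and len(diagnoses) == 0

    def test_bad_date_reports_line_number(self, tmp_path, registry_files):
        _, d = registry_files
        p = tmp_path / "p.tsv"
        p.write_text(PERSONS_TSV.replace("1987-11-30", "30/11/1987"))
        with pytest.raises(RowError, match="line"):
            load_registry(p, d)

    def test_death_before_birth_rejected(self, tmp_path, registry_files):
        _, d = registry_files
        p = tmp_path / "p.tsv"
        p.write_text(PERSONS_TSV.replace("2010-01-02", "1980-01-02"))
        with pytest.raises(RowError, match="death_date"):
            load_registry(p, d)

    def test_duplicate_person_id_rejected(self, tmp_path, registry_files):
        _, d = registry_files
        p = tmp_path / "p.tsv"
        p.write_text(PERSONS_TSV + "1\tmale\t1991-01-01\t\t\t\t\t1\n")
        with pytest.raises(RowError, match="duplicate"):
            load_registry(p, d)


def _events(rows):
    return pd.DataFrame(
        [{"person_id": pid, "icd_version": v, "code": code,
          "date": pd.Timestamp(date)} for pid, v, code, date in rows])


class TestIcdMapping:
    def test_schizophrenia_prefix(self):
        out = map_icd_codes(_events([("1", 10, "F200", "2000-01-01")]),
                            default_catalog())
        assert set(out["disorder"]) == {"SCZ"}

    def test_excluded_autism_subcode(self):
        out = map_icd_codes(_events([("1", 10, "F842", "2000-01-01")]),
                            default_catalog())
        assert "ASD" not in set(out["disorder"])

    def test_bipolar_codes_also_map_to_affective(self):
        out = map_icd_codes(_events([("1", 10, "F310", "2000-01-01")]),
                            default_catalog())
        assert set(out["disorder"]) == {"AFF", "BD"}

    def test_unmapped_code_dropped(self):
        out = map_icd_codes(_events([("1", 10, "X999", "2000-01-01")]),
                            default_catalog())
        assert len(out) == 0

    def test_unknown_icd_version_rejected(self):
        with pytest.raises(ValueError, match="ICD version"):
            map_icd_codes(_events([("1", 7, "F200", "2000-01-01")]),
                          default_catalog())

    def test_earliest_date_kept_and_order_independent(self):
        rows = [("1", 10, "F200", "2005-01-01"),
                ("1", 10, "F201", "2001-06-01"),
                ("1", 10, "F209", "2009-01-01")]
        cat = default_catalog()
        out_fwd = map_icd_codes(_events(rows), cat)
        out_rev = map_icd_codes(_events(rows[::-1]), cat)
        assert out_fwd.equals(out_rev)
        assert out_fwd["date"].iloc[0] == pd.Timestamp("2001-06-01")

    def test_idempotent_on_mapped_duplicates(self):
        rows = [("1", 10, "F200", "2001-01-01")] * 3
        out = map_icd_codes(_events(rows), default_catalog())
        assert len(out) == 1

    def test_dotted_codes_normalised(self):
        out = map_icd_codes(_events([("1", 10, "f50.1", "2000-01-01")]),
                            default_catalog())
        assert set(out["disorder"]) == {"AN"}

    def test_range_expansion(self):
        assert expand_code_range("F30-F39") == [f"F{n}" for n in range(30, 40)]
        assert expand_code_range("I48") == ["I48"]

    def test_catalog_requires_prefixes(self):
        with pytest.raises(ValueError):
            DisorderCatalog.from_dict({"EMPTY": {"class": "mental"}})


def _person(pid, birth, born_in=True, mother=None, father=None):
    return dict(person_id=pid, sex="female", birth_date=pd.Timestamp(birth),
                death_date=pd.NaT, emigration_date=pd.NaT, mother_id=mother,
                father_id=father, born_in_country=born_in)


class TestCohortFilters:
    RULES = CohortRules(birth_year_range=(1981, 2005),
                        study_end=pd.Timestamp("2012-12-31"))

    def test_early_psychotic_diagnosis_excludes_person(self):
        persons = pd.DataFrame([_person("1", "1990-01-01")])
        events = pd.DataFrame([{"person_id": "1", "disorder": "SCZ",
                                "date": pd.Timestamp("1999-06-01")}])  # age 9
        cohort = apply_cohort_filters(persons, events, self.RULES)
        assert len(cohort) == 0

    def test_early_adhd_diagnosis_retained(self):
        persons = pd.DataFrame([_person("1", "1990-01-01")])
        events = pd.DataFrame([{"person_id": "1", "disorder": "ADHD",
                                "date": pd.Timestamp("1999-06-01")}])
        cohort = apply_cohort_filters(persons, events, self.RULES)
        assert cohort.person_ids == frozenset({"1"})

    def test_foreign_born_excluded(self):
        persons = pd.DataFrame([_person("1", "1990-01-01", born_in=False),
                                _person("2", "1990-01-01")])
        cohort = apply_cohort_filters(persons, pd.DataFrame(
            columns=["person_id", "disorder", "date"]), self.RULES)
        assert cohort.person_ids == frozenset({"2"})

    def test_birth_year_range_enforced(self):
        persons = pd.DataFrame([_person("1", "1975-01-01"),
                                _person("2", "1990-01-01"),
                                _person("3", "2007-01-01")])
        cohort = apply_cohort_filters(persons, pd.DataFrame(
            columns=["person_id", "disorder", "date"]), self.RULES)
        assert cohort.person_ids == frozenset({"2"})

    def test_filters_commute_and_never_add(self):
        persons = pd.DataFrame([
            _person("1", "1990-01-01", born_in=False),
            _person("2", "1990-01-01"), _person("3", "1979-01-01"),
            _person("4", "1992-01-01")])
        events = pd.DataFrame([{"person_id": "4", "disorder": "BD",
                                "date": pd.Timestamp("2000-01-01")}])
        full = apply_cohort_filters(persons, events, self.RULES)
        only_country = apply_cohort_filters(
            persons, events, CohortRules((1900, 2100),
                                         self.RULES.study_end,
                                         early_exclusion_disorders=()))
        only_years = apply_cohort_filters(
            persons, events, CohortRules(self.RULES.birth_year_range,
                                         self.RULES.study_end,
                                         require_born_in_country=False,
                                         early_exclusion_disorders=()))
        only_age = apply_cohort_filters(
            persons, events, CohortRules((1900, 2100), self.RULES.study_end,
                                         require_born_in_country=False))
        intersected = (only_country.person_ids & only_years.person_ids
                       & only_age.person_ids)
        assert full.person_ids == intersected == frozenset({"2"})
        assert full.person_ids <= frozenset(persons["person_id"])


class TestPedigree:
    def test_full_sibling_set(self):
        persons = pd.DataFrame([
            _person("M", "1960-01-01"), _person("F", "1961-01-01"),
            _person("A", "1990-01-01", mother="M", father="F"),
            _person("B", "1992-01-01", mother="M", father="F")])
        idx = build_pedigree_index(persons)
        assert idx.sibling_sets == [frozenset({"A", "B"})]
        assert idx.a_R == 0.5
        pairs = set(map(tuple, idx.parent_child.to_numpy()))
        assert pairs == {("M", "A"), ("M", "B"), ("F", "A"), ("F", "B")}

    def test_half_siblings_not_linked(self):
        persons = pd.DataFrame([
            _person("M", "1960-01-01"),
            _person("A", "1990-01-01", mother="M", father="F1"),
            _person("B", "1992-01-01", mother="M", father="F2")])
        idx = build_pedigree_index(persons)
        assert idx.sibling_sets == []

    def test_missing_parent_never_groups(self):
        persons = pd.DataFrame([
            _person("A", "1990-01-01", mother="M"),
            _person("B", "1992-01-01", mother="M")])
        idx = build_pedigree_index(persons)
        assert idx.sibling_sets == []
        assert set(idx.parent_child["parent_id"]) == {"M"}

    def test_all_parents_missing_gives_empty_index(self):
        persons = pd.DataFrame([_person("A", "1990-01-01"),
                                _person("B", "1992-01-01")])
        idx = build_pedigree_index(persons)
        assert len(idx.sibships) == 0 and len(idx.parent_child) == 0

    def test_cyclic_parentage_rejected(self):
        persons = pd.DataFrame([
            _person("A", "1990-01-01", mother="B"),
            _person("B", "1992-01-01", mother="A")])
        with pytest.raises(ValueError, match="cyclic"):
            build_pedigree_index(persons)

    def test_self_parent_rejected(self):
        persons = pd.DataFrame([_person("A", "1990-01-01", mother="A")])
        with pytest.raises(ValueError, match="own parent"):
            build_pedigree_index(persons)
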