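"""Register-shaped data model: readers/writers, ICD mapping, cohort filters,
and pedigree indexing.

Person and diagnosis tables are plain TSV (UTF-8, ISO-8601 dates, empty
string = missing) mirroring the layout of Nordic national registers: one
row per person with parental links and vital dates, and one row per
hospital diagnosis with its ICD version and code.  Disorder definitions
are prefix sets over dot-stripped ICD codes, loaded from a structured
catalogue (a packaged ICD-10 default is provided).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

PERSON_COLUMNS = [
    "person_id", "sex", "birth_date", "death_date", "emigration_date",
    "mother_id", "father_id", "born_in_country",
]
DIAGNOSIS_COLUMNS = ["person_id", "icd_version", "code", "date"]

DAYS_PER_YEAR = 365.25

__all__ = [
    "SchemaError", "RowError", "PERSON_COLUMNS", "DIAGNOSIS_COLUMNS",
    "load_registry", "write_registry", "DisorderCatalog", "default_catalog",
    "map_icd_codes", "CohortRules", "Cohort", "apply_cohort_filters",
    "PedigreeIndex", "build_pedigree_index", "age_in_years",
]


class SchemaError(ValueError):
    """A required column is missing or mistyped."""


class RowError(ValueError):
    """A row-level parse or consistency failure, reported with line numbers."""


def age_in_years(date, birth_date):
    """Real-valued age: (date - birth_date) / 365.25 days."""
    return (date - birth_date) / pd.Timedelta(days=DAYS_PER_YEAR)


def _parse_dates(frame: pd.DataFrame, columns: Iterable[str], path) -> None:
    for col in columns:
        raw = frame[col].fillna("").astype(str).str.strip()
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        bad = raw.ne("") & parsed.isna()
        if bad.any():
            lines = [str(i + 2) for i in frame.index[bad][:5]]  # +2: header + 1-based
            raise RowError(
                f"{path}: unparseable {col} on line(s) {', '.join(lines)}"
            )
        frame[col] = parsed


def _read_table(path, required: list[str], date_columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    frame = frame.replace({"": pd.NA})
    _parse_dates(frame, date_columns, path)
    return frame


def load_registry(person_path, diagnosis_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the person and diagnosis tables.

    Returns typed DataFrames; identifiers stay as strings, dates become
    datetime64, ``born_in_country`` becomes boolean and ``icd_version``
    integer.  Raises :class:`SchemaError` for missing columns and
    :class:`RowError` (with line numbers) for malformed rows.
    """
    persons = _read_table(person_path, PERSON_COLUMNS,
                          ["birth_date", "death_date", "emigration_date"])
    if persons["person_id"].isna().any():
        raise RowError(f"{person_path}: empty person_id")
    if persons["person_id"].duplicated().any():
        dup = persons["person_id"][persons["person_id"].duplicated()].iloc[0]
        raise RowError(f"{person_path}: duplicate person_id {dup!r}")
    if len(persons) and persons["birth_date"].isna().any():
        line = persons.index[persons["birth_date"].isna()][0] + 2
        raise RowError(f"{person_path}: missing birth_date on line {line}")
    for col in ("death_date", "emigration_date"):
        early = persons[col].notna() & (persons[col] < persons["birth_date"])
        if early.any():
            line = persons.index[early][0] + 2
            raise RowError(f"{person_path}: {col} before birth_date on line {line}")
    bic = persons["born_in_country"].fillna("0")
    if not bic.isin(["0", "1"]).all():
        raise RowError(f"{person_path}: born_in_country must be 0 or 1")
    persons["born_in_country"] = bic.eq("1")

    diagnoses = _read_table(diagnosis_path, DIAGNOSIS_COLUMNS, ["date"])
    if len(diagnoses):
        if diagnoses["code"].isna().any():
            line = diagnoses.index[diagnoses["code"].isna()][0] + 2
            raise RowError(f"{diagnosis_path}: empty code on line {line}")
        try:
            diagnoses["icd_version"] = diagnoses["icd_version"].astype(int)
        except (TypeError, ValueError) as exc:
            raise RowError(f"{diagnosis_path}: non-integer icd_version") from exc
    else:
        diagnoses["icd_version"] = diagnoses["icd_version"].astype("int64")
    return persons, diagnoses


def _format_dates(frame: pd.DataFrame, columns: Iterable[str]) -> pd.DataFrame:
    out = frame.copy()
    for col in columns:
        out[col] = out[col].dt.strftime("%Y-%m-%d")
    return out


def write_registry(persons: pd.DataFrame, diagnoses: pd.DataFrame,
                   person_path, diagnosis_path) -> None:
    """Write the tables back to TSV in the canonical column order.

    Dates are formatted YYYY-MM-DD, missing values as empty strings and
    ``born_in_country`` as 0/1, so a load/write cycle is byte-stable.
    """
    p = _format_dates(persons, ["birth_date", "death_date", "emigration_date"])
    p["born_in_country"] = p["born_in_country"].astype(int)
    p[PERSON_COLUMNS].to_csv(person_path, sep="\t", index=False,
                             na_rep="", lineterminator="\n")
    d = _format_dates(diagnoses, ["date"])
    d[DIAGNOSIS_COLUMNS].to_csv(diagnosis_path, sep="\t", index=False,
                                na_rep="", lineterminator="\n")


# --------------------------------------------------------------------------
# Disorder catalogue and ICD mapping

_RANGE_RE = re.compile(r"^([A-Z]+)(\d+)\s*-\s*([A-Z]*)(\d+)$")


def expand_code_range(token: str) -> list[str]:
    """Expand a range notation like 'F30-F39' into ['F30', ..., 'F39']."""
    token = token.strip().upper().replace(".", "")
    m = _RANGE_RE.match(token)
    if not m:
        return [token]
    letter, lo, letter2, hi = m.groups()
    if letter2 and letter2 != letter:
        raise ValueError(f"code range {token!r} spans different letter blocks")
    width = len(lo)
    return [f"{letter}{n:0{width}d}" for n in range(int(lo), int(hi) + 1)]


@dataclass(frozen=True)
class DisorderDef:
    label: str
    disorder_class: str  # "mental" | "cardiometabolic"
    prefixes: Mapping[int, frozenset[str]]  # icd_version -> prefix set


@dataclass(frozen=True)
class DisorderCatalog:
    """Mapping of disorder label to per-ICD-version code prefix sets."""

    disorders: Mapping[str, DisorderDef]

    def __post_init__(self):
        for label, dd in self.disorders.items():
            if not any(dd.prefixes.get(v) for v in (8, 9, 10)):
                raise ValueError(f"disorder {label!r} has no code prefixes")

    def labels(self, disorder_class: str | None = None) -> list[str]:
        return [l for l, d in self.disorders.items()
                if disorder_class is None or d.disorder_class == disorder_class]

    def prefixes(self, label: str, icd_version: int) -> frozenset[str]:
        return self.disorders[label].prefixes.get(icd_version, frozenset())

    @classmethod
    def from_dict(cls, raw: Mapping) -> "DisorderCatalog":
        disorders = {}
        for label, entry in raw.items():
            prefixes = {}
            for version, key in ((8, "icd8"), (9, "icd9"), (10, "icd10")):
                tokens = entry.get(key) or []
                expanded: set[str] = set()
                for tok in tokens:
                    expanded.update(expand_code_range(str(tok)))
                if expanded:
                    prefixes[version] = frozenset(expanded)
            disorders[label] = DisorderDef(
                label=label, disorder_class=entry["class"], prefixes=prefixes
            )
        return cls(disorders=disorders)

    @classmethod
    def from_yaml(cls, path) -> "DisorderCatalog":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_catalog() -> DisorderCatalog:
    """The packaged ICD-10 default catalogue."""
    ref = resources.files("regliab").joinpath("data/default_catalog.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return DisorderCatalog.from_dict(yaml.safe_load(fh))


def map_icd_codes(events: pd.DataFrame, catalog: DisorderCatalog) -> pd.DataFrame:
    """Map diagnosis events to disorder labels; keep earliest date per label.

    An event maps to every disorder whose prefix set (for the event's ICD
    version) contains a prefix of the dot-stripped uppercase code; events
    matching nothing are dropped with a logged count.  Output columns:
    person_id, disorder, date (the per person-disorder onset).
    """
    if len(events) == 0:
        return pd.DataFrame(columns=["person_id", "disorder", "date"])
    versions = set(events["icd_version"].unique().tolist())
    unknown = versions - {8, 9, 10}
    if unknown:
        raise ValueError(f"unknown ICD version(s): {sorted(unknown)}")
    codes = events["code"].astype(str).str.upper().str.replace(".", "", regex=False)
    pieces = []
    matched = np.zeros(len(events), dtype=bool)
    for label in catalog.labels():
        mask = np.zeros(len(events), dtype=bool)
        for version in (8, 9, 10):
            prefixes = catalog.prefixes(label, version)
            if not prefixes:
                continue
            vmask = events["icd_version"].to_numpy() == version
            if vmask.any():
                hit = codes.str.startswith(tuple(prefixes)).to_numpy()
                mask |= vmask & hit
        matched |= mask
        if mask.any():
            sub = events.loc[mask, ["person_id", "date"]].copy()
            sub["disorder"] = label
            pieces.append(sub)
    n_dropped = int((~matched).sum())
    if n_dropped:
        logger.info("map_icd_codes: %d event(s) matched no disorder and were dropped",
                    n_dropped)
    if not pieces:
        return pd.DataFrame(columns=["person_id", "disorder", "date"])
    mapped = pd.concat(pieces, ignore_index=True)
    onset = (
        mapped.groupby(["person_id", "disorder"], as_index=False, sort=True)["date"]
        .min()
    )
    return onset[["person_id", "disorder", "date"]]


# --------------------------------------------------------------------------
# Cohort filters

@dataclass(frozen=True)
class CohortRules:
    """Inclusion rules for the analysis cohort."""

    birth_year_range: tuple[int, int]
    study_end: pd.Timestamp
    require_born_in_country: bool = True
    early_exclusion_disorders: tuple[str, ...] = ("SCZ", "BD", "AFF")
    early_exclusion_age: float = 10.0


@dataclass(frozen=True)
class Cohort:
    """A set of person identifiers under administrative censoring."""

    person_ids: frozenset
    study_end: pd.Timestamp
    birth_year_range: tuple[int, int]

    def __len__(self) -> int:
        return len(self.person_ids)


def apply_cohort_filters(persons: pd.DataFrame, mapped_events: pd.DataFrame,
                         rules: CohortRules) -> Cohort:
    """Apply country-of-birth, early-diagnosis, and birth-year filters.

    Persons are excluded when born outside the country, when their first
    diagnosis of any disorder in ``early_exclusion_disorders`` falls before
    ``early_exclusion_age`` years, or when their birth year falls outside
    the configured range.  Filters only remove persons and commute.
    """
    keep = pd.Series(True, index=persons.index)
    if rules.require_born_in_country:
        keep &= persons["born_in_country"].astype(bool)
    years = persons["birth_date"].dt.year
    lo, hi = rules.birth_year_range
    keep &= years.between(lo, hi)

    if len(mapped_events) and rules.early_exclusion_disorders:
        early = mapped_events[
            mapped_events["disorder"].isin(rules.early_exclusion_disorders)
        ]
        if len(early):
            joined = early.merge(
                persons[["person_id", "birth_date"]], on="person_id", how="inner"
            )
            onset_age = age_in_years(joined["date"], joined["birth_date"])
            too_young = set(joined.loc[onset_age < rules.early_exclusion_age,
                                       "person_id"])
            if too_young:
                logger.info("apply_cohort_filters: %d person(s) removed by the "
                            "early-diagnosis rule", len(too_young))
                keep &= ~persons["person_id"].isin(too_young)

    ids = frozenset(persons.loc[keep, "person_id"])
    return Cohort(person_ids=ids, study_end=pd.Timestamp(rules.study_end),
                  birth_year_range=rules.birth_year_range)


# --------------------------------------------------------------------------
# Pedigree indexing

@dataclass(frozen=True)
class PedigreeIndex:
    """Full-sibling sets and parent-offspring pairs.

    Both relationship kinds carry additive relationship a_R = 0.5.
    ``sibships`` maps person_id -> sibship key for persons belonging to a
    full-sibling set of size >= 2; ``parent_child`` lists one row per
    non-missing parent link.
    """

    sibships: pd.DataFrame  # columns: person_id, sibship
    parent_child: pd.DataFrame  # columns: parent_id, child_id
    a_R: float = 0.5

    @property
    def sibling_sets(self) -> list[frozenset]:
        return [frozenset(g) for _, g in self.sibships.groupby("sibship")["person_id"]]


def _check_acyclic(persons: pd.DataFrame) -> None:
    """Iteratively peel founder generations; leftovers imply a parental cycle."""
    remaining = persons[["person_id", "mother_id", "father_id"]]
    while len(remaining):
        mother_known = (~remaining["mother_id"].isin(remaining["person_id"]))
        father_known = (~remaining["father_id"].isin(remaining["person_id"]))
        resolvable = (remaining["mother_id"].isna() | mother_known) & (
            remaining["father_id"].isna() | father_known
        )
        if not resolvable.any():
            cyc = remaining["person_id"].iloc[0]
            raise ValueError(f"cyclic parentage detected involving person {cyc!r}")
        remaining = remaining[~resolvable]


def build_pedigree_index(persons: pd.DataFrame) -> PedigreeIndex:
    """Index full siblings (both parents shared and non-missing) and
    parent-offspring pairs; rejects cyclic parentage."""
    self_parent = (persons["person_id"] == persons["mother_id"]) | (
        persons["person_id"] == persons["father_id"]
    )
    if self_parent.any():
        bad = persons.loc[self_parent, "person_id"].iloc[0]
        raise ValueError(f"person {bad!r} is its own parent")
    _check_acyclic(persons)

    both = persons[persons["mother_id"].notna() & persons["father_id"].notna()]
    if len(both):
        key = both["mother_id"].astype(str) + "\x1f" + both["father_id"].astype(str)
        sizes = key.map(key.value_counts())
        sib = pd.DataFrame({"person_id": both["person_id"], "sibship": key})
        sib = sib[sizes >= 2].reset_index(drop=True)
    else:
        sib = pd.DataFrame(columns=["person_id", "sibship"])

    pieces = []
    for col in ("mother_id", "father_id"):
        links = persons[persons[col].notna()]
        if len(links):
            pieces.append(pd.DataFrame({
                "parent_id": links[col].to_numpy(),
                "child_id": links["person_id"].to_numpy(),
            }))
    if pieces:
        pc = pd.concat(pieces, ignore_index=True)
    else:
        pc = pd.DataFrame(columns=["parent_id", "child_id"])
    return PedigreeIndex(sibships=sib, parent_child=pc)
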