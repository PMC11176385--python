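"""Synthetic register simulator under a bivariate liability-threshold model.

Nuclear families (two founder parents, a configurable number of children)
receive per-trait liabilities for two disorders c and f.  Genetic
components follow an additive infinitesimal model: founder genetic values
are bivariate normal with variances (h_c2, h_f2) and covariance
rg * h_c * h_f; each child's genetic value is the mid-parent mean plus an
independent Mendelian-segregation deviate with half the founder genetic
covariance.  Environmental components are independent across individuals,
bivariate normal with variances (1 - h_c2, 1 - h_f2) and covariance
re * sqrt((1 - h_c2)(1 - h_f2)); total liability variance is 1 per trait.
A person is affected on trait t iff liability exceeds the upper-tail
normal quantile of the lifetime risk K_t.

Affected individuals draw an onset age from a truncated-logistic
distribution (independent of liability magnitude); a diagnosis event is
recorded only if onset precedes death, emigration and the administrative
study end.  Output conforms to the registry table formats, together with
a truth record echoing every generative parameter.

Exact familial recurrence risks implied by the model are available from
:func:`expected_familial_risks` by bivariate-normal quadrature, serving
as numerical oracles for the estimation modules.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.stats import norm

from .registry import DisorderCatalog, default_catalog, write_registry

logger = logging.getLogger(__name__)

__all__ = [
    "DisorderSpec", "SimulationConfig", "FamilialRiskOracle",
    "simulate_registry", "expected_familial_risks", "bvn_upper_tail",
    "familial_recurrence_risk", "cross_disorder_risk",
    "make_fixture", "SCENARIOS",
]


@dataclass(frozen=True)
class DisorderSpec:
    """Generative parameters for one disorder."""

    label: str
    K: float  # lifetime risk
    h2: float  # narrow-sense liability heritability
    onset_location: float = 23.0  # years; logistic location
    onset_scale: float = 3.0  # years; logistic scale

    def __post_init__(self):
        if not (0.0 < self.K < 1.0):
            raise ValueError(f"{self.label}: lifetime risk K must be in (0, 1)")
        if not (0.0 <= self.h2 < 1.0):
            raise ValueError(f"{self.label}: h2 must be in [0, 1)")
        if self.onset_scale <= 0:
            raise ValueError(f"{self.label}: onset_scale must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated register.

    Defaults emulate a Nordic-register-style design: birth cohorts
    1981-2005 with administrative censoring late enough (2045) that the
    configured early-adult onset distributions are essentially fully
    observed, a common mental disorder (K = 5%, h2 = 0.6) paired with a
    common cardiometabolic disorder (K = 10%, h2 = 0.4), moderate genetic
    overlap (rg = 0.3) and weak environmental overlap (re = 0.15), and
    small constant annual death and emigration hazards appropriate for
    young adults.
    """

    n_families: int = 1000
    children_per_family: int = 2
    birth_year_range: tuple[int, int] = (1981, 2005)
    study_end: str = "2045-12-31"
    disorder_c: DisorderSpec = field(
        default_factory=lambda: DisorderSpec("SCZ", K=0.05, h2=0.6,
                                             onset_location=23.0, onset_scale=3.0))
    disorder_f: DisorderSpec = field(
        default_factory=lambda: DisorderSpec("T2D", K=0.10, h2=0.4,
                                             onset_location=26.0, onset_scale=4.0))
    rg: float = 0.3
    re: float = 0.15
    death_hazard: float = 0.0002  # per year
    emigration_hazard: float = 0.001  # per year
    onset_max_age: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.n_families < 1 or self.children_per_family < 1:
            raise ValueError("n_families and children_per_family must be >= 1")
        if abs(self.rg) > 1 or abs(self.re) > 1:
            raise ValueError("rg and re must lie in [-1, 1] (covariances PSD)")
        if self.death_hazard < 0 or self.emigration_hazard < 0:
            raise ValueError("hazards must be >= 0")

    @property
    def genetic_cov(self) -> np.ndarray:
        hc = np.sqrt(self.disorder_c.h2)
        hf = np.sqrt(self.disorder_f.h2)
        return np.array([[hc * hc, self.rg * hc * hf],
                         [self.rg * hc * hf, hf * hf]])

    @property
    def environmental_cov(self) -> np.ndarray:
        ec = 1.0 - self.disorder_c.h2
        ef = 1.0 - self.disorder_f.h2
        off = self.re * np.sqrt(ec * ef)
        return np.array([[ec, off], [off, ef]])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass(frozen=True)
class FamilialRiskOracle:
    """Model-implied familial recurrence risks for one relationship kind."""

    a_R: float
    K_R_c: float  # risk of c given a relative affected with c
    K_R_f: float  # risk of f given a relative affected with f
    K_Rc: float  # risk of c given a relative affected with f


def bvn_upper_tail(t1: float, t2: float, rho: float) -> float:
    """P(Z1 > t1, Z2 > t2) for standard bivariate normal with correlation rho.

    Evaluated as a one-dimensional quadrature of the conditional tail,
    absolute tolerance well below 1e-8.
    """
    if abs(rho) >= 1.0:
        if rho >= 1.0:
            return float(norm.sf(max(t1, t2)))
        return float(max(0.0, norm.sf(t1) - norm.cdf(t2)))
    if rho == 0.0:
        return float(norm.sf(t1) * norm.sf(t2))
    s = np.sqrt(1.0 - rho * rho)
    value, _ = quad(
        lambda x: norm.pdf(x) * norm.sf((t2 - rho * x) / s),
        t1, np.inf, epsabs=1e-12, epsrel=1e-10, limit=200,
    )
    return float(value)


def familial_recurrence_risk(K: float, h2: float, a_R: float) -> float:
    """K_R = P(Z2 > T | Z1 > T) under liability correlation a_R * h2."""
    T = float(norm.isf(K))
    return bvn_upper_tail(T, T, a_R * h2) / K


def cross_disorder_risk(K_c: float, K_f: float, h_c2: float, h_f2: float,
                        rg: float, a_R: float) -> float:
    """K_Rc = P(Z_c > T_c | relative's Z_f > T_f), correlation a_R rg h_c h_f."""
    T_c = float(norm.isf(K_c))
    T_f = float(norm.isf(K_f))
    rho = a_R * rg * np.sqrt(h_c2 * h_f2)
    return bvn_upper_tail(T_f, T_c, rho) / K_f


def expected_familial_risks(config: SimulationConfig,
                            relationship: str = "full_sibling") -> FamilialRiskOracle:
    """Exact model-implied recurrence risks for the configured parameters.

    Full siblings and parent-offspring pairs both carry a_R = 0.5, so the
    two relationship kinds share the same oracle values.
    """
    if relationship not in ("full_sibling", "parent_offspring"):
        raise ValueError(f"unknown relationship {relationship!r}")
    a_R = 0.5
    c, f = config.disorder_c, config.disorder_f
    return FamilialRiskOracle(
        a_R=a_R,
        K_R_c=familial_recurrence_risk(c.K, c.h2, a_R),
        K_R_f=familial_recurrence_risk(f.K, f.h2, a_R),
        K_Rc=cross_disorder_risk(c.K, f.K, c.h2, f.h2, config.rg, a_R),
    )


def _truncated_logistic(rng: np.random.Generator, loc: float, scale: float,
                        upper: float, size: int) -> np.ndarray:
    """Inverse-CDF sampling of a logistic truncated to [0, upper]."""
    lo = 1.0 / (1.0 + np.exp(loc / scale))  # CDF at 0
    hi = 1.0 / (1.0 + np.exp(-(upper - loc) / scale))  # CDF at upper
    u = rng.uniform(lo, hi, size=size)
    return loc + scale * np.log(u / (1.0 - u))


def _exponential_or_inf(rng: np.random.Generator, hazard: float,
                        size: int) -> np.ndarray:
    if hazard <= 0:
        return np.full(size, np.inf)
    return rng.exponential(1.0 / hazard, size=size)


def simulate_registry(config: SimulationConfig,
                      catalog: DisorderCatalog | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate one register: (persons table, diagnoses table, truth record).

    Deterministic given ``config.seed``.  Diagnosis codes are the first
    ICD-10 prefix of each disorder's catalogue entry.
    """
    np.linalg.cholesky(config.genetic_cov + 1e-12 * np.eye(2))  # PSD check
    np.linalg.cholesky(config.environmental_cov + 1e-12 * np.eye(2))
    if catalog is None:
        catalog = default_catalog()
    rng = np.random.default_rng(config.seed)

    nfam = config.n_families
    nchild = config.children_per_family
    n_parents = 2 * nfam
    n_children = nfam * nchild
    n = n_parents + n_children

    # genetic components: founders, then mid-parent + segregation for children
    g_parents = rng.multivariate_normal(
        np.zeros(2), config.genetic_cov, size=n_parents, method="svd")
    g_mothers = g_parents[:nfam]
    g_fathers = g_parents[nfam:]
    midparent = 0.5 * (g_mothers + g_fathers)
    seg = rng.multivariate_normal(
        np.zeros(2), 0.5 * config.genetic_cov, size=n_children, method="svd")
    g_children = np.repeat(midparent, nchild, axis=0) + seg
    g = np.vstack([g_parents, g_children])

    e = rng.multivariate_normal(
        np.zeros(2), config.environmental_cov, size=n, method="svd")
    liab = g + e

    thr_c = norm.isf(config.disorder_c.K)
    thr_f = norm.isf(config.disorder_f.K)
    affected = np.column_stack([liab[:, 0] > thr_c, liab[:, 1] > thr_f])

    # demography
    year_lo, year_hi = config.birth_year_range
    child_years = rng.integers(year_lo, year_hi + 1, size=n_children)
    fam_min_year = np.minimum.reduceat(
        child_years, np.arange(0, n_children, nchild))
    parent_offset = rng.integers(20, 36, size=n_parents)
    parent_years = np.concatenate([fam_min_year, fam_min_year]) - parent_offset
    birth_year = np.concatenate([parent_years, child_years])
    birth_day = rng.integers(0, 365, size=n)
    birth_date = (pd.to_datetime(birth_year.astype(str) + "-01-01")
                  + pd.to_timedelta(birth_day, unit="D"))

    study_end = pd.Timestamp(config.study_end)
    admin_age = (study_end - birth_date) / pd.Timedelta(days=365.25)
    death_age = _exponential_or_inf(rng, config.death_hazard, n)
    emig_age = _exponential_or_inf(rng, config.emigration_hazard, n)

    death_recorded = (death_age <= emig_age) & (death_age <= admin_age)
    emig_recorded = (emig_age < death_age) & (emig_age <= admin_age)
    end_age = np.minimum(np.minimum(death_age, emig_age), admin_age.to_numpy())

    person_id = np.arange(1, n + 1).astype(str)
    mother_id = np.concatenate([
        np.full(n_parents, None, dtype=object),
        np.repeat(person_id[:nfam], nchild),
    ])
    father_id = np.concatenate([
        np.full(n_parents, None, dtype=object),
        np.repeat(person_id[nfam:n_parents], nchild),
    ])
    sex = np.concatenate([
        np.repeat("female", nfam), np.repeat("male", nfam),
        rng.choice(["female", "male"], size=n_children),
    ])

    def _date_or_nat(age_years, mask):
        out = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
        days = np.round(age_years[mask] * 365.25).astype(int)
        out[np.flatnonzero(mask)] = (
            birth_date[np.flatnonzero(mask)] + pd.to_timedelta(days, unit="D"))
        return out

    persons = pd.DataFrame({
        "person_id": person_id,
        "sex": sex,
        "birth_date": birth_date,
        "death_date": _date_or_nat(death_age, death_recorded).to_numpy(),
        "emigration_date": _date_or_nat(emig_age, emig_recorded).to_numpy(),
        "mother_id": mother_id,
        "father_id": father_id,
        "born_in_country": True,
    })

    # diagnoses: onset independent of liability magnitude given affection
    pieces = []
    for col, spec in ((0, config.disorder_c), (1, config.disorder_f)):
        idx = np.flatnonzero(affected[:, col])
        onset = _truncated_logistic(rng, spec.onset_location, spec.onset_scale,
                                    config.onset_max_age, idx.size)
        observed = onset < end_age[idx]
        idx, onset = idx[observed], onset[observed]
        days = np.round(onset * 365.25).astype(int)
        prefixes = sorted(catalog.prefixes(spec.label, 10))
        if not prefixes:
            raise ValueError(f"catalogue has no ICD-10 prefixes for {spec.label!r}")
        pieces.append(pd.DataFrame({
            "person_id": person_id[idx],
            "icd_version": 10,
            "code": prefixes[0],
            "date": birth_date[idx] + pd.to_timedelta(days, unit="D"),
        }))
    diagnoses = pd.concat(pieces, ignore_index=True)
    diagnoses = diagnoses.sort_values(
        ["person_id", "code", "date"], kind="stable").reset_index(drop=True)

    truth = {
        "config": _jsonable(config.to_dict()),
        "thresholds": {"c": float(thr_c), "f": float(thr_f)},
        "n_persons": int(n),
        "n_affected_c": int(affected[:, 0].sum()),
        "n_affected_f": int(affected[:, 1].sum()),
    }
    return persons, diagnoses, truth


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# --------------------------------------------------------------------------
# Packaged scenarios

def _tiny_handcheck() -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Four persons with hand-enumerable follow-up for the worked
    competing-risks example: one onset at ~age 1, one death at ~age 2,
    one emigration at ~age 3, one onset at ~age 4; study end at age ~6."""
    birth = pd.Timestamp("1990-01-01")
    persons = pd.DataFrame({
        "person_id": ["1", "2", "3", "4"],
        "sex": ["female", "male", "female", "male"],
        "birth_date": [birth] * 4,
        "death_date": [pd.NaT, pd.Timestamp("1992-01-01"), pd.NaT, pd.NaT],
        "emigration_date": [pd.NaT, pd.NaT, pd.Timestamp("1993-01-01"), pd.NaT],
        "mother_id": [None] * 4,
        "father_id": [None] * 4,
        "born_in_country": True,
    })
    diagnoses = pd.DataFrame({
        "person_id": ["1", "4"],
        "icd_version": [10, 10],
        "code": ["F900", "F900"],
        "date": [pd.Timestamp("1991-01-01"), pd.Timestamp("1994-01-01")],
    })
    truth = {"scenario": "tiny_handcheck", "expected_final_cif": 0.75,
             "study_end": "1996-01-01", "birth_year_range": [1990, 1990]}
    return persons, diagnoses, truth


SCENARIOS: dict[str, SimulationConfig | None] = {
    "null_model": SimulationConfig(n_families=3000, rg=0.0, re=0.0, seed=20230101),
    "moderate_rg": SimulationConfig(n_families=3000, seed=20230102),
    "high_h2": SimulationConfig(
        n_families=3000,
        disorder_c=DisorderSpec("SCZ", K=0.05, h2=0.8,
                                onset_location=23.0, onset_scale=3.0),
        disorder_f=DisorderSpec("T2D", K=0.05, h2=0.8,
                                onset_location=26.0, onset_scale=4.0),
        rg=0.5, re=0.1, seed=20230103),
    "tiny_handcheck": None,
}


def make_fixture(scenario: str, out_dir,
                 n_families: int | None = None) -> dict:
    """Write a seed-fixed registry bundle (persons.tsv, diagnoses.tsv,
    truth.json) for a packaged scenario; returns the truth record."""
    if scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; available: {sorted(SCENARIOS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if scenario == "tiny_handcheck":
        persons, diagnoses, truth = _tiny_handcheck()
    else:
        config = SCENARIOS[scenario]
        if n_families is not None:
            config = dataclasses.replace(config, n_families=n_families)
        persons, diagnoses, truth = simulate_registry(config)
        truth["scenario"] = scenario
    write_registry(persons, diagnoses, out / "persons.tsv", out / "diagnoses.tsv")
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
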