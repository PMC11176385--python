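"""Birth-year-stratified cumulative incidence under right censoring and
competing risks, and lifetime-risk extraction.

Follow-up runs from birth to the first of disorder onset (the event of
interest), death (the competing event), emigration or the administrative
study end (censoring).  The cumulative incidence function is the
Aalen-Johansen estimator: at each distinct event age a the CIF increments
by S(a-) d1(a) / n(a), with S the all-cause Kaplan-Meier survivor.
Pointwise variance uses the standard counting-process (delta-method)
estimator.  Lifetime risk is the CIF at the last observed age, taken as
the proportion of the birth cohort ever affected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import Cohort, PedigreeIndex, age_in_years

logger = logging.getLogger(__name__)

EVENT = "event_of_interest"
COMPETING = "competing_event"
CENSORED = "censored"

__all__ = [
    "EVENT", "COMPETING", "CENSORED", "CIFCurve", "LifetimeRisk",
    "build_event_histories", "estimate_cif", "lifetime_risk_from_cif",
    "conditional_cohort",
]


@dataclass(frozen=True)
class CIFCurve:
    """One stratum's cumulative incidence curve on its event-age grid."""

    stratum: int | None
    ages: np.ndarray
    cif: np.ndarray
    se: np.ndarray
    n_at_risk: np.ndarray
    n: int
    n_events: int
    flagged: bool  # True when the stratum has no events of interest


@dataclass(frozen=True)
class LifetimeRisk:
    """Lifetime risk: the CIF and its standard error at the last observed age."""

    K: float
    se: float
    stratum: int | None
    n: int
    flagged: bool = False


def build_event_histories(
    cohort: Cohort,
    persons: pd.DataFrame,
    mapped_events: pd.DataFrame,
    disorder: str,
) -> pd.DataFrame:
    """One follow-up record per cohort member for one disorder.

    Returns a DataFrame with person_id, birth_year, entry (0), exit (age in
    years) and reason (event_of_interest / competing_event / censored).
    Exit is the earliest of onset, death, emigration and study end; ties
    resolve in that order.  Onsets before birth raise; members whose
    follow-up has non-positive length (born at or after study end) are
    dropped with a logged count.
    """
    sub = persons[persons["person_id"].isin(cohort.person_ids)].copy()
    onsets = mapped_events[mapped_events["disorder"] == disorder]
    sub = sub.merge(
        onsets[["person_id", "date"]].rename(columns={"date": "onset_date"}),
        on="person_id", how="left",
    )
    birth = sub["birth_date"]
    onset_age = age_in_years(sub["onset_date"], birth)
    if (onset_age < 0).any():
        bad = sub.loc[onset_age < 0, "person_id"].iloc[0]
        raise ValueError(f"onset before birth for person {bad!r}")
    death_age = age_in_years(sub["death_date"], birth)
    emig_age = age_in_years(sub["emigration_date"], birth)
    admin_age = age_in_years(cohort.study_end, birth)

    ages = np.vstack([
        onset_age.to_numpy(dtype=float),
        death_age.to_numpy(dtype=float),
        np.fmin(emig_age.to_numpy(dtype=float), admin_age.to_numpy(dtype=float)),
    ])
    ages = np.where(np.isnan(ages), np.inf, ages)
    # ties resolve by row order: onset beats death beats censoring
    which = np.argmin(ages, axis=0)
    exit_age = ages[which, np.arange(ages.shape[1])]
    reason = np.array([EVENT, COMPETING, CENSORED], dtype=object)[which]

    histories = pd.DataFrame({
        "person_id": sub["person_id"].to_numpy(),
        "birth_year": birth.dt.year.to_numpy(),
        "entry": 0.0,
        "exit": exit_age,
        "reason": reason,
    })
    ok = np.isfinite(exit_age) & (exit_age > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("build_event_histories(%s): dropped %d record(s) with "
                    "non-positive follow-up", disorder, n_dropped)
    return histories[ok].reset_index(drop=True)


def _aalen_johansen(exit_age: np.ndarray, reason: np.ndarray, stratum) -> CIFCurve:
    n = exit_age.size
    ages, inverse = np.unique(exit_age, return_inverse=True)
    m = ages.size
    is_event = reason == EVENT
    is_competing = reason == COMPETING
    d1 = np.bincount(inverse, weights=is_event.astype(float), minlength=m)
    d2 = np.bincount(inverse, weights=is_competing.astype(float), minlength=m)
    total = np.bincount(inverse, minlength=m).astype(float)
    # half-open risk intervals: a person with exit == a is still at risk at a
    n_at_risk = n - np.concatenate(([0.0], np.cumsum(total)[:-1]))
    d = d1 + d2
    with np.errstate(divide="ignore", invalid="ignore"):
        km_factors = 1.0 - d / n_at_risk
    surv = np.cumprod(km_factors)
    surv_prev = np.concatenate(([1.0], surv[:-1]))
    inc = surv_prev * d1 / n_at_risk
    cif = np.cumsum(inc)

    # delta-method pointwise variance (Marubini-Valsecchi form), via cumsums
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), 0.0)
    a = np.cumsum(rho)
    b = np.cumsum(cif * rho)
    c = np.cumsum(cif**2 * rho)
    t2 = np.cumsum(surv_prev**2 * d1 * (n_at_risk - d1) / n_at_risk**3)
    sd = np.cumsum(surv_prev * d1 / n_at_risk**2)
    fsd = np.cumsum(cif * surv_prev * d1 / n_at_risk**2)
    var = cif**2 * a - 2.0 * cif * b + c + t2 - 2.0 * (cif * sd - fsd)
    var = np.clip(var, 0.0, None)

    n_events = int(d1.sum())
    return CIFCurve(
        stratum=stratum, ages=ages, cif=cif, se=np.sqrt(var),
        n_at_risk=n_at_risk.astype(int), n=n, n_events=n_events,
        flagged=(n_events == 0),
    )


def estimate_cif(histories: pd.DataFrame, stratify_by_birth_year: bool = False
                 ) -> list[CIFCurve]:
    """Aalen-Johansen CIF of the event of interest, optionally per birth year.

    Strata with no events of interest yield a flat zero curve flagged for
    downstream skipping.  Raises on empty input.
    """
    if len(histories) == 0:
        raise ValueError("no event histories supplied")
    if stratify_by_birth_year:
        groups = [(int(year), grp) for year, grp in
                  histories.groupby("birth_year", sort=True)]
    else:
        groups = [(None, histories)]
    curves = []
    for stratum, grp in groups:
        curves.append(_aalen_johansen(
            grp["exit"].to_numpy(dtype=float),
            grp["reason"].to_numpy(dtype=object),
            stratum,
        ))
    return curves


def lifetime_risk_from_cif(curve: CIFCurve) -> LifetimeRisk:
    """Lifetime risk = CIF at the largest observed age (se likewise)."""
    if curve.ages.size == 0:
        raise ValueError("empty CIF curve")
    return LifetimeRisk(
        K=float(curve.cif[-1]), se=float(curve.se[-1]),
        stratum=curve.stratum, n=curve.n, flagged=curve.flagged,
    )


def conditional_cohort(
    cohort: Cohort,
    pedigree: PedigreeIndex,
    relationship: str,
    conditioning_disorder: str,
    mapped_events: pd.DataFrame,
) -> Cohort:
    """Members with >= 1 relative of the given kind diagnosed with the
    conditioning disorder (relatives assessed over their full observed
    history).

    ``relationship`` is ``"full_sibling"`` or ``"parent"``.
    """
    affected = set(
        mapped_events.loc[mapped_events["disorder"] == conditioning_disorder,
                          "person_id"]
    )
    if relationship == "full_sibling":
        sib = pedigree.sibships
        flag = sib["person_id"].isin(affected)
        counts = flag.groupby(sib["sibship"]).transform("sum")
        others = counts - flag.astype(int)
        selected = set(sib.loc[others >= 1, "person_id"])
    elif relationship == "parent":
        pc = pedigree.parent_child
        selected = set(pc.loc[pc["parent_id"].isin(affected), "child_id"])
    else:
        raise ValueError(
            f"relationship must be 'full_sibling' or 'parent'; got {relationship!r}"
        )
    return Cohort(
        person_ids=frozenset(selected & cohort.person_ids),
        study_end=cohort.study_end,
        birth_year_range=cohort.birth_year_range,
    )
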