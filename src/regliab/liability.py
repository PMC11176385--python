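"""Normal-theory liability computations.

The liability-threshold model assumes each disorder reflects a latent
standard-normal liability Z; a person is affected iff Z exceeds the
threshold T = Phi^-1(1 - K), where K is the lifetime risk.  Familial
recurrence risks (the lifetime risk among people with an affected
relative) then identify the additive heritability h2 and, across two
disorders, the genetic correlation r_g, via the classical
Reich-Falconer normal-theory approximation.

All quantiles and densities are evaluated at double precision with
scipy's normal distribution; no series approximations are used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "LiabilityDomainError",
    "LiabilityParams",
    "HeritabilityEstimate",
    "GeneticCorrelationEstimate",
    "liability_params",
    "heritability",
    "genetic_correlation",
    "per_year_heritability",
    "per_year_genetic_correlation",
]


class LiabilityDomainError(ValueError):
    """Raised when inputs leave the domain of the liability formulas."""


@dataclass(frozen=True)
class LiabilityParams:
    """Normal-theory quantities implied by a lifetime risk K.

    Attributes
    ----------
    K : lifetime risk, in (0, 1).
    T : liability threshold, Phi^-1(1 - K), in SD units.
    y : standard-normal density height at T.
    i : mean liability of affected individuals, y / K
        (the selection intensity of the affected tail).
    """

    K: float
    T: float
    y: float
    i: float


@dataclass(frozen=True)
class HeritabilityEstimate:
    """Liability-scale heritability from a familial recurrence risk."""

    h2: float
    se: float
    K: float
    K_R: float
    a_R: float
    disorder: str | None = None
    birth_year: int | None = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class GeneticCorrelationEstimate:
    """Liability-scale genetic correlation from a cross-disorder familial risk.

    ``r_cf_plugin`` records the co-heritability correlation value substituted
    into the standard-error formula (the point estimate of rg itself).
    """

    rg: float
    se: float
    K_c: float
    K_f: float
    K_Rc: float
    h_c2: float
    h_f2: float
    a_R: float
    r_cf_plugin: float = float("nan")
    disorder_c: str | None = None
    disorder_f: str | None = None
    birth_year: int | None = None
    flags: tuple[str, ...] = ()


def liability_params(K: float) -> LiabilityParams:
    """Threshold T, density height y and affected-mean liability i for risk K.

    Raises
    ------
    LiabilityDomainError
        If K is outside the open interval (0, 1).
    """
    if not (0.0 < K < 1.0):
        raise LiabilityDomainError(f"lifetime risk K must be in (0, 1); got {K!r}")
    T = float(norm.isf(K))
    y = float(norm.pdf(T))
    return LiabilityParams(K=float(K), T=T, y=y, i=y / K)


def heritability(
    K: float,
    K_R: float,
    a_R: float,
    *,
    disorder: str | None = None,
    birth_year: int | None = None,
) -> HeritabilityEstimate:
    """Liability-scale h2 from population risk K and relative risk K_R.

    Uses the normal-theory approximation

        h2 = [T - T_R sqrt(1 - (1 - T/i)(T^2 - T_R^2))]
             / [a_R (i + (i - T) T_R^2)]

    with T, i from ``liability_params(K)`` and T_R from
    ``liability_params(K_R)``.  The standard error is

        se = (1/a_R) sqrt[ (K^2/y^2)(1/i - a_R h2 (i - T))^2
                           + K_R^2 / (i^2 y_R^2) ].

    Estimates outside [0, 1] are returned unclamped with a warning flag,
    so that downstream pooling across strata stays unbiased.
    """
    if a_R <= 0:
        raise LiabilityDomainError(f"relationship coefficient a_R must be > 0; got {a_R!r}")
    pop = liability_params(K)
    rel = liability_params(K_R)
    T, y, i = pop.T, pop.y, pop.i
    T_R, y_R = rel.T, rel.y

    radicand = 1.0 - (1.0 - T / i) * (T * T - T_R * T_R)
    if radicand < 0.0:
        raise LiabilityDomainError(
            "negative radicand in heritability formula for "
            f"K={K!r}, K_R={K_R!r}, a_R={a_R!r}"
        )
    h2 = (T - T_R * math.sqrt(radicand)) / (a_R * (i + (i - T) * T_R * T_R))
    se = (1.0 / a_R) * math.sqrt(
        (K * K / (y * y)) * (1.0 / i - a_R * h2 * (i - T)) ** 2
        + K_R * K_R / (i * i * y_R * y_R)
    )

    flags: list[str] = []
    if h2 < 0.0:
        flags.append("negative_h2")
        logger.warning("h2 estimate %.4f < 0 for K=%g, K_R=%g", h2, K, K_R)
    elif h2 > 1.0:
        flags.append("h2_above_1")
    return HeritabilityEstimate(
        h2=h2, se=se, K=float(K), K_R=float(K_R), a_R=float(a_R),
        disorder=disorder, birth_year=birth_year, flags=tuple(flags),
    )


def genetic_correlation(
    K_c: float,
    K_f: float,
    K_Rc: float,
    h_c2: float,
    h_f2: float,
    a_R: float,
    *,
    i_convention: str = "i_c",
    radicand_threshold: str = "T_c",
    disorder_c: str | None = None,
    disorder_f: str | None = None,
    birth_year: int | None = None,
) -> GeneticCorrelationEstimate:
    """Liability-scale genetic correlation between disorders c and f.

    ``K_Rc`` is the lifetime risk of disorder c among individuals with a
    relative affected by disorder f.  Selection on the relative's
    f-liability leaves the proband's c-liability normal with mean
    rho * i_f and variance 1 - rho^2 i_f (i_f - T_f), rho being the
    cross-relative cross-trait liability correlation a_R rg h_c h_f;
    solving T_c - rho i_f = T_Rc * sd for rho gives

        rho = [T_c - T_Rc sqrt(1 - (1 - T_f/i_f)(T_c^2 - T_Rc^2))]
              / [i_f + (i_f - T_f) T_Rc^2]

    and rg = rho / (a_R sqrt(h_c2 h_f2)).  ``radicand_threshold`` selects
    which population threshold enters the radicand difference with T_Rc:
    ``"T_c"`` (the default; the proband disorder, as the derivation above
    and the single-disorder formula require, making rg vanish exactly at
    K_Rc = K_c) or ``"T_f"`` (a published variant that agrees only when
    K_c = K_f).

    The standard-error formula contains a bare mean-liability ratio whose
    numerator is ambiguous in the source derivation; ``i_convention``
    selects ``"i_c"`` (mean liability of disorder c, the default and the
    analogue of the single-disorder formula) or ``"i_f"`` (making the ratio
    1 identically).  The co-heritability correlation appearing in the
    standard error is substituted with the rg point estimate.
    """
    if a_R <= 0:
        raise LiabilityDomainError(f"relationship coefficient a_R must be > 0; got {a_R!r}")
    if h_c2 * h_f2 <= 0:
        raise LiabilityDomainError(
            f"h_c2 * h_f2 must be > 0 to identify rg; got h_c2={h_c2!r}, h_f2={h_f2!r}"
        )
    if i_convention not in ("i_c", "i_f"):
        raise ValueError(f"i_convention must be 'i_c' or 'i_f'; got {i_convention!r}")
    if radicand_threshold not in ("T_c", "T_f"):
        raise ValueError(
            f"radicand_threshold must be 'T_c' or 'T_f'; got {radicand_threshold!r}")

    pc = liability_params(K_c)
    pf = liability_params(K_f)
    pRc = liability_params(K_Rc)
    T_c, y_c, i_c = pc.T, pc.y, pc.i
    T_f, y_f, i_f = pf.T, pf.y, pf.i
    T_Rc, y_Rc = pRc.T, pRc.y

    T_num = T_c if radicand_threshold == "T_c" else T_f
    radicand = 1.0 - (1.0 - T_f / i_f) * (T_num * T_num - T_Rc * T_Rc)
    if radicand < 0.0:
        raise LiabilityDomainError(
            "negative radicand in genetic-correlation formula for "
            f"K_c={K_c!r}, K_f={K_f!r}, K_Rc={K_Rc!r}"
        )
    hh = math.sqrt(h_c2 * h_f2)
    # covariance-scale numerator: a_R * rg * h_c * h_f
    cov_term = (T_c - T_Rc * math.sqrt(radicand)) / (
        a_R * (i_f + (i_f - T_f) * T_Rc * T_Rc)
    )
    rg = cov_term / hh

    r_cf = rg
    i_num = i_c if i_convention == "i_c" else i_f
    h_c = math.sqrt(h_c2)
    h_f = math.sqrt(h_f2)
    se_num = (1.0 / a_R) * math.sqrt(
        (K_f * K_f / (y_f * y_f))
        * (i_num / i_f - a_R * r_cf * h_c * h_f * (i_f - T_f)) ** 2
        + (1.0 / (i_f * i_f))
        * (K_Rc * K_Rc / (y_Rc * y_Rc) + K_c * K_c / (y_c * y_c))
    )
    se = se_num / hh

    flags: list[str] = []
    if abs(rg) > 1.0:
        flags.append("rg_outside_unit")
        logger.warning("rg estimate %.4f outside [-1, 1] for K_Rc=%g", rg, K_Rc)
    return GeneticCorrelationEstimate(
        rg=rg, se=se, K_c=float(K_c), K_f=float(K_f), K_Rc=float(K_Rc),
        h_c2=float(h_c2), h_f2=float(h_f2), a_R=float(a_R), r_cf_plugin=r_cf,
        disorder_c=disorder_c, disorder_f=disorder_f, birth_year=birth_year,
        flags=tuple(flags),
    )


def _usable(risk) -> bool:
    """A per-stratum lifetime risk usable for threshold estimation."""
    return (not getattr(risk, "flagged", False)) and 0.0 < risk.K < 1.0


def per_year_heritability(
    population_risks: Mapping[int, "LifetimeRisk"],
    relative_risks: Mapping[int, "LifetimeRisk"],
    a_R: float,
    *,
    disorder: str | None = None,
) -> list[HeritabilityEstimate]:
    """One heritability estimate per birth-year stratum.

    Strata flagged upstream (zero events), with risks outside (0, 1), or
    missing from either series are skipped with a logged reason; a formula
    domain failure in a single stratum likewise skips that stratum.
    """
    years = sorted(set(population_risks) & set(relative_risks))
    if not years:
        raise ValueError("no overlapping birth-year strata between the two series")
    for year in sorted(set(population_risks) ^ set(relative_risks)):
        logger.info("stratum %s present in only one series; skipped", year)
    out: list[HeritabilityEstimate] = []
    for year in years:
        pop, rel = population_risks[year], relative_risks[year]
        if not (_usable(pop) and _usable(rel)):
            logger.info("stratum %s skipped: flagged or degenerate lifetime risk", year)
            continue
        try:
            out.append(
                heritability(pop.K, rel.K, a_R, disorder=disorder, birth_year=year)
            )
        except LiabilityDomainError as exc:
            logger.info("stratum %s skipped: %s", year, exc)
    return out


def per_year_genetic_correlation(
    population_risks_c: Mapping[int, "LifetimeRisk"],
    population_risks_f: Mapping[int, "LifetimeRisk"],
    cross_relative_risks: Mapping[int, "LifetimeRisk"],
    h_c2: float,
    h_f2: float,
    a_R: float,
    *,
    i_convention: str = "i_c",
    disorder_c: str | None = None,
    disorder_f: str | None = None,
) -> list[GeneticCorrelationEstimate]:
    """One genetic-correlation estimate per birth-year stratum.

    ``h_c2`` and ``h_f2`` are the pooled heritabilities obtained beforehand;
    they are held fixed across strata.  Skipping rules mirror
    :func:`per_year_heritability`.
    """
    years = sorted(
        set(population_risks_c) & set(population_risks_f) & set(cross_relative_risks)
    )
    if not years:
        raise ValueError("no overlapping birth-year strata across the three series")
    out: list[GeneticCorrelationEstimate] = []
    for year in years:
        pc, pf, rc = (
            population_risks_c[year],
            population_risks_f[year],
            cross_relative_risks[year],
        )
        if not (_usable(pc) and _usable(pf) and _usable(rc)):
            logger.info("stratum %s skipped: flagged or degenerate lifetime risk", year)
            continue
        try:
            out.append(
                genetic_correlation(
                    pc.K, pf.K, rc.K, h_c2, h_f2, a_R,
                    i_convention=i_convention,
                    disorder_c=disorder_c, disorder_f=disorder_f, birth_year=year,
                )
            )
        except LiabilityDomainError as exc:
            logger.info("stratum %s skipped: %s", year, exc)
    return out
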