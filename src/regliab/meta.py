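"""Random-effects inverse-variance-weighted pooling of stratum estimates.

Per-birth-year (or per-country) estimates are combined with the
DerSimonian-Laird random-effects model: between-stratum variance tau2 is
the truncated moment estimator, weights are 1 / (s_k^2 + tau2), and the
pooled estimate is the weighted mean with se = sqrt(1 / sum of weights).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = ["EstimateSeries", "MetaEstimate", "estimate_tau2", "ivw_random",
           "correlation_significance"]


@dataclass(frozen=True)
class EstimateSeries:
    """An ordered series of stratum point estimates with standard errors."""

    theta: tuple[float, ...]
    se: tuple[float, ...]
    labels: tuple = ()

    def __post_init__(self):
        if len(self.theta) == 0:
            raise ValueError("estimate series is empty")
        if len(self.theta) != len(self.se):
            raise ValueError("theta and se differ in length")
        if any(s <= 0 for s in self.se):
            raise ValueError("all standard errors must be > 0")

    @classmethod
    def from_estimates(cls, estimates: Sequence, *, attr: str = "h2") -> "EstimateSeries":
        """Build from objects exposing ``se`` and a point-estimate attribute."""
        return cls(
            theta=tuple(float(getattr(e, attr)) for e in estimates),
            se=tuple(float(e.se) for e in estimates),
            labels=tuple(getattr(e, "birth_year", None) for e in estimates),
        )


@dataclass(frozen=True)
class MetaEstimate:
    """Pooled random-effects estimate."""

    theta: float
    se: float
    tau2: float
    k_used: int
    z: float
    p: float
    significant: bool | None = None
    alpha_adjusted: float | None = None

    @property
    def ci(self) -> tuple[float, float]:
        """Wald 95% interval, estimate +/- 1.96 se."""
        return (self.theta - 1.96 * self.se, self.theta + 1.96 * self.se)


def estimate_tau2(series: EstimateSeries) -> float:
    """DerSimonian-Laird moment estimate of the between-stratum variance.

    tau2 = max(0, (Q - (k - 1)) / C) with Q the fixed-effect heterogeneity
    statistic and C = sum(w) - sum(w^2)/sum(w), w = 1/s^2.  A single-element
    series returns 0 by convention.
    """
    theta = np.asarray(series.theta, dtype=float)
    se = np.asarray(series.se, dtype=float)
    k = theta.size
    if k < 2:
        return 0.0
    w = 1.0 / se**2
    theta_fixed = float(np.sum(w * theta) / np.sum(w))
    Q = float(np.sum(w * (theta - theta_fixed) ** 2))
    C = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if C <= 0:
        return 0.0
    return max(0.0, (Q - (k - 1)) / C)


def ivw_random(series: EstimateSeries, *, tau2: float | None = None) -> MetaEstimate:
    """Pooled estimate under the random-effects IVW model.

    ``tau2`` may be supplied (e.g. forced to 0 for the fixed-effect result);
    by default it is estimated with :func:`estimate_tau2`.
    """
    theta = np.asarray(series.theta, dtype=float)
    se = np.asarray(series.se, dtype=float)
    if tau2 is None:
        tau2 = estimate_tau2(series)
    w = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(math.sqrt(1.0 / np.sum(w)))
    z = pooled / pooled_se
    p = float(2.0 * norm.sf(abs(z)))
    return MetaEstimate(theta=pooled, se=pooled_se, tau2=float(tau2),
                        k_used=theta.size, z=z, p=p)


def correlation_significance(meta: MetaEstimate, alpha: float, m_tests: int) -> MetaEstimate:
    """Annotate a pooled estimate with Bonferroni-adjusted significance.

    The estimate is significant iff p < alpha / m_tests (strict inequality);
    ``m_tests`` is an explicit parameter and never inferred.
    """
    if m_tests < 1:
        raise ValueError(f"m_tests must be >= 1; got {m_tests!r}")
    threshold = alpha / m_tests
    return replace(meta, significant=bool(meta.p < threshold),
                   alpha_adjusted=threshold)
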