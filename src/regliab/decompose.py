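"""Comorbidity decomposition: hazard ratios to phenotypic correlations to G + E.

A published hazard ratio for disorder f given prior disorder c is converted
to a relative risk using the outcome's lifetime risk in the reference group,
to an odds ratio by 2x2 algebra, and to a tetrachoric-scale phenotypic
correlation r_p with the OR^(pi/4) approximation.  Under a bivariate
liability-threshold model r_p then splits exactly into a genetic component
G = rg * sqrt(h_c2 * h_f2) and a non-genetic remainder E = r_p - G, with
the environmental correlation r_e = E / sqrt((1 - h_c2)(1 - h_f2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = [
    "ComorbidityInputs", "DecompositionResult",
    "hr_to_rr", "rr_to_or", "or_to_rp", "decompose_rp",
    "decomposition_intervals",
]


@dataclass(frozen=True)
class ComorbidityInputs:
    """Inputs for one disorder pair's decomposition.

    ``r`` is the lifetime risk of the outcome disorder in the reference
    group (an IVW-pooled value supplied by the caller, never recomputed
    here); heritabilities are treated as fixed.
    """

    hr: float
    hr_lo: float
    hr_hi: float
    r: float
    rg: float
    rg_lo: float
    rg_hi: float
    h_c2: float
    h_f2: float
    pair: tuple[str, str] | None = None

    def __post_init__(self):
        if not (self.hr_lo <= self.hr <= self.hr_hi):
            raise ValueError(f"HR CI not ordered: {self.hr_lo}, {self.hr}, {self.hr_hi}")
        if not (self.rg_lo <= self.rg <= self.rg_hi):
            raise ValueError(f"rg CI not ordered: {self.rg_lo}, {self.rg}, {self.rg_hi}")
        if not (0.0 < self.r < 1.0):
            raise ValueError(f"reference-group risk r must be in (0, 1); got {self.r!r}")


@dataclass(frozen=True)
class DecompositionResult:
    """HR -> RR -> OR -> r_p chain plus the G/E split with 95% intervals."""

    rr: float
    odds_ratio: float
    rp: float
    rp_lo: float
    rp_hi: float
    g: float
    g_lo: float
    g_hi: float
    e: float
    e_lo: float
    e_hi: float
    re: float
    pair: tuple[str, str] | None = None
    flags: tuple[str, ...] = ()


def hr_to_rr(hr: float, r: float) -> float:
    """Relative risk implied by a hazard ratio at outcome risk r.

    RR = (1 - exp(HR * log(1 - r))) / r = (1 - (1 - r)^HR) / r.
    As r -> 0 the RR tends to the HR, but r = 0 itself is rejected rather
    than silently substituting that limit.
    """
    if hr <= 0:
        raise ValueError(f"hazard ratio must be > 0; got {hr!r}")
    if not (0.0 < r < 1.0):
        raise ValueError(f"reference risk r must be in (0, 1); got {r!r}")
    return (1.0 - math.exp(hr * math.log1p(-r))) / r


def rr_to_or(rr: float, p: float) -> float:
    """Odds ratio from a relative risk at nonexposed incidence p.

    OR = (1 - p) RR / (1 - RR p); requires RR * p < 1 (exposed risk < 1).
    """
    if rr <= 0:
        raise ValueError(f"relative risk must be > 0; got {rr!r}")
    if not (0.0 < p < 1.0):
        raise ValueError(f"incidence p must be in (0, 1); got {p!r}")
    if rr * p >= 1.0:
        raise ValueError(f"RR * p = {rr * p!r} >= 1: exposed risk would reach 1")
    return (1.0 - p) * rr / (1.0 - rr * p)


def or_to_rp(odds_ratio: float) -> float:
    """Tetrachoric-correlation approximation from an odds ratio.

    r_p = (OR^(pi/4) - 1) / (OR^(pi/4) + 1); OR = 0 maps to -1.
    """
    if odds_ratio < 0:
        raise ValueError(f"odds ratio must be >= 0; got {odds_ratio!r}")
    q = odds_ratio ** (math.pi / 4.0)
    return (q - 1.0) / (q + 1.0)


def decompose_rp(
    rp: float, rg: float, h_c2: float, h_f2: float
) -> tuple[float, float, float]:
    """Split a phenotypic correlation into (G, E, re).

    G = rg sqrt(h_c2 h_f2), E = rp - G (exact by construction), and
    re = E / sqrt((1 - h_c2)(1 - h_f2)).  With h2 = 1 on either trait the
    environmental variance vanishes and re is returned as NaN.
    """
    if h_c2 < 0 or h_f2 < 0 or h_c2 > 1 or h_f2 > 1:
        raise ValueError(f"heritabilities must lie in [0, 1]; got {h_c2!r}, {h_f2!r}")
    g = rg * math.sqrt(h_c2 * h_f2)
    e = rp - g
    env_var = (1.0 - h_c2) * (1.0 - h_f2)
    re = e / math.sqrt(env_var) if env_var > 0 else float("nan")
    return g, e, re


def decomposition_intervals(inputs: ComorbidityInputs) -> DecompositionResult:
    """Full decomposition with conservative interval arithmetic for the CIs.

    The r_p interval pushes the HR bounds through the monotone
    HR -> RR -> OR -> r_p chain; the G interval rescales the rg bounds by
    sqrt(h_c2 h_f2) (order-corrected for negative values); the E interval
    is [rp_lo - g_hi, rp_hi - g_lo].  Heritabilities carry no uncertainty.
    """
    rr = hr_to_rr(inputs.hr, inputs.r)
    odds = rr_to_or(rr, inputs.r)
    rp = or_to_rp(odds)
    rp_bounds = sorted(
        or_to_rp(rr_to_or(hr_to_rr(h, inputs.r), inputs.r))
        for h in (inputs.hr_lo, inputs.hr_hi)
    )
    g, e, re = decompose_rp(rp, inputs.rg, inputs.h_c2, inputs.h_f2)
    scale = math.sqrt(inputs.h_c2 * inputs.h_f2)
    g_bounds = sorted((inputs.rg_lo * scale, inputs.rg_hi * scale))
    e_lo = rp_bounds[0] - g_bounds[1]
    e_hi = rp_bounds[1] - g_bounds[0]
    flags = ("re_undefined",) if math.isnan(re) else ()
    return DecompositionResult(
        rr=rr, odds_ratio=odds, rp=rp, rp_lo=rp_bounds[0], rp_hi=rp_bounds[1],
        g=g, g_lo=g_bounds[0], g_hi=g_bounds[1], e=e, e_lo=e_lo, e_hi=e_hi,
        re=re, pair=inputs.pair, flags=flags,
    )


def decomposition_delta(inputs: ComorbidityInputs) -> dict:
    """Delta-method alternative to the interval arithmetic (optional variant).

    Treats log HR and rg as normal with SEs recovered from their 95% CIs,
    propagates var(rp) via the derivative of the monotone chain and
    var(G) = var(rg) * h_c2 * h_f2, and reports z-scores and two-sided
    p-values for G and E under an independence assumption.  Labelled as a
    variant because the interval-arithmetic form is the primary output.
    """
    rr = hr_to_rr(inputs.hr, inputs.r)
    odds = rr_to_or(rr, inputs.r)
    rp = or_to_rp(odds)
    g, e, re = decompose_rp(rp, inputs.rg, inputs.h_c2, inputs.h_f2)

    se_log_hr = (math.log(inputs.hr_hi) - math.log(inputs.hr_lo)) / (2 * 1.96)
    # d rp / d log HR by finite difference on the smooth monotone chain
    eps = 1e-6
    hr_up = inputs.hr * math.exp(eps)
    rp_up = or_to_rp(rr_to_or(hr_to_rr(hr_up, inputs.r), inputs.r))
    drp = (rp_up - rp) / eps
    var_rp = (drp * se_log_hr) ** 2
    se_rg = (inputs.rg_hi - inputs.rg_lo) / (2 * 1.96)
    var_g = se_rg**2 * inputs.h_c2 * inputs.h_f2
    var_e = var_rp + var_g
    out = {}
    for name, value, var in (("g", g, var_g), ("e", e, var_e), ("rp", rp, var_rp)):
        se = math.sqrt(var)
        z = value / se if se > 0 else float("inf") if value else 0.0
        out[name] = {"estimate": value, "se": se, "z": z,
                     "p": float(2.0 * norm.sf(abs(z)))}
    out["re"] = re
    return out
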