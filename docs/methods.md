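# Methods

`regliab` estimates liability-scale heritability (h²) and genetic
correlation (r_g) from familial recurrence risks observed in
register-shaped data, and decomposes the phenotypic correlation between a
mental disorder (labelled c) and a cardiometabolic disorder (labelled f)
into a genetic component G and a non-genetic remainder E. This note
records the model, the estimation procedure, the defaults and the
numerical choices, and what the synthetic-registry validation does and
does not establish.

## Liability-threshold model

Each disorder is modelled by a latent liability Z ~ N(0, 1); a person is
affected iff Z > T, where T = Φ⁻¹(1 − K) and K is the lifetime risk.
Derived quantities: y = φ(T), the normal density at the threshold, and
i = y/K, the mean liability of the affected tail (the selection
intensity). All quantiles and densities are computed with scipy's normal
distribution at double precision; no series approximations are used.

### Heritability from familial recurrence

For a relative pair with additive genetic relationship a_R (½ for full
siblings and for parent–offspring), liabilities are bivariate normal with
correlation a_R·h². Conditioning on an affected relative shifts the
index person's conditional liability mean to a_R·h²·i and reduces its
variance by the usual selection algebra. Solving the resulting threshold
equation for h² gives the classical normal-theory estimator

    h² = [T − T_R √(1 − (1 − T/i)(T² − T_R²))] / [a_R (i + (i − T) T_R²)]

with T_R the threshold implied by the relatives' recurrence risk K_R.
The standard error is computed from the closed form

    se(h²) = (1/a_R) √[ (K²/y²)(1/i − a_R h²(i − T))² + K_R²/(i² y_R²) ]

implemented exactly as written. Note this expression contains no sample
size: it is insensitive to the number of individuals behind K̂ and K̂_R
and is, in our simulations, conservative (larger than the empirical
sampling variability of per-year estimates by roughly an order of
magnitude at register scale). Because all birth-year strata then receive
near-equal weights, the pooled point estimate is essentially the
unweighted mean of per-year estimates and is unaffected; pooled
uncertainty statements inherit the conservatism. A parametric-bootstrap
check of this behaviour is easy to run with the simulator but is not part
of the strict test suite.

### Genetic correlation from cross-disorder recurrence

Let K_Rc be the risk of disorder c among individuals with a relative
affected by disorder f. The cross-relative, cross-trait liability
correlation is ρ = a_R·r_g·h_c·h_f. Selection on the relative's
f-liability leaves the proband's c-liability normal with mean ρ·i_f and
variance 1 − ρ²·i_f(i_f − T_f); solving T_c − ρ·i_f = T_Rc·sd for ρ
yields

    ρ = [T_c − T_Rc √(1 − (1 − T_f/i_f)(T_c² − T_Rc²))]
        / [i_f + (i_f − T_f) T_Rc²],       r_g = ρ / (a_R √(h_c² h_f²)).

A published variant of this formula writes T_f² rather than T_c² inside
the radicand. The two agree exactly when K_c = K_f, but only the T_c²
form satisfies the null identity r_g = 0 at K_Rc = K_c for unequal
margins and round-trips against exact bivariate-normal recurrence risks
(both facts are asserted in the test suite). We therefore use the T_c²
form by default and expose the variant via
`genetic_correlation(..., radicand_threshold="T_f")` for comparison.

Two further ambiguities in the standard-error expression are resolved as
follows: the bare mean-liability ratio is taken as i_c/i_f (the analogue
of the single-disorder formula; `i_convention="i_f"` gives the literal
alternative, a ratio of 1), and the co-heritability correlation r_cf is
substituted with the r_g point estimate (a plug-in; no closed alternative
exists).

Estimates are not clamped: negative h² and |r_g| > 1 are returned with
warning flags so that pooling across strata stays unbiased; clamping
occurs only where a downstream formula would need the square root of a
non-positive product, which raises instead.

## Cumulative incidence and lifetime risk

Follow-up runs from birth (age 0) to the first of: disorder onset (event
of interest), death (competing event), emigration or the administrative
study end (censoring); ties resolve in that order. Age is computed as
(date − birth date)/365.25 in real-valued years. The cumulative
incidence function is the Aalen–Johansen estimator: at each distinct
event age a, the CIF increments by S(a−)·d₁(a)/n(a), where S is the
all-cause Kaplan–Meier survivor and n(a) counts subjects with exit age
≥ a (half-open risk intervals). Events of interest and competing events
at the same age are processed jointly from the same risk set. Pointwise
variance uses the Marubini–Valsecchi delta-method estimator; the test
suite pins point estimates to values frozen from R's `cmprsk::cuminc`
(exact agreement) and calibrates the standard errors against the
empirical sampling spread over replicated simulations. Lifetime risk is
the CIF at the last observed age of the stratum, with its pointwise
standard error.

Everything is stratified by birth year. Strata with zero events of
interest yield K = 0 and are flagged; per-year estimation skips flagged
or degenerate strata (K outside (0,1), or inputs outside the estimator's
domain) with a logged reason.

Conditioned cohorts contain persons with ≥ 1 full sibling diagnosed with
the same disorder (for h²) or ≥ 1 parent diagnosed with the other
disorder (for r_g); relatives' affection is assessed over their full
observed history, with no requirement that the relative's diagnosis
precede the index person's follow-up.

## Pooling

Per-year estimates are combined with a random-effects inverse-variance
model. The between-year variance τ² uses the DerSimonian–Laird moment
estimator truncated at zero (the canonical moment estimator for this
model form); weights are 1/(s_k² + τ²), the pooled standard error is
√(1/Σw), and confidence intervals are estimate ± 1.96·se throughout.
Significance of pooled correlations is Bonferroni-adjusted with an
explicit test count `m_tests` — never inferred from the data.

## Comorbidity decomposition

A hazard ratio HR for disorder f given prior disorder c converts to a
risk ratio RR = (1 − (1 − r)^HR)/r at the outcome's reference-group
lifetime risk r (supplied as the IVW-pooled lifetime risk, never
recomputed inside the module), to an odds ratio by 2×2 algebra, and to a
phenotypic correlation by the Digby approximation
r_p = (OR^(π/4) − 1)/(OR^(π/4) + 1). The decomposition is then
G = r_g√(h_c²h_f²), E = r_p − G (exact by construction), and
r_e = E/√((1 − h_c²)(1 − h_f²)).

Interval propagation is deliberately conservative interval arithmetic:
the r_p interval pushes the HR bounds through the monotone chain, the G
interval rescales the r_g bounds (order-corrected for negative values),
and the E interval is [r_p,lo − G_hi, r_p,hi − G_lo]. Heritabilities are
treated as fixed. A delta-method variant (`decomposition_delta`) yields
SEs, z-scores and p-values for G and E under an independence assumption
and is labelled as a variant because the interval form is primary.

A caution on the Digby map: it is accurate near balanced margins (error
< 0.001 at 50% margins for OR ≈ 2.1, < 0.02 down to ~30% margins) but
overestimates the true tetrachoric correlation at rare margins (+0.08 at
10% margins, +0.11 at 5%). Since G is computed from r_g independently,
this bias inflates E — and hence the apparent environmental share — for
rare disorder pairs. The cross-check against the exact tetrachoric is
asserted at common margins only, and results at rare margins should be
read with this in mind.

When the pipeline runs on simulated data with no external hazard-ratio
table, the phenotypic correlation is instead estimated directly from the
cohort's observed 2×2 affection table (Woolf interval on log OR;
Haldane–Anscombe 0.5 correction when a cell is empty), flagged
`empirical_or` in the output.

## Synthetic registry

The simulator draws nuclear families (two founders, default two
children). Founder genetic values for the two traits are bivariate
normal with variances (h_c², h_f²) and covariance r_g·h_c·h_f; each
child's genetic value is the mid-parent mean plus an independent
segregation deviate with half the founder genetic covariance, giving
a_R = ½ for both full siblings and parent–offspring. Environmental
deviations are independent across individuals with variances
(1 − h_c², 1 − h_f²) and covariance r_e√((1 − h_c²)(1 − h_f²)); total
liability variance is 1 per trait. Affection is a threshold crossing;
onset age is an independent truncated-logistic draw on [0, 100] years
given affection (the estimation chain uses only lifetime affection, so
no onset–liability link is modelled); death and emigration are constant-
hazard exponentials; a diagnosis is emitted only if onset precedes death,
emigration and the study end. No shared-environment component and no
assortative mating are modelled.

Default study conditions: 25 birth cohorts (1981–2005, uniform), study
end 2045-12-31, disorder c with K = 0.05, h² = 0.6, onset location 23 y
and scale 3 y, disorder f with K = 0.10, h² = 0.4, onset 26 ± 4 y,
r_g = 0.3, r_e = 0.15, death hazard 2×10⁻⁴/y and emigration hazard
10⁻³/y. The onset laws are early-adult on purpose: they put ~1% of mass
below the age-10 diagnostic-validity exclusion and leave > 99% of onsets
observed by the study end even for the youngest cohort, so the observed
lifetime risk approximates the generative K. They are stylised — real
cardiometabolic onsets centre decades later — because the simulator's
job is to validate the estimators under the model they assume, not to
reproduce any register's empirical onset law.

Exact familial recurrence risks implied by the model
(`expected_familial_risks`) are computed by one-dimensional quadrature of
the bivariate-normal conditional tail (absolute tolerance ≪ 1e−8,
cross-checked against scipy's bivariate normal CDF), and serve as
oracles: estimator round trips recover h² within ±0.05 over a
(K, h²) grid and r_g within ±0.005 across unequal margins, and the full
pipeline at 500,000 families recovers (h_c², h_f², r_g) =
(0.6, 0.4, 0.3) within (±0.05, ±0.05, ±0.10). For the packaged
`moderate_rg` scenario re-run at 30,000 families the validation bands
used in the tests are ±0.10 for each h² and ±0.35 for r_g (per-year r_g
estimates are noisy at that size). Test and acceptance problem sizes
(500k families for recovery, 200k for the null check, 30–150k for
distributional checks) were chosen as the smallest sizes at which
Monte-Carlo error is comfortably inside those bands.

What passing these tests shows: the estimation chain is correct under
its own assumptions, including censoring, competing mortality, family
ascertainment and birth-year stratification. What it does not show:
robustness to features real registers have and the generator omits —
ICD-version switches over calendar time, diagnostic drift and coverage
trends (the stratification is designed to absorb these but is untested
against them), shared family environment (which would inflate h² and
r_e-mediated quantities), assortative mating, onset–liability
dependence, and incomplete follow-up of late-onset disorders (observed
"lifetime" risks then under-estimate K, and both K and K_R are thinned;
the estimators inherit a small attenuation, ~0.01–0.03 on h² at the
default ~3% thinning).

## Small conditioning biases

Conditioning on "≥ 1 affected relative" is not identical to the
single-relative conditional the formulas assume: with two parents, ~5% of
conditioned children (at K_f = 0.10) have two affected parents and are
more enriched than the pairwise theory implies, biasing r_g upward by a
few percent of its value; the analogous sibling effect is eliminated at
the default two children per family. These are properties of the design
being emulated, not of the implementation.

## Degenerate inputs and tie-breaks

- K outside (0,1): domain error from `liability_params`.
- Negative radicand in h²/r_g formulas (extreme K_R): error naming the
  offending inputs; per-year wrappers skip the stratum with a log line.
- a_R ≤ 0 or h_c²·h_f² ≤ 0: domain errors.
- RR·p ≥ 1 in the OR conversion, r = 0 in the RR conversion: domain
  errors (the r → 0 limit RR → HR is not silently substituted).
- Exit-age ties: same-age events and competing events share one risk
  set; censored records at the same age remain at risk through it.
- τ² truncates at 0; a single stratum passes through with τ² = 0.
- h² = 1 on either trait leaves r_e undefined (NaN, flagged); G and E
  are still returned.

## Reproducibility

Every stochastic component takes a single integer seed
(`numpy.random.default_rng`); pipeline runs write a manifest with the
configuration, its SHA-256 hash, the seed and library versions, and two
runs with equal seed and configuration produce byte-identical report
bundles (asserted for every packaged scenario).
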