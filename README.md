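# regliab

Register-based liability-threshold genetic epidemiology: heritability and
genetic correlation from familial recurrence risks, and decomposition of
mental–cardiometabolic comorbidity into genetic and environmental
components.

## The problem

National health registers record, for whole birth cohorts, every hospital
diagnosis together with family links (mother/father identifiers). From
such data one can ask how much of the liability to a disorder is
heritable, how much the genetic architectures of two disorders overlap,
and — given an observed comorbidity between a mental disorder (MD) and a
cardiometabolic disorder (CMD) — how much of that comorbidity is driven
by shared genes versus shared environment. `regliab` implements that
estimation chain for register-shaped tables, and ships a
synthetic-registry simulator so the whole chain can be validated against
known ground truth.

## The model

Each disorder is modelled with a liability-threshold model: a latent
standard-normal liability Z, with a person affected iff Z > T, where
T = Φ⁻¹(1 − K) and K is the lifetime risk. Writing y for the normal
density at T and i = y/K for the mean liability of the affected tail,
the heritability of liability follows from the population risk K and the
risk K_R among individuals with an affected relative (relationship
coefficient a_R = ½ for full siblings and parent–offspring):

    h² = [T − T_R √(1 − (1 − T/i)(T² − T_R²))] / [a_R (i + (i − T) T_R²)]

The genetic correlation r_g between disorders c and f uses the analogous
cross-disorder risk K_Rc (risk of c given a relative affected with f),
dividing the implied cross-relative liability covariance by
a_R √(h_c² h_f²). Lifetime risks are estimated per birth year as the
Aalen–Johansen cumulative incidence at the last observed age (death is a
competing risk; emigration and the administrative study end censor), and
per-year estimates are pooled with a DerSimonian–Laird random-effects
inverse-variance model.

Comorbidity measured as a hazard ratio HR converts to a phenotypic
correlation via RR = (1 − (1 − r)^HR)/r, OR = (1 − p)RR/(1 − RR·p) with
p = r, and r_p = (OR^(π/4) − 1)/(OR^(π/4) + 1), which then decomposes as

    G = r_g √(h_c² h_f²),   E = r_p − G,
    r_e = E / √((1 − h_c²)(1 − h_f²)).

## Worked example

```python
from regliab import heritability
from regliab.decompose import ComorbidityInputs, decomposition_intervals

est = heritability(K=0.01, K_R=0.05, a_R=0.5)
print(f"h2 = {est.h2:.3f} (se {est.se:.3f})")

res = decomposition_intervals(ComorbidityInputs(
    hr=2.0, hr_lo=1.7, hr_hi=2.4, r=0.10,
    rg=0.30, rg_lo=0.20, rg_hi=0.40, h_c2=0.6, h_f2=0.4))
print(f"RR = {res.rr:.3f}  OR = {res.odds_ratio:.3f}  rp = {res.rp:.3f}")
print(f"G  = {res.g:.3f} [{res.g_lo:.3f}, {res.g_hi:.3f}]")
print(f"E  = {res.e:.3f} [{res.e_lo:.3f}, {res.e_hi:.3f}]")
```

prints

```
h2 = 0.555 (se 0.421)
RR = 1.900  OR = 2.111  rp = 0.285
G  = 0.147 [0.098, 0.196]
E  = 0.138 [0.024, 0.259]
```

A population risk of 1% rising to 5% in the relatives of cases implies a
liability heritability of 0.56; a hazard ratio of 2 at a 10% baseline
risk corresponds to a phenotypic correlation of 0.285, of which 0.147 is
attributable to the genetic overlap (r_g = 0.3 at the given
heritabilities) and the remaining 0.138 to non-genetic factors.

The full pipeline on a simulated register (truth: h_c² = 0.6,
h_f² = 0.4, r_g = 0.3):

```python
from regliab.pipeline import PipelineConfig, run_pipeline
from regliab.simulate import SimulationConfig

bundle = run_pipeline(PipelineConfig(
    simulation=SimulationConfig(n_families=50000), seed=7))
print(bundle.h2_meta[["disorder", "h2", "se"]].round(4).to_string(index=False))
print(bundle.rg_meta[["rg", "se"]].round(4).to_string(index=False))
```

prints

```
disorder     h2     se
     SCZ 0.5586 0.1392
     T2D 0.4165 0.1872
    rg     se
0.3215 0.6299
```

recovering the generative parameters within sampling error. The same run
is available from the shell:

```sh
regliab simulate --n-families 50000 --seed 7 --out registry/
regliab run-all --config docs/example_config.yaml --seed 7 --outdir report/
```

## Layout

- `regliab.registry` — TSV readers/writers, ICD-prefix disorder
  catalogue, cohort filters, pedigree index.
- `regliab.simulate` — synthetic-registry generator and exact
  bivariate-normal familial-risk oracles.
- `regliab.incidence` — Aalen–Johansen CIF with pointwise standard
  errors; relative-conditioned cohorts; lifetime-risk extraction.
- `regliab.liability` — thresholds, h² (with SE), r_g (with SE),
  per-birth-year estimation.
- `regliab.meta` — DerSimonian–Laird random-effects IVW pooling and
  Bonferroni annotation.
- `regliab.decompose` — HR → RR → OR → r_p chain and the G/E split with
  interval arithmetic (delta-method variant available).
- `regliab.pipeline` / `regliab.cli` — orchestration, report bundles,
  `regliab` command-line interface.

See `docs/methods.md` for the statistical details, default parameter
choices, and known limitations.
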