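"""Pipeline orchestration: simulate/load -> CIF -> per-year estimation ->
random-effects meta-analysis -> comorbidity decomposition.

Runs the full estimation chain for one disorder pair (c, f): birth-year-
stratified lifetime risks for the general population, full-sibling
same-disorder cohorts and parent cross-disorder cohorts; per-year
liability-scale h2 and rg; DerSimonian-Laird pooling; and the G/E
decomposition of the phenotypic correlation.  When no published hazard
ratios are supplied, the phenotypic correlation is estimated from the
cohort's observed 2x2 affection table via the odds-ratio tetrachoric
approximation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decompose import (ComorbidityInputs, DecompositionResult,
                        decomposition_intervals, or_to_rp)
from .incidence import (build_event_histories, conditional_cohort,
                        estimate_cif, lifetime_risk_from_cif)
from .liability import per_year_genetic_correlation, per_year_heritability
from .meta import EstimateSeries, MetaEstimate, correlation_significance, ivw_random
from .registry import (CohortRules, DisorderCatalog, apply_cohort_filters,
                       build_pedigree_index, default_catalog, load_registry,
                       map_icd_codes)
from .simulate import SCENARIOS, SimulationConfig, simulate_registry

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "ReportBundle", "run_pipeline",
           "write_bundle"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one end-to-end run.

    Exactly one data source is used: ``simulation`` (a
    :class:`SimulationConfig` or packaged scenario name) or
    ``persons_path``/``diagnoses_path``.  ``hr_table`` optionally points to
    a TSV of published hazard ratios (columns: disorder_c, disorder_f, hr,
    hr_lo, hr_hi); without it the decomposition falls back to the cohort's
    empirical odds ratio.
    """

    simulation: SimulationConfig | str | None = None
    persons_path: str | None = None
    diagnoses_path: str | None = None
    disorder_c: str | None = None
    disorder_f: str | None = None
    birth_year_range: tuple[int, int] | None = None
    study_end: str | None = None
    catalog_path: str | None = None
    a_R: float = 0.5
    alpha: float = 0.05
    m_tests: int = 1
    hr_table: str | None = None
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if isinstance(sim, dict):
            from .simulate import DisorderSpec
            for key in ("disorder_c", "disorder_f"):
                if key in sim and isinstance(sim[key], dict):
                    sim[key] = DisorderSpec(**sim[key])
            if "birth_year_range" in sim:
                sim["birth_year_range"] = tuple(sim["birth_year_range"])
            sim = SimulationConfig(**sim)
        if "birth_year_range" in raw and raw["birth_year_range"] is not None:
            raw["birth_year_range"] = tuple(raw["birth_year_range"])
        return cls(simulation=sim, **raw)


@dataclass
class ReportBundle:
    """Assembled report tables plus a reproducibility manifest."""

    per_year_h2: pd.DataFrame
    h2_meta: pd.DataFrame
    per_year_rg: pd.DataFrame
    rg_meta: pd.DataFrame
    decomposition: pd.DataFrame
    manifest: dict


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _risks_by_year(histories) -> dict[int, "LifetimeRisk"]:
    curves = estimate_cif(histories, stratify_by_birth_year=True)
    return {c.stratum: lifetime_risk_from_cif(c) for c in curves}


def _pool(estimates, attr) -> MetaEstimate:
    series = EstimateSeries.from_estimates(
        [e for e in estimates if e.se > 0], attr=attr)
    return ivw_random(series)


def _pooled_lifetime_risk(risks: dict) -> MetaEstimate:
    usable = [r for r in risks.values()
              if not r.flagged and r.se > 0 and 0 < r.K < 1]
    if not usable:
        raise ValueError("no usable strata for pooled lifetime risk")
    return ivw_random(EstimateSeries(
        theta=tuple(r.K for r in usable), se=tuple(r.se for r in usable),
        labels=tuple(r.stratum for r in usable)))


def _empirical_rp(persons, cohort, mapped, disorder_c, disorder_f):
    """Phenotypic correlation from the cohort's observed 2x2 affection table.

    Uses the odds-ratio tetrachoric approximation with a Woolf interval on
    log OR (Haldane-Anscombe 0.5 correction when a cell is empty).
    """
    ids = pd.Series(sorted(cohort.person_ids))
    aff_c = ids.isin(set(mapped.loc[mapped["disorder"] == disorder_c, "person_id"]))
    aff_f = ids.isin(set(mapped.loc[mapped["disorder"] == disorder_f, "person_id"]))
    a = int((aff_c & aff_f).sum())
    b = int((aff_c & ~aff_f).sum())
    c = int((~aff_c & aff_f).sum())
    d = int((~aff_c & ~aff_f).sum())
    cells = np.array([a, b, c, d], dtype=float)
    flags = []
    if (cells == 0).any():
        cells = cells + 0.5
        flags.append("haldane_correction")
    odds = cells[0] * cells[3] / (cells[1] * cells[2])
    se_log = math.sqrt((1.0 / cells).sum())
    lo = odds * math.exp(-1.96 * se_log)
    hi = odds * math.exp(1.96 * se_log)
    return odds, (or_to_rp(lo), or_to_rp(hi)), or_to_rp(odds), tuple(flags)


@_stage("data")
def _obtain_data(config: PipelineConfig, catalog):
    if config.simulation is not None:
        sim = config.simulation
        if isinstance(sim, str):
            if sim not in SCENARIOS or SCENARIOS[sim] is None:
                raise ValueError(f"unknown simulation scenario {sim!r}")
            sim = SCENARIOS[sim]
        sim = dataclasses.replace(sim, seed=config.seed)
        persons, diagnoses, truth = simulate_registry(sim, catalog)
        return persons, diagnoses, sim, truth
    if not (config.persons_path and config.diagnoses_path):
        raise ValueError("config must provide a simulation or input paths")
    persons, diagnoses = load_registry(config.persons_path, config.diagnoses_path)
    return persons, diagnoses, None, None


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage in order; deterministic given seed and inputs."""
    catalog = (DisorderCatalog.from_yaml(config.catalog_path)
               if config.catalog_path else default_catalog())
    persons, diagnoses, sim, truth = _obtain_data(config, catalog)

    disorder_c = config.disorder_c or (sim.disorder_c.label if sim else None)
    disorder_f = config.disorder_f or (sim.disorder_f.label if sim else None)
    if not (disorder_c and disorder_f):
        raise PipelineError("stage 'config' failed: disorder pair not specified")
    birth_year_range = config.birth_year_range or (
        tuple(sim.birth_year_range) if sim else None)
    study_end = config.study_end or (sim.study_end if sim else None)
    if not (birth_year_range and study_end):
        raise PipelineError(
            "stage 'config' failed: birth_year_range and study_end required")

    mapped = _stage("map_icd_codes")(map_icd_codes)(diagnoses, catalog)
    rules = CohortRules(birth_year_range=tuple(birth_year_range),
                        study_end=pd.Timestamp(study_end))
    cohort = _stage("cohort_filters")(apply_cohort_filters)(persons, mapped, rules)
    pedigree = _stage("pedigree")(build_pedigree_index)(persons)
    logger.info("cohort: %d persons; %d sibships", len(cohort),
                pedigree.sibships["sibship"].nunique() if len(pedigree.sibships) else 0)

    per_year_h2_rows, h2_meta_rows = [], []
    pooled_h2: dict[str, MetaEstimate] = {}
    pop_risks: dict[str, dict] = {}
    for disorder in (disorder_c, disorder_f):
        @_stage(f"heritability[{disorder}]")
        def _h2_stage(disorder=disorder):
            hist_pop = build_event_histories(cohort, persons, mapped, disorder)
            risks_pop = _risks_by_year(hist_pop)
            sib = conditional_cohort(cohort, pedigree, "full_sibling",
                                     disorder, mapped)
            hist_sib = build_event_histories(sib, persons, mapped, disorder)
            risks_sib = _risks_by_year(hist_sib)
            ests = per_year_heritability(risks_pop, risks_sib, config.a_R,
                                         disorder=disorder)
            if not ests:
                raise ValueError(f"no usable strata for h2 of {disorder}")
            return risks_pop, ests, _pool(ests, "h2")
        risks_pop, ests, meta = _h2_stage()
        pop_risks[disorder] = risks_pop
        pooled_h2[disorder] = meta
        for e in ests:
            per_year_h2_rows.append({
                "disorder": disorder, "birth_year": e.birth_year, "K": e.K,
                "K_R": e.K_R, "h2": e.h2, "se": e.se,
                "flags": ";".join(e.flags)})
        h2_meta_rows.append({
            "disorder": disorder, "h2": meta.theta, "se": meta.se,
            "tau2": meta.tau2, "k_used": meta.k_used, "z": meta.z, "p": meta.p,
            "ci_lo": meta.ci[0], "ci_hi": meta.ci[1]})

    @_stage("genetic_correlation")
    def _rg_stage():
        cond = conditional_cohort(cohort, pedigree, "parent", disorder_f, mapped)
        hist = build_event_histories(cond, persons, mapped, disorder_c)
        risks_cross = _risks_by_year(hist)
        h_c2 = max(pooled_h2[disorder_c].theta, 1e-6)
        h_f2 = max(pooled_h2[disorder_f].theta, 1e-6)
        ests = per_year_genetic_correlation(
            pop_risks[disorder_c], pop_risks[disorder_f], risks_cross,
            h_c2, h_f2, config.a_R,
            disorder_c=disorder_c, disorder_f=disorder_f)
        if not ests:
            raise ValueError("no usable strata for rg")
        meta = correlation_significance(_pool(ests, "rg"),
                                        config.alpha, config.m_tests)
        return ests, meta
    rg_ests, rg_meta = _rg_stage()
    per_year_rg_rows = [{
        "disorder_c": e.disorder_c, "disorder_f": e.disorder_f,
        "birth_year": e.birth_year, "K_c": e.K_c, "K_f": e.K_f,
        "K_Rc": e.K_Rc, "rg": e.rg, "se": e.se, "flags": ";".join(e.flags)}
        for e in rg_ests]
    rg_meta_rows = [{
        "disorder_c": disorder_c, "disorder_f": disorder_f,
        "rg": rg_meta.theta, "se": rg_meta.se, "tau2": rg_meta.tau2,
        "k_used": rg_meta.k_used, "z": rg_meta.z, "p": rg_meta.p,
        "significant": rg_meta.significant,
        "alpha_adjusted": rg_meta.alpha_adjusted,
        "ci_lo": rg_meta.ci[0], "ci_hi": rg_meta.ci[1]}]

    @_stage("decomposition")
    def _decomp_stage():
        h_c2 = min(max(pooled_h2[disorder_c].theta, 0.0), 1.0 - 1e-9)
        h_f2 = min(max(pooled_h2[disorder_f].theta, 0.0), 1.0 - 1e-9)
        rg_lo, rg_hi = rg_meta.ci
        pooled_r = _pooled_lifetime_risk(pop_risks[disorder_f])
        if config.hr_table is not None:
            hr = pd.read_csv(config.hr_table, sep="\t")
            row = hr[(hr["disorder_c"] == disorder_c)
                     & (hr["disorder_f"] == disorder_f)]
            if len(row) != 1:
                raise ValueError(
                    f"hr_table must contain exactly one row for the pair "
                    f"({disorder_c}, {disorder_f}); found {len(row)}")
            row = row.iloc[0]
            inputs = ComorbidityInputs(
                hr=float(row["hr"]), hr_lo=float(row["hr_lo"]),
                hr_hi=float(row["hr_hi"]), r=pooled_r.theta,
                rg=rg_meta.theta, rg_lo=rg_lo, rg_hi=rg_hi,
                h_c2=h_c2, h_f2=h_f2, pair=(disorder_c, disorder_f))
            return decomposition_intervals(inputs), ()
        odds, (rp_lo, rp_hi), rp, flags = _empirical_rp(
            persons, cohort, mapped, disorder_c, disorder_f)
        from .decompose import decompose_rp
        g, e, re = decompose_rp(rp, rg_meta.theta, h_c2, h_f2)
        scale = math.sqrt(h_c2 * h_f2)
        g_lo, g_hi = sorted((rg_lo * scale, rg_hi * scale))
        return DecompositionResult(
            rr=float("nan"), odds_ratio=odds, rp=rp, rp_lo=rp_lo, rp_hi=rp_hi,
            g=g, g_lo=g_lo, g_hi=g_hi, e=e, e_lo=rp_lo - g_hi, e_hi=rp_hi - g_lo,
            re=re, pair=(disorder_c, disorder_f)), flags + ("empirical_or",)
    decomp, decomp_flags = _decomp_stage()
    decomposition = pd.DataFrame([{
        "disorder_c": disorder_c, "disorder_f": disorder_f,
        "rr": decomp.rr, "odds_ratio": decomp.odds_ratio,
        "rp": decomp.rp, "rp_lo": decomp.rp_lo, "rp_hi": decomp.rp_hi,
        "g": decomp.g, "g_lo": decomp.g_lo, "g_hi": decomp.g_hi,
        "e": decomp.e, "e_lo": decomp.e_lo, "e_hi": decomp.e_hi,
        "re": decomp.re,
        "flags": ";".join(tuple(decomp.flags) + tuple(decomp_flags))}])

    manifest = _manifest(config, truth)
    return ReportBundle(
        per_year_h2=pd.DataFrame(per_year_h2_rows),
        h2_meta=pd.DataFrame(h2_meta_rows),
        per_year_rg=pd.DataFrame(per_year_rg_rows),
        rg_meta=pd.DataFrame(rg_meta_rows),
        decomposition=decomposition,
        manifest=manifest,
    )


def _config_dict(config: PipelineConfig) -> dict:
    raw = dataclasses.asdict(config)
    if isinstance(config.simulation, SimulationConfig):
        raw["simulation"] = config.simulation.to_dict()
    return raw


def _manifest(config: PipelineConfig, truth) -> dict:
    raw = _config_dict(config)
    raw.pop("output_dir", None)  # result-irrelevant; keeps reruns comparable
    blob = json.dumps(raw, sort_keys=True, default=str)
    versions = {}
    for mod in ("numpy", "scipy", "pandas"):
        versions[mod] = __import__(mod).__version__
    manifest = {
        "package": "regliab",
        "version": __version__,
        "config": raw,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.seed,
        "library_versions": versions,
    }
    if truth is not None:
        manifest["simulation_truth"] = truth
    return manifest


def write_bundle(bundle: ReportBundle, out_dir) -> None:
    """Write the report tables and manifest; byte-stable given equal inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "per_year_h2.tsv": bundle.per_year_h2,
        "h2_meta.tsv": bundle.h2_meta,
        "per_year_rg.tsv": bundle.per_year_rg,
        "rg_meta.tsv": bundle.rg_meta,
        "decomposition.tsv": bundle.decomposition,
    }
    for name, frame in tables.items():
        frame.to_csv(out / name, sep="\t", index=False, float_format="%.10g",
                     lineterminator="\n")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True, default=str)
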