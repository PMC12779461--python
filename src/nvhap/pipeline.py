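"""End-to-end orchestration: simulate -> detect -> classify codes ->
trends -> pre/post effects, with a run manifest and a plain-text summary.

The YAML configuration has four optional blocks plus a seed::

    seed: 1
    simulate: {...}     # SimConfig field overrides
    detector: {...}     # DetectorRules field overrides
    prepost:  {...}     # PrePostConfig field overrides (outcome set per run)
    outdir: results/run1

All randomness flows from the single manifest seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coding_definition import classify_table
from .counterfactual import PrePostConfig, evaluate_prepost, split_pre_post, unadjusted_differences
from .electronic_definition import DetectorRules, detect_nvhap
from .synthetic_data import CohortTables, SimConfig, generate_cohort
from .trend_models import (compare_definitions_gee, fit_linear_trend_binary,
                           fit_linear_trend_los, quarterly_summaries)

log = logging.getLogger("nvhap")

_KNOWN_KEYS = {"seed", "outdir", "simulate", "detector", "prepost", "covariates"}


def percent(numerator: float, denominator: float, digits: int = 2) -> float:
    """Proportion as a percentage rounded to the printed precision."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, digits)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if "seed" not in cfg:
        raise ValueError("configuration must set an integer 'seed'")
    return cfg


def _build(cls, block: dict | None, what: str):
    block = block or {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ValueError(f"unknown {what} keys: {sorted(unknown)}")
    return cls(**block)


def attach_outcomes(cohort: CohortTables, rules: DetectorRules | None = None) -> pd.DataFrame:
    """Hospitalization table with nvhap_electronic / nvhap_coding columns
    from the two surveillance definitions."""
    hosp = cohort.hospitalizations.copy()
    events = detect_nvhap(cohort.patient_days, cohort.antibiotic_days, rules,
                          hospitalizations=hosp)
    hosp["nvhap_electronic"] = hosp["hospitalization_id"].isin(
        set(events["hospitalization_id"])).astype(np.int8)
    coded = classify_table(cohort.diagnoses)
    hosp["nvhap_coding"] = hosp["hospitalization_id"].map(coded).fillna(False).astype(np.int8)
    return hosp, events


def _manifest(cfg: dict, seed: int) -> dict:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "package_version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }


def _trend_dict(fit) -> dict:
    return {
        "value_start": fit.value_start, "value_end": fit.value_end,
        "difference": fit.difference, "difference_se": fit.difference_se,
        "difference_ci95": list(fit.difference_ci),
        "slope_per_year": fit.slope_per_year, "slope_per_year_se": fit.slope_per_year_se,
        "params": np.asarray(fit.params).tolist(),
        "cov": np.asarray(fit.cov).tolist(),
    }


def _effect_dict(res) -> dict:
    return {
        "outcome": res.outcome,
        "per_site": res.per_site.to_dict(orient="records"),
        "pooled": {"rd": res.pooled.rd, "se": res.pooled.se,
                   "ci95": list(res.pooled.ci95),
                   "weights": res.pooled.weights.tolist(),
                   "sigma": res.pooled.sigma.tolist()},
    }


def run_pipeline(config, outdir=None) -> Path:
    """Execute the full synthetic study; returns the output directory."""
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config["seed"])
    outdir = Path(outdir or config.get("outdir") or "nvhap_run")
    outdir.mkdir(parents=True, exist_ok=True)

    sim = _build(SimConfig, config.get("simulate"), "simulate")
    rules = _build(DetectorRules, config.get("detector"), "detector")
    prepost_block = dict(config.get("prepost") or {})
    prepost_block.pop("outcome", None)

    log.info("stage simulate: drawing cohort")
    cohort = generate_cohort(sim, seed=seed)
    n = len(cohort.hospitalizations)
    if n == 0:
        raise ValueError("simulated cohort is empty; increase the arrival rate")
    log.info("stage simulate: %d hospitalizations, %d patient-days",
             n, len(cohort.patient_days))
    cohort.write(outdir / "cohort")

    log.info("stage detect/classify")
    hosp, events = attach_outcomes(cohort, rules)
    events.to_csv(outdir / "events.csv", index=False)
    hosp.to_csv(outdir / "hospitalizations_outcomes.csv", index=False)

    covariates = config.get("covariates") or sim.covariates
    start, end = sim.start, sim.end

    log.info("stage trends")
    trends = {}
    quarterly = {}
    for name, col in [("nvhap_electronic", "nvhap_electronic"),
                      ("nvhap_coding", "nvhap_coding"),
                      ("death30", "death30")]:
        fit = fit_linear_trend_binary(hosp["admit_date"], hosp[col], start, end, outcome=name)
        trends[name] = _trend_dict(fit)
        quarterly[name] = quarterly_summaries(hosp["admit_date"], hosp[col], fit)
    los_fit = fit_linear_trend_los(hosp["admit_date"], hosp["los"], start, end)
    trends["los"] = _trend_dict(los_fit)
    quarterly["los"] = quarterly_summaries(hosp["admit_date"], hosp["los"], los_fit)

    long = pd.concat([
        hosp[["hospitalization_id", "admit_date"]].assign(
            definition="electronic", indicator=hosp["nvhap_electronic"]),
        hosp[["hospitalization_id", "admit_date"]].assign(
            definition="coding", indicator=hosp["nvhap_coding"]),
    ], ignore_index=True)
    comp = compare_definitions_gee(long, study_start=start)
    trends["definition_comparison"] = {
        "interaction_per_year": comp.interaction_per_year,
        "interaction_se": comp.interaction_se,
        "interaction_ci95": list(comp.interaction_ci),
        "slope_coding_per_year": comp.slope_coding_per_year,
        "slope_electronic_per_year": comp.slope_electronic_per_year,
    }

    log.info("stage evaluate (pre/post effects)")
    effects = {}
    for outcome in ("nvhap_electronic", "nvhap_coding", "death30", "los"):
        cfg_pp = PrePostConfig(outcome=outcome, **prepost_block)
        res = evaluate_prepost(hosp, cohort.implementation_dates, covariates,
                               cfg_pp, study_start=start)
        effects[outcome] = _effect_dict(res)
        pre, post = split_pre_post(hosp, cohort.implementation_dates, cfg_pp)
        crude_site, crude_pooled = unadjusted_differences(
            pre, post, outcome if outcome != "los" else "los",
            kind="mean_los" if outcome == "los" else "risk")
        effects[outcome]["unadjusted"] = {
            "per_site": crude_site.to_dict(orient="records"),
            "pooled": {"rd": crude_pooled.rd, "se": crude_pooled.se,
                       "ci95": list(crude_pooled.ci95)},
        }
        res.per_site.to_csv(outdir / f"effects_{outcome}_sites.csv", index=False)

    results = {"n_hospitalizations": n,
               "prevalence_electronic_pct": 100.0 * hosp["nvhap_electronic"].mean(),
               "prevalence_coding_pct": 100.0 * hosp["nvhap_coding"].mean(),
               "trends": trends, "effects": effects}
    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    for name, q in quarterly.items():
        q.to_csv(outdir / f"quarterly_{name}.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(_manifest(config, seed), fh, indent=2)
    _write_summary(outdir / "summary.txt", results)
    log.info("pipeline complete: %s", outdir)
    return outdir


def _write_summary(path: Path, r: dict) -> None:
    t = r["trends"]
    e = r["effects"]
    lines = [
        "NV-HAP synthetic surveillance study",
        "=" * 40,
        f"hospitalizations: {r['n_hospitalizations']}",
        f"NV-HAP prevalence, electronic definition: {r['prevalence_electronic_pct']:.2f}%",
        f"NV-HAP prevalence, coding definition:     {r['prevalence_coding_pct']:.2f}%",
        "",
        "Temporal trends (study start -> end)",
        "-" * 40,
    ]
    for name in ("nvhap_electronic", "nvhap_coding", "death30"):
        d = t[name]
        lines.append(
            f"{name}: {100 * d['value_start']:.2f}% -> {100 * d['value_end']:.2f}% "
            f"(diff {100 * d['difference']:+.3f} pp, "
            f"95% CI {100 * d['difference_ci95'][0]:+.3f} to {100 * d['difference_ci95'][1]:+.3f}; "
            f"log-odds/yr {d['slope_per_year']:+.3f})")
    d = t["los"]
    lines.append(f"mean LOS: {d['value_start']:.2f} -> {d['value_end']:.2f} days "
                 f"(diff {d['difference']:+.2f} days, 95% CI "
                 f"{d['difference_ci95'][0]:+.2f} to {d['difference_ci95'][1]:+.2f})")
    c = t["definition_comparison"]
    lines += ["",
              f"definition-by-time interaction (electronic - coding, log-odds/yr): "
              f"{c['interaction_per_year']:+.3f} "
              f"(95% CI {c['interaction_ci95'][0]:+.3f} to {c['interaction_ci95'][1]:+.3f})",
              "",
              "Pre/post implementation effects (actual - counterfactual)",
              "-" * 40]
    for name, res in e.items():
        p = res["pooled"]
        if name == "los":
            lines.append(f"{name}: pooled {p['rd']:+.3f} days "
                         f"(95% CI {p['ci95'][0]:+.3f} to {p['ci95'][1]:+.3f})")
        else:
            lines.append(f"{name}: pooled {100 * p['rd']:+.3f} pp "
                         f"(95% CI {100 * p['ci95'][0]:+.3f} to {100 * p['ci95'][1]:+.3f})")
    path.write_text("\n".join(lines) + "\n")
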