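"""Orchestration of the full characterization report.

`run_pipeline` chains the analysis stages — titer/EOP host-range summary,
adsorption and one-step kinetics fits, stability windows, and the cocktail
killing-dynamics endpoints — into one `CharacterizationReport`.  A stage
that fails records its error and the rest of the report is still produced.

All randomness flows through the single configured seed: stage s of
replicate i draws from seed + a fixed stage offset, so reruns with the same
config are byte-identical (the provenance block carries no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cocktail import scenario_library, simulate
from .hostrange import HostRangeMatrix, demo_matrix, summaries_to_frame, summarize_host_range
from .io import RunConfig, kinetic_series_from_frame, read_assay_table
from .kinetics import estimate_latent_burst, fit_adsorption, stability_profile
from .synthetic import (
    PHAGE_PRESETS,
    NoiseModel,
    make_adsorption_series,
    make_onestep_series,
    make_stability_series,
)

logger = logging.getLogger("phagechar")

#: Host density used in the demo kinetic assays (the one-step inoculum).
DEMO_HOST_DENSITY = 1e8
DEMO_MOI = 0.001
DEMO_REPLICATES = 3

# fixed per-stage seed offsets so stages stay independent under one seed
_STAGE_SEED = {"adsorption": 1000, "onestep": 2000, "stability": 3000}


@dataclass
class CharacterizationReport:
    """Everything the pipeline computed, JSON/CSV serializable."""

    growth_params: list = field(default_factory=list)
    hostrange_summary: list = field(default_factory=list)
    stability: dict = field(default_factory=dict)
    cocktail_endpoints: list = field(default_factory=list)
    errors: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def body_dict(self) -> dict:
        return {
            "growth_params": self.growth_params,
            "hostrange_summary": self.hostrange_summary,
            "stability": self.stability,
            "cocktail_endpoints": self.cocktail_endpoints,
            "errors": self.errors,
        }

    def to_dict(self) -> dict:
        return {**self.body_dict(), "provenance": self.provenance}


def _triplicate_mean_kinetics(phage_key: str, seed: int) -> dict:
    """Fit adsorption + one-step parameters on seeded triplicate synthetic assays."""
    preset = PHAGE_PRESETS[phage_key]
    ks, lats, bursts = [], [], []
    for rep in range(DEMO_REPLICATES):
        noise_a = NoiseModel(count_noise=True, seed=seed + _STAGE_SEED["adsorption"] + rep)
        ads = make_adsorption_series(preset, host_density=DEMO_HOST_DENSITY, noise=noise_a)
        ks.append(fit_adsorption(ads, host_density=DEMO_HOST_DENSITY).k_ads)
        noise_o = NoiseModel(count_noise=True, seed=seed + _STAGE_SEED["onestep"] + rep)
        ost = make_onestep_series(
            preset, host_density=DEMO_HOST_DENSITY, moi=DEMO_MOI, noise=noise_o
        )
        est = estimate_latent_burst(ost)
        lats.append(est.latent_min)
        bursts.append(est.burst)
    return {
        "phage_id": preset.phage_id,
        "k_ads_ml_per_min": float(np.mean(ks)),
        "latent_min": float(np.mean(lats)),
        "burst": float(np.mean(bursts)),
        "n_replicates": DEMO_REPLICATES,
    }


def _kinetics_from_tables(config: RunConfig) -> list[dict]:
    out = []
    ads_df = read_assay_table(config.inputs["adsorption"], "adsorption")
    ost_df = read_assay_table(config.inputs["onestep"], "onestep")
    host_density = float(ads_df.attrs["metadata"].get("host_density", DEMO_HOST_DENSITY))
    ks = [
        fit_adsorption(s, host_density=host_density)
        for s in kinetic_series_from_frame(ads_df, "adsorption")
    ]
    ests = [estimate_latent_burst(s) for s in kinetic_series_from_frame(ost_df, "onestep")]
    out.append(
        {
            "phage_id": ads_df.attrs["metadata"].get("phage_id", ""),
            "k_ads_ml_per_min": float(np.mean([g.k_ads for g in ks])),
            "latent_min": float(np.mean([e.latent_min for e in ests])),
            "burst": float(np.mean([e.burst for e in ests])),
            "n_replicates": len(ks),
        }
    )
    return out


def _stability_stage(config: RunConfig, kind: str) -> dict:
    key = f"stability_{kind}"
    if key in config.inputs:
        df = read_assay_table(config.inputs[key], "stability")
        reference = float(df.attrs["metadata"].get("reference", 1e8))
        conditions, titers = df["condition"].to_numpy(), df["titer"].to_numpy()
    else:  # demo: synthesize viability and convert back to titers
        reference = 1e8
        noise = NoiseModel(titer_cv=0.05, seed=config.seed + _STAGE_SEED["stability"])
        series = make_stability_series(kind, noise=noise)
        conditions = series.conditions
        titers = series.viability / 100.0 * reference
    report = stability_profile(kind, conditions, titers, reference=reference)
    return {
        "kind": kind,
        "stable_window": list(report.stable_window) if report.stable_window else None,
        "inactivated_conditions": report.inactivated_conditions.tolist(),
        "viability_percent": report.series.viability.round(3).tolist(),
        "conditions": report.series.conditions.tolist(),
    }


def _cocktail_stage(config: RunConfig) -> list[dict]:
    rows = []
    for name, scenario in scenario_library(config.scenario_variant).items():
        traj = simulate(scenario)
        at = traj.at_hours()
        floor = scenario.extinction_threshold
        rows.append(
            {
                "scenario": name,
                "time_h": at["time_h"].tolist(),
                "viable_total_cfu_per_ml": at["viable_total"].round(6).tolist(),
                "log10_viable": [
                    float(np.log10(max(v, floor))) if v > 0 else 0.0
                    for v in at["viable_total"]
                ],
            }
        )
    return rows


def run_pipeline(config: RunConfig) -> CharacterizationReport:
    """Run every stage the config provides inputs for (all of them in demo mode)."""
    config.validate()
    report = CharacterizationReport()
    report.provenance = {
        "package": "phagechar",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.canonical_json().encode()).hexdigest(),
    }

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # record and continue with partial results
            logger.error("stage %s failed: %s", name, exc)
            report.errors[name] = f"{type(exc).__name__}: {exc}"
            return None

    # host range
    def hostrange_stage():
        if "hostrange" in config.inputs:
            df = read_assay_table(config.inputs["hostrange"], "hostrange")
            matrix = HostRangeMatrix(df)
        else:
            matrix = demo_matrix()
        return [dict(s.__dict__) for s in summarize_host_range(matrix)]

    result = stage("hostrange", hostrange_stage)
    if result:
        report.hostrange_summary = result

    # growth kinetics
    def kinetics_stage():
        if "adsorption" in config.inputs and "onestep" in config.inputs:
            return _kinetics_from_tables(config)
        return [_triplicate_mean_kinetics(key, config.seed) for key in PHAGE_PRESETS]

    result = stage("kinetics", kinetics_stage)
    if result:
        report.growth_params = result

    # stability
    for kind in ("pH", "temperature"):
        result = stage(f"stability_{kind}", lambda k=kind: _stability_stage(config, k))
        if result:
            report.stability[kind] = result

    # cocktail simulations
    result = stage("cocktail", lambda: _cocktail_stage(config))
    if result:
        report.cocktail_endpoints = result

    return report


def write_report(report: CharacterizationReport, outdir, formats=("json", "csv")) -> list[Path]:
    """Serialize a report; JSON carries everything, CSVs mirror the tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if "json" in formats:
        p = outdir / "report.json"
        p.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))
        written.append(p)
    if "csv" in formats:
        if report.growth_params:
            p = outdir / "growth_params.csv"
            pd.DataFrame(report.growth_params).to_csv(p, index=False)
            written.append(p)
        if report.hostrange_summary:
            p = outdir / "hostrange_summary.csv"
            pd.DataFrame(report.hostrange_summary).to_csv(p, index=False)
            written.append(p)
        if report.cocktail_endpoints:
            rows = []
            for entry in report.cocktail_endpoints:
                for t, v, lg in zip(
                    entry["time_h"], entry["viable_total_cfu_per_ml"], entry["log10_viable"]
                ):
                    rows.append(
                        {
                            "scenario": entry["scenario"],
                            "time_h": t,
                            "viable_total_cfu_per_ml": v,
                            "log10_viable": lg,
                        }
                    )
            p = outdir / "cocktail_endpoints.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            written.append(p)
    return written
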