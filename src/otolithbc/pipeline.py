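"""End-to-end orchestration: simulate -> back-calculate -> cohorts -> analyze -> plot.

A run is driven by one YAML config with two sections, ``sim`` (fields of
:class:`~otolithbc.synthetic.SimConfig`) and ``analysis`` (fields of
:class:`~otolithbc.data_model.AnalysisConfig`), plus a single seed.  The seed
is fanned out to per-stage substreams via ``numpy.random.SeedSequence`` so a
stage can be re-run in isolation; outputs are deterministic (byte-identical
CSVs) given config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import backcalc, cohorts, stats, viz
from .data_model import (
    AnalysisConfig, ConfigError, read_fish_table, write_fish_table,
    write_observations,
)
from .synthetic import SimConfig, simulate_population

log = logging.getLogger("otolithbc")

STAGES = ("simulate", "backcalc", "cohorts", "analyze", "plot")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


def _build_configs(config: dict) -> tuple[SimConfig, AnalysisConfig]:
    sim_keys = {f.name for f in dataclasses.fields(SimConfig)}
    ana_keys = {f.name for f in dataclasses.fields(AnalysisConfig)}
    sim_raw = dict(config.get("sim", {}) or {})
    ana_raw = dict(config.get("analysis", {}) or {})
    for section, raw, keys in (("sim", sim_raw, sim_keys), ("analysis", ana_raw, ana_keys)):
        unknown = set(raw) - keys
        if unknown:
            raise ConfigError(f"unknown {section} config key(s): {sorted(unknown)}")
    if "age_weights" in sim_raw:
        sim_raw["age_weights"] = {
            k: tuple(v) for k, v in sim_raw["age_weights"].items()
        }
    if "status_effect_ages" in sim_raw:
        sim_raw["status_effect_ages"] = tuple(sim_raw["status_effect_ages"])
    sim_cfg = SimConfig(**sim_raw)
    sim_cfg.validate()
    return sim_cfg, AnalysisConfig(**ana_raw)


def stage_seeds(seed: int) -> dict[str, int]:
    """Fan one seed out to independent per-stage substreams (< 2**31)."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(STAGES, children)
    }


def run_pipeline(
    config: dict | str | Path,
    seed: int = 0,
    outdir: str | Path = "run",
    fish_csv: str | Path | None = None,
    make_plots: bool = True,
) -> dict:
    """Run the full pipeline into ``outdir``; returns a manifest dict.

    ``fish_csv`` substitutes a real fish table for the simulation stage.
    Outputs: ``fish.csv``, ``truth.csv`` (simulated runs), ``params.json``,
    ``obs.csv``, ``counts.csv``, ``results.csv``, ``table2.csv``, ``figs/``
    and ``run.json`` (seed, config hash, gating decisions).
    """
    if not isinstance(config, dict):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh) or {}
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    sim_cfg, ana_cfg = _build_configs(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)
    manifest: dict = {"outdir": str(outdir), "seed": seed, "config_sha256": cfg_hash,
                      "stage_seeds": seeds, "gates": {}}

    stage = "simulate"
    try:
        if fish_csv is None:
            records, truth = simulate_population(sim_cfg, seed=seeds["simulate"])
            write_fish_table(records, outdir / "fish.csv")
            truth.to_csv(outdir / "truth.csv", index=False)
        else:
            records = read_fish_table(fish_csv)

        stage = "backcalc"
        params = backcalc.fit(records, ana_cfg)
        with open(outdir / "params.json", "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(params), fh, indent=2)
        obs = backcalc.back_calculate_all(records, params, ana_cfg)

        stage = "cohorts"
        obs = cohorts.add_year_labels(obs, ana_cfg)
        write_observations(obs, outdir / "obs.csv")
        datasets = cohorts.pool_by_age(obs, ana_cfg)
        counts = cohorts.sample_size_table(records, obs)
        counts.to_csv(outdir / "counts.csv")

        stage = "analyze"
        results = stats.analyze_cohorts(datasets, ana_cfg)
        results.to_csv(outdir / "results.csv", index=False)
        summary = stats.summary_table(datasets, decimals=ana_cfg.report_decimals)
        summary.to_csv(outdir / "table2.csv")
        manifest["gates"] = {
            str(int(a)): g for a, g in zip(results["age"], results["gate"])
        }

        stage = "plot"
        if make_plots:
            figs = viz.plot_all(datasets, results, ana_cfg, outdir / "figs")
            manifest["figures"] = [str(p) for p in figs]
    except Exception as err:
        raise StageError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(outdir / "run.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
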