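"""End-to-end pipeline: data (read or simulate) -> ranks -> networks ->
covariates -> model fits -> event windows, with every artefact written as CSV.

The configuration is a flat YAML/dict mirroring the package defaults::

    simulate: true          # or false with paths: {scans, agonistic, demography}
    seed: 1
    scenario: {n_groups: 3, years: 8, effects: {beta_immigrant: -1.0}}
    outdir: out
    lax: false
    elo: {start: 1000, k: 100}
    node_strength: weighted_degree   # or raw_rate
    min_focals_per_window: 0
    interval: 0.95
    backend: mixedlm
    models: [individual, dyadic, infant_gam, immigrant_gam]

Every stage logs its row counts; any failure aborts with the stage name.
Identical config + seed produces byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import io
from .simulate import ScenarioConfig, Effects, simulate
from .elo import run_elo, build_rank_table, elo_daily_frame
from .networks import calendar_window, build_network, networks_frame, node_strength_frame
from .covariates import build_model_tables
from .events import find_events, event_strength_series, compile_event_tables
from .models import (fit_hierarchical, fit_event_gam, FitResult,
                     INDIVIDUAL_SPEC, DYADIC_SPEC, INFANT_GAM_SPEC,
                     IMMIGRANT_GAM_SPEC)

log = logging.getLogger("gorillanet")

STAGES = ("data", "ranks", "networks", "covariates", "eventwindows", "fit")


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    pass


def _scenario_from_config(config: dict) -> ScenarioConfig:
    sc = dict(config.get("scenario") or {})
    eff = Effects(**(sc.pop("effects", None) or {}))
    for key in ("females_per_group", "focals_per_female_year", "scans_per_focal"):
        if key in sc:
            sc[key] = tuple(sc[key])
    seed = int(config.get("seed", 0))
    return ScenarioConfig(effects=eff, seed=sc.pop("seed", seed), **sc)


def _write(df: pd.DataFrame, path: Path, stage: str) -> None:
    out = df.copy()
    for c in out.columns:
        if out[c].map(lambda v: hasattr(v, "isoformat"), na_action="ignore").any():
            out[c] = out[c].map(lambda v: v.isoformat() if hasattr(v, "isoformat") else v)
    out.to_csv(path, index=False)
    log.info("[%s] wrote %s (%d rows)", stage, path.name, len(out))


def _fit_outputs(fr: FitResult, outdir: Path) -> None:
    _write(fr.summaries, outdir / f"fit_{fr.model_id}.csv", "fit")
    if fr.smooth_tests is not None:
        _write(fr.smooth_tests, outdir / f"fit_{fr.model_id}_smooths.csv", "fit")
    meta = dict(fr.diagnostics, r2_marginal=fr.r2_marginal,
                r2_conditional=fr.r2_conditional)
    with open(outdir / f"fit_{fr.model_id}_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)


def run_pipeline(config: dict, stages=("all",)) -> dict:
    """Run the requested pipeline stages; returns the in-memory artefacts.

    `stages` is a sequence drawn from "data", "ranks", "networks",
    "covariates", "eventwindows", "fit" or "all"; prerequisites of a
    requested stage always run.
    """
    if "all" in stages:
        wanted = set(STAGES)
    else:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {', '.join(sorted(unknown))}")
        wanted = set(stages)
        for s, deps in {"ranks": {"data"}, "networks": {"data"},
                        "covariates": {"data", "ranks", "networks"},
                        "eventwindows": {"data"},
                        "fit": {"data", "ranks", "networks", "covariates",
                                "eventwindows"}}.items():
            if s in wanted:
                wanted |= deps
    outdir = Path(config.get("outdir", "out"))
    outdir.mkdir(parents=True, exist_ok=True)
    art: dict = {}

    def stage(name):
        return name in wanted

    # -- data ---------------------------------------------------------------
    try:
        if config.get("simulate", False):
            scenario = _scenario_from_config(config)
            sim = simulate(scenario)
            art["demography"], art["scans"], art["agonistic"] = \
                sim.demography, sim.scans, sim.agonistic
            art["truth"] = sim.truth
            sim.write(outdir / "data")
            log.info("[data] simulated %d individuals, %d scans, %d agonistic events",
                     len(sim.demography), len(sim.scans), len(sim.agonistic))
            years = list(range(scenario.start_year,
                               scenario.start_year + scenario.years))
        else:
            paths = config.get("paths") or {}
            for key in ("scans", "agonistic", "demography"):
                if key not in paths:
                    raise ConfigError(
                        f"simulate is false and paths.{key} is missing")
            lax = bool(config.get("lax", False))
            art["demography"] = io.read_demography(paths["demography"])
            art["scans"] = io.read_scans(paths["scans"], art["demography"], lax=lax)
            art["agonistic"] = io.read_agonistic(paths["agonistic"],
                                                 art["demography"], lax=lax)
            log.info("[data] read %d scans, %d agonistic events",
                     len(art["scans"]), len(art["agonistic"]))
            ys = sorted({d.year for d in art["scans"]["date"]})
            years = list(range(min(ys), max(ys) + 1)) if ys else []
        art["years"] = years
    except ConfigError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'data' failed: {exc}") from exc

    demography, scans, agonistic = art["demography"], art["scans"], art["agonistic"]

    # -- ranks --------------------------------------------------------------
    if stage("ranks"):
        try:
            elo = run_elo(agonistic, demography,
                          start=float((config.get("elo") or {}).get("start", 1000)),
                          k=float((config.get("elo") or {}).get("k", 100)))
            ranks = build_rank_table(elo, demography, years)
            art["elo"], art["ranks"] = elo, ranks
            _write(ranks, outdir / "ranks.csv", "ranks")
            _write(elo_daily_frame(elo), outdir / "elo_daily.csv", "ranks")
        except Exception as exc:
            raise PipelineError(f"stage 'ranks' failed: {exc}") from exc

    # -- networks -----------------------------------------------------------
    if stage("networks"):
        try:
            mode = config.get("node_strength", "weighted_degree")
            min_focals = int(config.get("min_focals_per_window", 0))
            nets = [build_network(scans, demography, calendar_window(g, y),
                                  node_strength=mode, min_focals=min_focals)
                    for g in demography.groups for y in years]
            art["networks"] = nets
            art["dyadic_strengths"] = networks_frame(nets)
            art["node_strengths"] = node_strength_frame(nets)
            _write(art["dyadic_strengths"], outdir / "networks.csv", "networks")
            _write(art["node_strengths"], outdir / "node_strength.csv", "networks")
        except Exception as exc:
            raise PipelineError(f"stage 'networks' failed: {exc}") from exc

    # -- covariates ---------------------------------------------------------
    if stage("covariates"):
        try:
            individual, dyad = build_model_tables(
                art["node_strengths"], art["dyadic_strengths"], art["ranks"],
                demography)
            art["individual_year"], art["dyad_year"] = individual, dyad
            _write(individual, outdir / "individual_year.csv", "covariates")
            _write(dyad, outdir / "dyad_year.csv", "covariates")
        except Exception as exc:
            raise PipelineError(f"stage 'covariates' failed: {exc}") from exc

    # -- event windows ------------------------------------------------------
    if stage("eventwindows"):
        try:
            anchors = find_events(demography)
            series = [event_strength_series(scans, demography, a) for a in anchors]
            infant, imm = compile_event_tables(series)
            art["event_anchors"] = anchors
            art["event_infant"], art["event_immigrant"] = infant, imm
            _write(infant, outdir / "event_series_infant.csv", "eventwindows")
            _write(imm, outdir / "event_series_immigrant.csv", "eventwindows")
            log.info("[eventwindows] %d anchors -> %d infant rows, %d immigrant rows",
                     len(anchors), len(infant), len(imm))
        except Exception as exc:
            raise PipelineError(f"stage 'eventwindows' failed: {exc}") from exc

    # -- fits ---------------------------------------------------------------
    if stage("fit"):
        try:
            seed = int(config.get("seed", 0))
            backend = config.get("backend", "mixedlm")
            models = config.get("models",
                                ["individual", "dyadic", "infant_gam",
                                 "immigrant_gam"])
            art["fits"] = {}
            for model_id in models:
                if model_id == "individual":
                    fr = fit_hierarchical(INDIVIDUAL_SPEC, art["individual_year"],
                                          seed=seed, backend=backend)
                elif model_id == "dyadic":
                    fr = fit_hierarchical(DYADIC_SPEC, art["dyad_year"],
                                          seed=seed, backend=backend)
                elif model_id in ("infant_gam", "immigrant_gam"):
                    spec = INFANT_GAM_SPEC if model_id == "infant_gam" \
                        else IMMIGRANT_GAM_SPEC
                    table = art["event_infant"] if model_id == "infant_gam" \
                        else art["event_immigrant"]
                    if len(table) == 0 or table["condition"].nunique() < 2:
                        log.warning("[fit] %s skipped: no usable event rows",
                                    model_id)
                        continue
                    fr = fit_event_gam(spec, table, seed=seed, backend=backend)
                else:
                    raise ConfigError(f"unknown model {model_id!r}")
                art["fits"][model_id] = fr
                _fit_outputs(fr, outdir)
                log.info("[fit] %s: n=%d converged=%s R2m=%.3f R2c=%.3f",
                         model_id, fr.diagnostics["n"],
                         fr.diagnostics["converged"], fr.r2_marginal,
                         fr.r2_conditional)
        except (ConfigError, PipelineError):
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'fit' failed: {exc}") from exc
    return art
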