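"""Config-driven orchestration of the full invasion-risk analysis.

Stages run in dependency order::

    simulate -> screen -> fit -> evaluate -> project -> overlap -> risk
             -> disperse -> demography -> report

Every stage consumes and produces only plain-text artifacts (Esri ASCII
grids, delimited tables, JSON), so each is independently re-runnable from
the files on disk. A run emits a resolved-config snapshot and a manifest
listing every artifact with its content hash; identical config + seed
reproduce identical hashes. Randomness is controlled by one global seed
from which each stage derives a stable sub-seed (CRC of the stage name),
so adding or dropping stages never shifts another stage's random stream.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
import warnings
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demography as demo
from . import dispersal, evalmetrics, maxent, risk, screen, synth
from .raster import (Grid, GridStack, latitude_band_counts,
                     proximity_component, read_ascii_grid, read_occurrences,
                     write_ascii_grid, write_occurrences)

__all__ = ["DEFAULT_CONFIG", "STAGES", "PipelineError", "DependencyError",
           "load_config", "run_pipeline"]

logger = logging.getLogger("snailrisk")

STAGES = ("simulate", "screen", "fit", "evaluate", "project", "overlap",
          "risk", "disperse", "demography", "report")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "snailrisk_out",
    "simulate": {
        "nrows": 60, "ncols": 60, "n_vars": 6, "smoothing_radius": 3,
        "correlated_pair": ["env6", "env1", 0.9],
        "snail_truth": {"env1": [2.5, 0.0], "env2": [0.0, -1.5]},
        "snail_intercept": -1.0,
        "crop_truth": {"env1": [2.0, 0.0], "env3": [1.0, 0.0]},
        "crop_intercept": -0.5,
        "n_occurrences": 150,
        "forest_fraction": 0.6,
        "future_periods": 4,
        "trends": {"env1": -0.15},
        "n_sites": 16,
        "demography_effect": 10.0,
        "demography_noise_sd": 1.5,
    },
    "screen": {"threshold": 0.7, "sample_n": 10000, "priority": None},
    "fit": {"reg_beta": 1.0, "background_n": 2000,
            "feature_types": ["linear", "quadratic", "product"]},
    "evaluate": {"n_replicates": 5, "test_fraction": 0.3},
    "overlap": {"band_width": 0.1},
    "risk": {"forest_classes": [1], "high_threshold": 0.5,
             "band_width": 0.1},
    "disperse": {
        "rc_threshold": 600, "disp_steps": 20, "ini_mat_age": 1,
        "propagule_prod": 1.0, "ldd_freq": 0.05, "ldd_min_dist": 2,
        "ldd_max_dist": 0, "kernel": [1.0], "replicates": 5,
    },
    "demography": {"group_high": [2, 3], "group_low": [0, 1]},
    "report": {},
}


class PipelineError(RuntimeError):
    pass


class DependencyError(PipelineError):
    """An input artifact of a stage is missing; names the producing stage."""


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in override.items():
        if key not in defaults:
            raise PipelineError(f"unknown config key: {path}{key}")
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge(defaults[key], val, f"{path}{key}.")
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Resolve a config: defaults <- YAML file <- in-memory overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    """Shared state of one pipeline invocation."""

    def __init__(self, cfg: dict):
        self.cfg = cfg
        self.outdir = Path(cfg["outdir"])
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.artifacts: list[Path] = []
        self.warnings: list[str] = []

    def path(self, *parts: str) -> Path:
        p = self.outdir.joinpath(*parts)
        p.parent.mkdir(parents=True, exist_ok=True)
        return p

    def put_grid(self, grid: Grid, *parts: str) -> Path:
        p = self.path(*parts)
        write_ascii_grid(grid, p)
        self.artifacts.append(p)
        return p

    def put_table(self, df: pd.DataFrame, *parts: str) -> Path:
        p = self.path(*parts)
        df.to_csv(p, index=False)
        self.artifacts.append(p)
        return p

    def put_text(self, text: str, *parts: str) -> Path:
        p = self.path(*parts)
        p.write_text(text)
        self.artifacts.append(p)
        return p

    def need(self, relpath: str, producer: str) -> Path:
        p = self.outdir / relpath
        if not p.exists():
            raise DependencyError(
                f"missing input '{relpath}'; run the '{producer}' stage first")
        return p

    def load_stack(self, subdir: str, producer: str) -> GridStack:
        d = self.need(subdir, producer)
        names = sorted(p.stem for p in Path(d).glob("*.asc"))
        return GridStack({n: read_ascii_grid(Path(d) / f"{n}.asc")
                          for n in names})


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(run: _Run, seed: int) -> None:
    c = run.cfg["simulate"]
    n_vars = c["n_vars"]
    mixing = np.eye(n_vars)
    names = [f"env{i + 1}" for i in range(n_vars)]
    if c["correlated_pair"]:
        child, parent, w = c["correlated_pair"]
        i, j = names.index(child), names.index(parent)
        mixing[i, i] = np.sqrt(max(0.0, 1 - float(w) ** 2))
        mixing[i, j] = float(w)
    spec = synth.LandscapeSpec(
        nrows=c["nrows"], ncols=c["ncols"], n_vars=n_vars,
        smoothing_radius=c["smoothing_radius"], mixing=mixing, seed=seed)
    stack = synth.gen_env_stack(spec)
    for name, g in stack.layers.items():
        run.put_grid(g, "env", f"{name}.asc")

    for species, truth_key, icpt_key in (
            ("snail", "snail_truth", "snail_intercept"),
            ("crop", "crop_truth", "crop_intercept")):
        truth = synth.TruthModel(
            coefficients={k: tuple(v) for k, v in c[truth_key].items()},
            intercept=c[icpt_key])
        surface = synth.true_suitability(stack, truth)
        run.put_grid(surface, "truth", f"{species}_suitability.asc")
        occ = synth.sample_occurrences(
            surface, c["n_occurrences"],
            seed=seed + zlib.crc32(species.encode()) % 1000,
            species=species)
        p = run.path("occ", f"{species}.csv")
        write_occurrences(occ, p)
        run.artifacts.append(p)

    landcover = synth.gen_landcover(spec, c["forest_fraction"])
    run.put_grid(landcover, "landcover.asc")

    series = synth.gen_future_series(stack, c["trends"], c["future_periods"])
    for k, st in enumerate(series, start=1):
        for name, g in st.layers.items():
            run.put_grid(g, "env_future", f"period{k}", f"{name}.asc")

    # demographic sites stratified by suitability value (not cell rank), so
    # every category from unsuitable to highly suitable receives sites even
    # though most of the landscape sits at low suitability
    surface = read_ascii_grid(run.path("truth", "snail_suitability.asc"))
    cells = np.flatnonzero(surface.mask.ravel())
    vals = surface.values.ravel()[cells]
    targets = np.linspace(vals.min(), vals.max(), c["n_sites"])
    picks = []
    available = np.ones(cells.size, dtype=bool)
    for t in targets:
        dist = np.where(available, np.abs(vals - t), np.inf)
        j = int(np.argmin(dist))
        picks.append(j)
        available[j] = False
    picks = np.asarray(picks)
    sites = []
    for i, cell in enumerate(cells[picks]):
        r, col = divmod(int(cell), surface.ncols)
        lon, lat = surface.cell_center(r, col)
        sites.append((f"site{i + 1:02d}", lon, lat))
    sitedf = synth.gen_demography(
        sites, surface, effect=c["demography_effect"],
        noise_sd=c["demography_noise_sd"], seed=seed + 7)
    run.put_table(sitedf, "sites.csv")


def _stage_screen(run: _Run, seed: int) -> None:
    c = run.cfg["screen"]
    stack = run.load_stack("env", "simulate")
    corr = screen.corr_matrix(stack, sample_n=c["sample_n"], seed=seed)
    result = screen.prune_correlated(corr, threshold=c["threshold"],
                                     priority=c["priority"])
    p = run.path("screen", "corr_matrix.csv")
    corr.to_csv(p)
    run.artifacts.append(p)
    run.put_table(result.report(), "screen", "screen_report.csv")
    run.put_text("\n".join(result.retained) + "\n", "screen", "retained.txt")


def _retained(run: _Run) -> list[str]:
    p = run.need("screen/retained.txt", "screen")
    return [l for l in p.read_text().splitlines() if l]


def _stage_fit(run: _Run, seed: int) -> None:
    c = run.cfg["fit"]
    stack = run.load_stack("env", "simulate").subset(_retained(run))
    spec = maxent.FeatureSpec(types=tuple(c["feature_types"]))
    for species in ("snail", "crop"):
        occ = read_occurrences(run.need(f"occ/{species}.csv", "simulate"))
        bg = maxent.sample_background(
            stack, min(c["background_n"], stack.data_cells().size),
            seed=seed)
        model = maxent.fit(occ, bg, stack, spec=spec,
                           reg_beta=c["reg_beta"])
        run.put_text(model.to_text(), "models", f"{species}.lambdas.txt")
        run.put_grid(maxent.predict(model, stack),
                     "suitability", f"{species}_current.asc")
        run.put_table(maxent.percent_contribution(model),
                      "models", f"{species}_contribution.csv")
        run.put_table(
            maxent.permutation_importance(model, occ, bg, stack, seed=seed),
            "models", f"{species}_perm_importance.csv")


def _stage_evaluate(run: _Run, seed: int) -> None:
    c = run.cfg["evaluate"]
    fc = run.cfg["fit"]
    stack = run.load_stack("env", "simulate").subset(_retained(run))
    spec = maxent.FeatureSpec(types=tuple(fc["feature_types"]))
    rows = []
    for species in ("snail", "crop"):
        occ = read_occurrences(run.need(f"occ/{species}.csv", "simulate"))
        ev = maxent.replicate_evaluate(
            occ, stack, spec=spec, reg_beta=fc["reg_beta"],
            n_replicates=c["n_replicates"],
            test_fraction=c["test_fraction"], seed=seed,
            background_n=fc["background_n"])
        per = ev.per_replicate.copy()
        per.insert(0, "species", species)
        per.insert(1, "replicate", range(len(per)))
        rows.append(per)
        fmt = ev.formatted()
        fmt["species"] = species
        run.put_text(json.dumps(fmt, indent=2, sort_keys=True) + "\n",
                     "evaluate", f"{species}_summary.json")
        run.put_text(repr(float(ev.per_replicate["mtss_threshold"].mean()))
                     + "\n", "evaluate", f"{species}_mtss.txt")
    run.put_table(pd.concat(rows, ignore_index=True),
                  "evaluate", "replicates.csv")


def _read_mtss(run: _Run, species: str) -> float:
    p = run.need(f"evaluate/{species}_mtss.txt", "evaluate")
    return float(p.read_text().strip())


def _stage_project(run: _Run, seed: int) -> None:
    fc = run.cfg["fit"]
    retained = _retained(run)
    stack = run.load_stack("env", "simulate").subset(retained)
    spec = maxent.FeatureSpec(types=tuple(fc["feature_types"]))
    periods = sorted(p.name for p in (run.outdir / "env_future").iterdir())
    for species in ("snail", "crop"):
        occ = read_occurrences(run.need(f"occ/{species}.csv", "simulate"))
        bg = maxent.sample_background(
            stack, min(fc["background_n"], stack.data_cells().size),
            seed=_stage_seed(run.cfg["seed"], "fit"))
        model = maxent.fit(occ, bg, stack, spec=spec, reg_beta=fc["reg_beta"])
        for period in periods:
            fstack = run.load_stack(f"env_future/{period}",
                                    "simulate").subset(retained)
            run.put_grid(maxent.predict(model, fstack),
                         "suitability_future", period, f"{species}.asc")


def _stage_overlap(run: _Run, seed: int) -> None:
    c = run.cfg["overlap"]
    maps = {}
    for species in ("snail", "crop"):
        suit = read_ascii_grid(
            run.need(f"suitability/{species}_current.asc", "fit"))
        maps[species] = evalmetrics.binarize(suit, _read_mtss(run, species))
        run.put_grid(maps[species], "overlap", f"{species}_presence.asc")
    both = risk.overlap_map(maps["snail"], maps["crop"])
    run.put_grid(both, "overlap", "overlap.asc")
    prop = risk.proportional_overlap(maps["snail"], maps["crop"])
    bands = latitude_band_counts(both, c["band_width"])
    run.put_table(bands, "overlap", "overlap_by_latitude.csv")
    stats = {
        "snail_suitable_cells": int(np.nansum(maps["snail"].values == 1)),
        "crop_suitable_cells": int(np.nansum(maps["crop"].values == 1)),
        "overlap_cells": int(np.nansum(both.values == 1)),
        "proportional_overlap": prop,
    }
    run.put_text(json.dumps(stats, indent=2, sort_keys=True) + "\n",
                 "overlap", "overlap_stats.json")


def _stage_risk(run: _Run, seed: int) -> None:
    c = run.cfg["risk"]
    snail_suit = read_ascii_grid(
        run.need("suitability/snail_current.asc", "fit"))
    crop_presence = read_ascii_grid(
        run.need("overlap/crop_presence.asc", "overlap"))
    landcover = read_ascii_grid(run.need("landcover.asc", "simulate"))
    occ = read_occurrences(run.need("occ/snail.csv", "simulate"))

    snail_cat = evalmetrics.categorize(snail_suit, _read_mtss(run, "snail"))
    crop_mask = crop_presence.mask & (crop_presence.values == 1)
    restrict = np.where(crop_mask, snail_cat.values, np.nan)
    suit_comp = snail_cat.with_values(restrict)

    lc = risk.landcover_component(landcover,
                                  set(float(x) for x in c["forest_classes"]))
    lc_comp = lc.with_values(np.where(crop_mask, lc.values, np.nan))
    dist_comp = proximity_component(crop_presence, occ)

    components = risk.RiskComponents(suitability=suit_comp,
                                     landcover=lc_comp, distance=dist_comp)
    risk_map = risk.invasion_risk(components)
    run.put_grid(risk_map, "risk", "invasion_risk.asc")
    run.put_grid(snail_cat, "risk", "snail_categories.asc")
    run.put_text(
        "\n".join(f"{k} {v}" for k, v in
                  evalmetrics.CATEGORY_LABELS.items()) + "\n",
        "risk", "snail_categories.legend.txt")
    bands = risk.risk_by_latitude(risk_map, c["high_threshold"],
                                  c["band_width"])
    run.put_table(bands, "risk", "risk_by_latitude.csv")


def _stage_disperse(run: _Run, seed: int) -> None:
    c = run.cfg["disperse"]
    params = dispersal.DispersalParams(
        rc_threshold=c["rc_threshold"],
        enc_chg_steps=run.cfg["simulate"]["future_periods"],
        disp_steps=c["disp_steps"], ini_mat_age=c["ini_mat_age"],
        propagule_prod=c["propagule_prod"], ldd_freq=c["ldd_freq"],
        ldd_min_dist=c["ldd_min_dist"], ldd_max_dist=c["ldd_max_dist"],
        kernel=tuple(c["kernel"]), replicates=c["replicates"], seed=seed)

    landcover = read_ascii_grid(run.need("landcover.asc", "simulate"))
    # transformed (non-forest) land is the barrier
    barrier = landcover.with_values(
        np.where(landcover.mask, 1.0 - landcover.values, np.nan))
    initial = read_ascii_grid(
        run.need("overlap/snail_presence.asc", "overlap"))
    periods = sorted(p.name for p in
                     (run.outdir / "suitability_future").iterdir())
    series = [dispersal.suitability_to_1000(read_ascii_grid(
        run.need(f"suitability_future/{period}/snail.asc", "project")))
        for period in periods]
    crop_series = []
    mtss_crop = _read_mtss(run, "crop")
    for period in periods:
        g = read_ascii_grid(
            run.need(f"suitability_future/{period}/crop.asc", "project"))
        crop_series.append(evalmetrics.binarize(g, mtss_crop))

    summary = {}
    for scenario in dispersal.SCENARIOS:
        occ_series, history = dispersal.run(initial, barrier, series,
                                            params, scenario=scenario)
        for period, g in zip(periods, occ_series):
            run.put_grid(g, "disperse", scenario, f"{period}.asc")
        if len(history):
            run.put_table(history, "disperse", scenario, "history.csv")
        summary[scenario] = [float(np.nansum(g.values)) for g in occ_series]
        if scenario == "constrained":
            future = risk.future_risk_series(occ_series, crop_series)
            for period, g in zip(periods, future):
                run.put_grid(g, "disperse", "future_risk", f"{period}.asc")
    run.put_text(json.dumps(summary, indent=2, sort_keys=True) + "\n",
                 "disperse", "occupied_cells.json")


def _stage_demography(run: _Run, seed: int) -> None:
    c = run.cfg["demography"]
    sites = pd.read_csv(run.need("sites.csv", "simulate"))
    suit = read_ascii_grid(run.need("suitability/snail_current.asc", "fit"))
    records = demo.assign_sites(sites, suit, _read_mtss(run, "snail"))
    rows = []
    for parameter in ("adults", "juveniles"):
        mean_a, mean_b, t, p = demo.compare_groups(
            records, set(c["group_high"]), set(c["group_low"]), parameter)
        rows.append({"parameter": parameter, "mean_high": mean_a,
                     "mean_low": mean_b, "t": t, "p": p})
    run.put_table(pd.DataFrame(rows), "demography", "comparisons.csv")
    run.put_table(pd.DataFrame(
        [{"site_id": r.site_id, "lon": r.lon, "lat": r.lat,
          "suitability": r.suitability_value, "category": r.category,
          "adults": r.adults, "juveniles": r.juveniles}
         for r in records]), "demography", "site_records.csv")


def _stage_report(run: _Run, seed: int) -> None:
    summary: dict = {}
    ev = run.need("evaluate/replicates.csv", "evaluate")
    df = pd.read_csv(ev)
    for species, grp in df.groupby("species"):
        summary[species] = {
            "auc_train_mean": float(grp["auc_train"].mean()),
            "auc_test_mean": float(grp["auc_test"].mean()),
            "tss_mean": float(grp["tss"].mean()),
            "mtss_mean": float(grp["mtss_threshold"].mean()),
        }
    stats = json.loads(
        run.need("overlap/overlap_stats.json", "overlap").read_text())
    summary["overlap"] = stats
    occ = json.loads(
        run.need("disperse/occupied_cells.json", "disperse").read_text())
    summary["dispersal_occupied_cells"] = occ
    comp = pd.read_csv(run.need("demography/comparisons.csv", "demography"))
    summary["demography"] = comp.to_dict(orient="records")
    run.put_text(json.dumps(summary, indent=2, sort_keys=True) + "\n",
                 "report", "summary.json")


_STAGE_FUNCS = {
    "simulate": _stage_simulate, "screen": _stage_screen,
    "fit": _stage_fit, "evaluate": _stage_evaluate,
    "project": _stage_project, "overlap": _stage_overlap,
    "risk": _stage_risk, "disperse": _stage_disperse,
    "demography": _stage_demography, "report": _stage_report,
}


def run_pipeline(config: dict, stages: list[str] | None = None) -> dict:
    """Run the requested stages in dependency order; return the manifest."""
    stages = list(stages) if stages else list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s): {unknown}")
    ordered = [s for s in STAGES if s in stages]
    run = _Run(config)
    snapshot = run.path("config_resolved.yaml")
    snapshot.write_text(yaml.safe_dump(config, sort_keys=True))
    run.artifacts.append(snapshot)

    for stage in ordered:
        t0 = time.time()
        seed = _stage_seed(config["seed"], stage)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            _STAGE_FUNCS[stage](run, seed)
        for w in caught:
            run.warnings.append(f"{stage}: {w.message}")
        logger.info("stage %-10s done in %.2fs", stage, time.time() - t0)

    manifest = {
        "stages": ordered,
        "seed": config["seed"],
        "warnings": run.warnings,
        "artifacts": {
            str(p.relative_to(run.outdir)): _sha256(p)
            for p in sorted(set(run.artifacts))},
    }
    mpath = run.path("manifest.json")
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
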