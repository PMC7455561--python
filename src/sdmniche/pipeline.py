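"""End-to-end orchestration: config → staged run → manifest.

The pipeline mirrors how ensemble habitat-suitability studies are
actually conducted: ingest and clean occurrences (deduplicate, thin to a
minimum distance), derive terrain predictors from elevation, align all
layers on one grid, screen collinearity with stepwise VIF, draw a
background sample, split presences 80/20, fit the five algorithms,
evaluate each and their ensemble, derive response curves and permutation
importance, binarize the ensemble at the max-TSS threshold to estimate
suitable area, repeat per species, and finish with a pairwise niche-
overlap matrix.

Every stage logs its record counts (raw → deduplicated → thinned, cells
masked, background drawn), and a single global seed deterministically
derives per-stage seeds by stage-name hashing, so reruns with the same
config are bit-identical and stages can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from . import models as md
from . import occurrences as occ
from . import overlap as ov
from . import predictors as pe
from . import synthetic as syn
from .raster import (PROJECTED, PredictorStack, RasterGrid, SuitabilityMap,
                     align_stack, read_ascii_grid, write_ascii_grid)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "make_demo",
           "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from the global seed (below 2^31)."""
    h = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serializable as flat YAML."""

    occurrences: dict[str, str]          # species -> CSV path
    rasters: dict[str, str]              # predictor -> .asc path
    out_dir: str
    rng_seed: int
    crs_kind: str = PROJECTED
    elevation_layer: str = "elevation"
    derive_terrain: bool = True
    th_block: int = 4                    # fine cells per TH block side
    thin_km: float = 5.0
    thin_repeats: int = 100
    vif_threshold: float = 10.0
    algorithms: tuple[str, ...] = md.ALGORITHMS
    hyperparameters: dict = field(default_factory=dict)
    train_fraction: float = 0.8
    background_n: int = 10000
    ensemble_rule: str = "uniform"       # or "tss"
    binarization: str = "max-tss"
    focal_species: str | None = None     # response curves + importance target

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["algorithms"] = tuple(raw.get("algorithms", md.ALGORITHMS))
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class RunManifest:
    """Record of one run: config snapshot, counts, outputs, timings."""

    config: dict
    counts: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    wall_clock: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "counts": self.counts,
             "outputs": self.outputs, "wall_clock": self.wall_clock},
            indent=2, sort_keys=True))


def _json_out(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full analysis; any stage failure aborts with its name."""
    out = Path(config.out_dir)
    for sub in ("occurrences", "rasters", "maps", "models", "metrics",
                "curves"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config={k: (list(v) if isinstance(v, tuple) else v)
                                   for k, v in config.__dict__.items()})
    stage = "setup"

    def record(path: Path) -> Path:
        manifest.outputs.append(str(path.relative_to(out)))
        return path

    try:
        t0 = time.perf_counter()
        # --- ingest rasters -------------------------------------------------
        stage = "ingest-rasters"
        layers = {name: read_ascii_grid(p, config.crs_kind)
                  for name, p in config.rasters.items()}

        # --- terrain derivation --------------------------------------------
        stage = "terrain"
        if config.derive_terrain and config.elevation_layer in layers:
            elev = layers[config.elevation_layer]
            layers["slope"] = pe.compute_slope(elev)
            layers["th"] = pe.compute_topographic_heterogeneity(
                elev, config.th_block)

        # --- alignment ------------------------------------------------------
        stage = "align"
        ref = next(iter(config.rasters))
        stack = align_stack(layers, reference=ref)
        manifest.counts["cells_valid"] = int(stack.grid.valid.sum())
        manifest.counts["cells_masked"] = int(stack.mask.sum())

        # --- VIF screening ---------------------------------------------------
        stage = "vif"
        table = stack.table()
        n_sample = min(len(table), 10000)
        idx = np.random.default_rng(
            stage_seed(config.rng_seed, "vif")).choice(
                len(table), n_sample, replace=False)
        vif_df = pd.DataFrame(table[np.sort(idx)], columns=stack.names)
        report = pe.vif_stepwise(vif_df, config.vif_threshold)
        report.to_json(record(out / "vif.json"))
        keep = report.retained
        stack = PredictorStack({n: stack[n] for n in keep})
        manifest.counts["predictors_retained"] = len(keep)
        manifest.counts["predictors_removed"] = len(report.removed)
        for name in keep:
            write_ascii_grid(stack[name], record(out / "rasters" / f"{name}.asc"))
        manifest.wall_clock["prepare"] = round(time.perf_counter() - t0, 3)

        # --- occurrences + per-species modelling ----------------------------
        stage = "background"
        t0 = time.perf_counter()
        n_bg = min(config.background_n, int(stack.grid.valid.sum()))
        background = syn.sample_background(
            stack, n_bg, stage_seed(config.rng_seed, "background"))
        bg_table = occ.extract_env_values(background, stack)
        manifest.counts["background_drawn"] = len(bg_table)

        species_maps: dict[str, SuitabilityMap] = {}
        land_table = pd.DataFrame(stack.table(), columns=stack.names)
        focal = config.focal_species or next(iter(config.occurrences))
        for species, path in config.occurrences.items():
            stage = f"occurrences[{species}]"
            raw = occ.read_occurrences(path, species_label=species,
                                       crs_kind=config.crs_kind,
                                       x_col="x" if config.crs_kind == PROJECTED
                                       else "lon",
                                       y_col="y" if config.crs_kind == PROJECTED
                                       else "lat")
            manifest.counts[f"{species}_raw"] = len(raw)
            dedup = occ.deduplicate(raw, stack.transform.cell_size)
            manifest.counts[f"{species}_deduplicated"] = len(dedup)
            thinned = occ.spatial_thin(
                dedup, config.thin_km,
                stage_seed(config.rng_seed, f"thin:{species}"),
                config.thin_repeats)
            manifest.counts[f"{species}_thinned"] = len(thinned)
            occ.write_occurrences(
                thinned, record(out / "occurrences" / f"{species}_thinned.csv"))

            stage = f"split[{species}]"
            train, test = ev.split_train_test(
                thinned, config.train_fraction,
                stage_seed(config.rng_seed, f"split:{species}"))
            train_table = occ.extract_env_values(train, stack)
            test_table = occ.extract_env_values(test, stack)
            manifest.counts[f"{species}_train"] = len(train_table)
            manifest.counts[f"{species}_test"] = len(test_table)

            maps, evals, metrics = [], [], {}
            for alg in config.algorithms:
                stage = f"fit[{species}:{alg}]"
                spec_ = md.ModelSpec(alg, config.hyperparameters.get(alg, {}),
                                     stage_seed(config.rng_seed,
                                                f"fit:{species}:{alg}"))
                model = md.fit_model(spec_, train_table, bg_table)
                md.save_model(model, record(out / "models" / f"{species}_{alg}.pkl"))
                smap = md.predict_suitability(model, stack)
                write_ascii_grid(smap.grid,
                                 record(out / "maps" / f"{species}_{alg}.asc"))
                stage = f"evaluate[{species}:{alg}]"
                res = ev.evaluate_scores(
                    model.predict_table(test_table),
                    model.predict_table(bg_table),
                    smap.grid.values[smap.grid.valid])
                maps.append(smap)
                evals.append(res)
                metrics[alg] = res.to_dict()
                if alg == "glm" and species == focal:
                    for pred in model.predictors:
                        curve = md.response_curve(model, pred)
                        curve.to_frame().to_csv(
                            record(out / "curves" / f"{species}_{pred}.csv"),
                            index=False, float_format="%.8g")

            stage = f"ensemble[{species}]"
            weights = "uniform" if config.ensemble_rule == "uniform" else "tss"
            emap = ev.ensemble_combine(maps, weights, evals)
            write_ascii_grid(emap.grid,
                             record(out / "maps" / f"{species}_ensemble.asc"))
            pres_scores = _scores_at(emap, test)
            bg_scores = _scores_at(emap, background)
            eres = ev.evaluate_scores(pres_scores, bg_scores,
                                      emap.grid.values[emap.grid.valid])
            metrics["ensemble"] = eres.to_dict()
            # Boyce over all presences: the calibration metric is unstable
            # on small held-out sets, so the all-presence value is the
            # headline one; the held-out value stays in 'boyce'.
            try:
                metrics["ensemble"]["boyce_all_presences"] = ev.boyce_index(
                    _scores_at(emap, thinned),
                    emap.grid.values[emap.grid.valid])
            except ValueError:
                metrics["ensemble"]["boyce_all_presences"] = None

            stage = f"binarize[{species}]"
            _, area = ev.binarize_and_area(emap, eres.threshold)
            metrics["ensemble"]["suitable_area_km2"] = round(area, 3)
            _json_out(record(out / "metrics" / f"{species}_metrics.json"),
                      metrics)
            species_maps[species] = emap

            if species == focal:
                stage = f"importance[{species}]"
                imp_table = pd.concat([train_table, bg_table],
                                      ignore_index=True)
                # ensemble prediction over a table = weighted member mean
                members = [md.load_model(out / "models" / f"{species}_{a}.pkl")
                           for a in config.algorithms]
                w = np.asarray(emap.metadata["weights"])

                def _ensemble_predict(tbl):
                    return sum(wi * m.predict_table(tbl)
                               for wi, m in zip(w, members))
                imp = ev.variable_importance(
                    _ensemble_predict, imp_table, n_repeats=10,
                    rng_seed=stage_seed(config.rng_seed, "importance"))
                _json_out(record(out / f"importance_{species}.json"),
                          {"importance": imp.importance,
                           "ranked": imp.ranked()})
        manifest.wall_clock["modelling"] = round(time.perf_counter() - t0, 3)

        # --- niche overlap ----------------------------------------------------
        t0 = time.perf_counter()
        stage = "overlap"
        if len(species_maps) >= 2:
            dmat = ov.overlap_matrix(species_maps, "schoener_d")
            imat = ov.overlap_matrix(species_maps, "hellinger_i")
            dmat.to_csv(record(out / "overlap_schoener_d.csv"),
                        float_format="%.6f")
            imat.to_csv(record(out / "overlap_hellinger_i.csv"),
                        float_format="%.6f")
            _json_out(record(out / "overlap.json"),
                      {"schoener_d": json.loads(dmat.to_json()),
                       "hellinger_i": json.loads(imat.to_json()),
                       "n_cells": int(stack.grid.valid.sum())})
        else:
            logger.info("single species run; overlap stage skipped")
            manifest.counts["overlap_skipped"] = 1
        manifest.wall_clock["overlap"] = round(time.perf_counter() - t0, 3)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.to_json(out / "manifest.json")
    return manifest


def _scores_at(smap: SuitabilityMap, points: occ.OccurrenceSet) -> np.ndarray:
    """Suitability of the cells containing the given points."""
    g = smap.grid
    r, c = g.transform.index(points.xy[:, 0], points.xy[:, 1], g.shape)
    inside = (r >= 0) & (c >= 0)
    vals = g.values[r[inside], c[inside]]
    return vals[np.isfinite(vals)]


# ---------------------------------------------------------------------------
# packaged demo scenario

DEMO_SCENARIOS = ("two-prey-demo",)


def make_demo(scenario_name: str, out_dir: str | Path,
              rng_seed: int = 1234) -> RunConfig:
    """Write a ready-to-run synthetic fixture set and its config.

    ``two-prey-demo``: a 120×120 km landscape of four predictors (bio5,
    bio12, bio18, elevation), one predator-like species with a gaussian
    precipitation niche centred at 600 mm, one prey species with a very
    similar niche and one with a distant niche.  Occurrence counts echo
    field-study sample sizes (45 / 200 / 110 raw records).
    """
    if scenario_name not in DEMO_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario_name!r}; "
                         f"known: {list(DEMO_SCENARIOS)}")
    out = Path(out_dir)
    (out / "rasters").mkdir(parents=True, exist_ok=True)
    (out / "occurrences").mkdir(parents=True, exist_ok=True)
    scenario = syn.SyntheticScenario(
        shape=(120, 120),
        ranges={"bio5": (18.0, 48.0), "bio12": (50.0, 1200.0),
                "bio18": (0.0, 300.0), "elevation": (0.0, 3500.0)},
        correlation=np.array([[1.0, -0.5, -0.3, -0.4],
                              [-0.5, 1.0, 0.6, 0.5],
                              [-0.3, 0.6, 1.0, 0.3],
                              [-0.4, 0.5, 0.3, 1.0]]),
        rng_seed=stage_seed(rng_seed, "demo-stack"))
    stack = syn.generate_env_stack(scenario)
    raster_paths = {}
    for name in stack.names:
        p = out / "rasters" / f"{name}.asc"
        write_ascii_grid(stack[name], p)
        raster_paths[name] = str(p)

    species = {
        "predator": (syn.VirtualSpecies({
            "bio12": syn.GaussianResponse(600.0, 150.0),
            "bio5": syn.GaussianResponse(40.0, 8.0)}), 45),
        "prey_similar": (syn.VirtualSpecies({
            "bio12": syn.GaussianResponse(630.0, 160.0),
            "bio5": syn.GaussianResponse(39.0, 8.0)}), 200),
        "prey_distant": (syn.VirtualSpecies({
            "bio12": syn.GaussianResponse(150.0, 80.0),
            "bio5": syn.GaussianResponse(28.0, 6.0)}), 110),
    }
    occurrence_paths = {}
    for name, (vs, n) in species.items():
        suit = syn.suitability_surface(vs, stack)
        pts = syn.sample_presences(suit, n,
                                   stage_seed(rng_seed, f"demo-{name}"), name)
        p = out / "occurrences" / f"{name}.csv"
        occ.write_occurrences(pts, p)
        occurrence_paths[name] = str(p)

    config = RunConfig(occurrences=occurrence_paths, rasters=raster_paths,
                       out_dir=str(out / "run"), rng_seed=rng_seed,
                       crs_kind=PROJECTED, thin_km=2.0, thin_repeats=20,
                       background_n=2000, focal_species="predator")
    config.to_yaml(out / "config.yaml")
    return config
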