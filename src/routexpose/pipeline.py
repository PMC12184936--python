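"""End-to-end orchestration of the six analysis stages.

generate -> grid -> route -> exposure -> train -> interpret

Each stage reads its upstream artifacts from the run's output directory and
writes its own, so any stage can be re-run independently; a missing upstream
artifact raises :class:`DependencyError` naming the stage to run first.  A
single global seed deterministically derives one sub-seed per stage, so one
number reproduces a whole run byte-for-byte.  Stage events are appended to
``run.log.jsonl`` as machine-readable JSON lines.
"""

from __future__ import annotations

import dataclasses
import json
import pickle
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from . import io
from .errors import DependencyError, NoRouteError, RoutexposeError
from .exposure import expand_flows, trip_features
from .hexgrid import (
    aggregate_buildings,
    aggregate_streets,
    assign_noise,
    count_pois,
    get_scheme,
    make_grid,
)
from .interpretation import gini_importance, partial_dependence, plot_importance, plot_pdp
from .modeling import (
    ModelConfig,
    NearMissUndersampler,
    evaluate,
    feature_columns,
    prune_correlated,
    split,
    train_forest,
    tune_forest,
)
from .router import build_network, shortest_itinerary
from .synthetic_city import (
    MODES,
    CityConfig,
    ODFlow,
    UtilityParams,
    flows_to_frame,
    generate_city,
    generate_flows,
    suppress_small_flows,
)

__all__ = ["RunConfig", "STAGES", "run_all", "run_stage"]

STAGES = ("generate", "grid", "route", "exposure", "train", "interpret")


@dataclass
class RunConfig:
    """Everything one run needs: sub-configs, output directory, global seed."""

    city: CityConfig = field(default_factory=CityConfig)
    utility: UtilityParams = field(default_factory=UtilityParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    n_flows: int = 2000
    suppression_threshold: int = 10
    cell_area: float = 250_000.0
    tune: bool = False
    make_plots: bool = False
    out_dir: str = "run_output"
    seed: int = 1

    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))

        return json.dumps(dataclasses.asdict(self), default=enc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        doc = json.loads(text)
        kwargs = dict(doc)
        if "city" in doc:
            city = dict(doc["city"])
            for k in ("bbox", "poi_categories"):
                if k in city:
                    city[k] = tuple(city[k])
            kwargs["city"] = CityConfig(**city)
        if "utility" in doc:
            kwargs["utility"] = UtilityParams(**doc["utility"])
        if "model" in doc:
            model = dict(doc["model"])
            for k in ("tree_grid", "max_features_grid", "keep_list"):
                if model.get(k) is not None:
                    model[k] = tuple(model[k])
            kwargs["model"] = ModelConfig(**model)
        return cls(**kwargs)

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the global seed; stable across runs."""
        return int(
            np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())]).generate_state(1)[0]
            % (2**31)
        )


def _log(out: Path, stage: str, **fields) -> None:
    record = {"stage": stage, **fields}
    with open(out / "run.log.jsonl", "a") as fh:
        fh.write(json.dumps(record, sort_keys=True) + "\n")


def _need(out: Path, filename: str, producer: str) -> Path:
    path = out / filename
    if not path.exists():
        raise DependencyError(f"missing artifact {filename!r}; run stage {producer!r} first")
    return path


# --------------------------------------------------------------------------
# stages


def stage_generate(cfg: RunConfig, out: Path) -> dict:
    seed = cfg.stage_seed("generate")
    city_cfg = dataclasses.replace(cfg.city, seed=seed)
    city = generate_city(city_cfg)
    flows = generate_flows(city, cfg.utility, cfg.n_flows, seed=seed + 1)
    kept = suppress_small_flows(flows, cfg.suppression_threshold)

    io.write_layer(city.streets, out / "streets.geojson")
    io.write_layer(city.buildings, out / "buildings.geojson")
    io.write_layer(city.pois, out / "pois.geojson")
    io.write_layer(city.noise, out / "noise.geojson")
    io.write_table(flows_to_frame(flows), out / "flows_raw.csv")
    io.write_table(flows_to_frame(kept), out / "flows.csv")
    info = {
        "seed": seed,
        "flows_generated": len(flows),
        "flows_suppressed": len(flows) - len(kept),
        "flows_retained": len(kept),
    }
    _log(out, "generate", **info)
    return info


def stage_grid(cfg: RunConfig, out: Path) -> dict:
    streets = io.read_layer(_need(out, "streets.geojson", "generate"))
    buildings = io.read_layer(_need(out, "buildings.geojson", "generate"))
    pois = io.read_layer(_need(out, "pois.geojson", "generate"))
    noise = io.read_layer(_need(out, "noise.geojson", "generate"))
    scheme = get_scheme(cfg.city.noise_scheme_name)

    grid = make_grid(cfg.city.bbox, cell_area=cfg.cell_area,
                     categories=cfg.city.poi_categories)
    grid = aggregate_buildings(grid, buildings)
    grid = aggregate_streets(grid, streets)
    grid = count_pois(grid, pois)
    grid = assign_noise(grid, noise, scheme)
    io.write_layer(grid.cells.drop(columns=["row", "col"]), out / "grid.geojson")
    info = {"cells": len(grid.cells), "cell_area_m2": cfg.cell_area}
    _log(out, "grid", **info)
    return info


def _load_flows(out: Path) -> list[ODFlow]:
    frame = io.read_table(_need(out, "flows.csv", "generate"))
    return [
        ODFlow(
            origin=(row.origin_x, row.origin_y),
            dest=(row.dest_x, row.dest_y),
            mode=row.mode,
            count=int(row.count_),
        )
        for row in frame.rename(columns={"count": "count_"}).itertuples()
    ]


def stage_route(cfg: RunConfig, out: Path) -> dict:
    streets = io.read_layer(_need(out, "streets.geojson", "generate"))
    flows = _load_flows(out)
    net = build_network(streets)

    features = []
    dropped = 0
    for i, flow in enumerate(flows):
        try:
            it = shortest_itinerary(net, flow.origin, flow.dest, flow.mode)
        except NoRouteError:
            dropped += 1
            _log(out, "route", event="no_route", flow=i, mode=flow.mode)
            continue
        features.append(
            {
                "geometry": it.geometry,
                "flow_id": i,
                "mode": it.mode,
                "count": flow.count,
                "total_distance": it.total_distance,
            }
        )
    io.write_layer(pd.DataFrame(features), out / "itineraries.geojson")
    info = {"routed": len(features), "no_route_dropped": dropped}
    _log(out, "route", **info)
    return info


@dataclass
class _ItineraryView:
    """Just enough of an itinerary for exposure accounting."""

    origin: tuple
    dest: tuple
    mode: str
    geometry: LineString
    total_distance: float


def stage_exposure(cfg: RunConfig, out: Path) -> dict:
    its = io.read_layer(_need(out, "itineraries.geojson", "route"))
    grid_cells = io.read_layer(_need(out, "grid.geojson", "grid"))
    scheme = get_scheme(cfg.city.noise_scheme_name)

    from .hexgrid import HexGrid, hexagon_edge_for_area

    grid_cells = grid_cells.sort_values("cell_id").reset_index(drop=True)
    grid_cells["row"] = 0
    grid_cells["col"] = 0
    grid = HexGrid(
        cells=grid_cells,
        cell_area=cfg.cell_area,
        edge_length=hexagon_edge_for_area(cfg.cell_area),
        bbox=cfg.city.bbox,
        categories=cfg.city.poi_categories,
        scheme=scheme,
    )
    records = []
    for row in its.itertuples():
        coords = list(row.geometry.coords)
        view = _ItineraryView(
            origin=coords[0],
            dest=coords[-1],
            mode=row.mode,
            geometry=row.geometry,
            total_distance=row.total_distance,
        )
        records.append((trip_features(view, grid, scheme), int(row.count)))
    table = expand_flows(records, scheme)
    io.write_table(table, out / "trips.csv")
    table.to_parquet(out / "trips.parquet", index=False)
    info = {"flows_expanded": len(records), "individuals": len(table)}
    _log(out, "exposure", **info)
    return info


def stage_train(cfg: RunConfig, out: Path) -> dict:
    table = io.read_table(_need(out, "trips.csv", "exposure"))
    mc = cfg.model
    seed = cfg.stage_seed("train")

    retained = prune_correlated(table, mc.correlation_threshold, mc.keep_list)
    pruned = table[["individual_id", "mode"] + retained]
    train, test = split(pruned, mc.test_fraction, seed=seed)

    sampler = NearMissUndersampler(variant=mc.nearmiss_variant)
    Xb, yb = sampler.fit_resample(train[retained], train["mode"])
    balanced = Xb.copy()
    balanced.insert(0, "mode", yb)

    if cfg.tune:
        (n_trees, max_features), grid = tune_forest(balanced, mc)
        io.write_table(grid, out / "tuning_grid.csv")
    else:
        n_trees = mc.n_trees_final or max(mc.tree_grid)
        max_features = mc.max_features_final or "sqrt"
    model = train_forest(balanced, n_trees, max_features, seed=seed)
    report = evaluate(model, test[["mode"] + retained])

    with open(out / "model.pkl", "wb") as fh:
        pickle.dump(model, fh)
    io.write_json(
        {
            "features": retained,
            "n_trees": n_trees,
            "max_features": max_features,
            "seed": seed,
            "class_order": list(MODES),
            "oob_score": model.oob_score_,
        },
        out / "model_meta.json",
    )
    io.write_json(report.to_dict(), out / "eval.json")
    report.confusion.to_csv(out / "confusion.csv")
    info = {
        "seed": seed,
        "features_retained": len(retained),
        "train_rows": len(train),
        "balanced_rows": len(balanced),
        "test_rows": len(test),
        "n_trees": n_trees,
        "max_features": max_features if isinstance(max_features, int) else str(max_features),
        "accuracy": report.accuracy,
        "oob_score": model.oob_score_,
    }
    _log(out, "train", **info)
    return info


def stage_interpret(cfg: RunConfig, out: Path) -> dict:
    meta = io.read_json(_need(out, "model_meta.json", "train"))
    with open(_need(out, "model.pkl", "train"), "rb") as fh:
        model = pickle.load(fh)
    table = io.read_table(_need(out, "trips.csv", "exposure"))

    imp = gini_importance(model)
    io.write_table(imp, out / "importance.csv")
    results = [
        partial_dependence(model, table[meta["features"]], feat)
        for feat in meta["features"]
    ]
    pdp = pd.concat([r.to_frame() for r in results], ignore_index=True)
    io.write_table(pdp, out / "pdp.csv")
    if cfg.make_plots:
        plot_importance(imp, out / "importance.png")
        plot_pdp(results, out / "pdp.png")
    info = {"top_feature": imp.iloc[0]["feature"], "features": len(results)}
    _log(out, "interpret", **info)
    return info


_STAGE_FUNCS = {
    "generate": stage_generate,
    "grid": stage_grid,
    "route": stage_route,
    "exposure": stage_exposure,
    "train": stage_train,
    "interpret": stage_interpret,
}


def run_stage(cfg: RunConfig, stage: str) -> dict:
    if stage not in _STAGE_FUNCS:
        raise DependencyError(f"unknown stage {stage!r}; stages: {STAGES}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return _STAGE_FUNCS[stage](cfg, out)


def run_all(cfg: RunConfig) -> dict:
    """Execute all six stages; returns (and writes) the run report.

    On a stage failure the report written so far names the failed stage, so
    the run can resume from the persisted upstream artifacts.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(cfg.to_json())
    report: dict = {"seed": cfg.seed, "stages": {}}
    t0 = time.time()
    for stage in STAGES:
        try:
            report["stages"][stage] = _STAGE_FUNCS[stage](cfg, out)
        except RoutexposeError as err:
            report["failed_stage"] = stage
            report["error"] = str(err)
            io.write_json(report, out / "report.json")
            raise
    train_info = report["stages"]["train"]
    imp = io.read_table(out / "importance.csv")
    report["accuracy"] = train_info["accuracy"]
    report["selected_hyperparameters"] = {
        "n_trees": train_info["n_trees"],
        "max_features": train_info["max_features"],
    }
    report["top5_importance"] = [
        {"feature": r.feature, "importance": float(r.importance)}
        for r in imp.head(5).itertuples()
    ]
    report["elapsed_s"] = round(time.time() - t0, 2)
    io.write_json(report, out / "report.json")
    return report
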