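"""End-to-end orchestration: simulate -> decadal means -> velocity fields ->
filters -> centroids -> comparison -> statistics, from a single config.

A :class:`RunConfig` (constructable from a YAML file) fixes the scenario or
input paths, the decade windows, the estimator list and all thresholds; a
single master seed is fanned out deterministically to the per-stage
generators so stages can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ranges import build_tracks, write_tracks_csv
from .stats import build_comparison, fit_table, heading_summary, mixed_fit
from .synthetic import (
    FieldScenario,
    SpeciesScenario,
    make_dem,
    make_species_records,
    make_temperature_series,
    read_records_csv,
)
from .velocity import (
    GriddedField,
    MatchConfig,
    VelocityField,
    decadal_mean,
    gradient_velocity,
    match_velocity,
)

log = logging.getLogger("climvel")


@dataclass
class RunConfig:
    """Everything one end-to-end run needs.

    Either synthetic scenarios (``field_scenario``/``species_scenario``) or
    input paths (``climate_dir``/``records_csv``/``dem_path``) supply the
    data; decade windows are half-open ``[start, start+10)`` pairs.
    """

    decades: List[Tuple[int, int]] = field(default_factory=lambda: [(1960, 1970), (1970, 1980)])
    mode: str = "birds"
    methods: List[str] = field(default_factory=lambda: ["gradient", "match"])
    min_grad: float = 1e-4
    outlier_threshold: float = 1000.0
    split_lon: Optional[float] = -100.0
    first_to_last: bool = True
    elevation: bool = True
    dem_kind: str = "linear_slope"
    dem_slope: float = 5.0
    match: MatchConfig = field(default_factory=MatchConfig)
    field_scenario: Optional[FieldScenario] = None
    species_scenario: Optional[SpeciesScenario] = None
    climate_dir: Optional[str] = None
    records_csv: Optional[str] = None
    dem_path: Optional[str] = None
    advection: str = "match_field"  # prescribed | gradient_field | match_field
    prescribed_velocity: Tuple[float, float] = (0.0, 2.0)
    out_dir: str = "climvel_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "field_scenario" in raw and isinstance(raw["field_scenario"], dict):
            raw["field_scenario"] = FieldScenario(**raw["field_scenario"])
        if "species_scenario" in raw and isinstance(raw["species_scenario"], dict):
            raw["species_scenario"] = SpeciesScenario(**raw["species_scenario"])
        if "match" in raw and isinstance(raw["match"], dict):
            raw["match"] = MatchConfig(**raw["match"])
        if "decades" in raw:
            raw["decades"] = [tuple(d) for d in raw["decades"]]
        if "prescribed_velocity" in raw:
            raw["prescribed_velocity"] = tuple(raw["prescribed_velocity"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return {f.name: convert(getattr(self, f.name)) for f in dataclasses.fields(self)}


def validate(config: RunConfig) -> List[str]:
    """Schema report: a list of violations (empty when the config is valid)."""
    problems = []
    if not config.methods:
        problems.append("at least one method is required")
    for m in config.methods:
        if m not in ("gradient", "match"):
            problems.append(f"unknown method {m!r}")
    if config.mode not in ("birds", "marine"):
        problems.append(f"unknown mode {config.mode!r}")
    if len(config.decades) < 2:
        problems.append("need at least two decade windows")
    ordered = sorted(config.decades)
    for d in config.decades:
        if d[1] <= d[0]:
            problems.append(f"decade window {d} is empty")
    for a, b in zip(ordered, ordered[1:]):
        if b[0] < a[1]:
            problems.append(f"decade windows {a} and {b} overlap")
    if config.decades != ordered:
        problems.append("decade windows are not in increasing order")
    if config.field_scenario is None and config.climate_dir is None:
        problems.append("no climate input: set field_scenario or climate_dir")
    if config.species_scenario is None and config.records_csv is None:
        problems.append("no records input: set species_scenario or records_csv")
    if config.elevation and config.dem_path is None and config.dem_kind is None:
        problems.append("elevation analysis requested but no DEM source")
    if config.advection == "prescribed" and config.prescribed_velocity is None:
        problems.append("prescribed advection needs prescribed_velocity")
    return problems


def _child_seeds(master: int, n: int = 4) -> List[int]:
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a manifest dict (also written to
    ``out_dir/manifest.json``).  Deterministic for a fixed master seed."""
    problems = validate(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    os.makedirs(config.out_dir, exist_ok=True)
    seeds = _child_seeds(config.seed)
    manifest = {
        "config": config.to_jsonable(),
        "version": __version__,
        "seed": config.seed,
        "stage_seconds": {},
        "outputs": {},
    }
    stage_t0 = time.time()

    def tick(stage: str):
        now = time.time()
        manifest["stage_seconds"][stage] = round(now - tick.last, 3)
        tick.last = now
        log.info("stage %s done (%.2fs)", stage, manifest["stage_seconds"][stage])

    tick.last = stage_t0

    try:
        # 1. climate fields
        if config.field_scenario is not None:
            yearly = make_temperature_series(config.field_scenario)
        else:
            yearly = []
            for name in sorted(os.listdir(config.climate_dir)):
                if not name.endswith(".nc"):
                    continue
                f = GriddedField.load(os.path.join(config.climate_dir, name))
                if f.period is None:
                    raise ValueError(f"{name} lacks period metadata")
                yearly.append((int(f.period[0]), f))
        tick("climate_input")

        means = {tuple(d): decadal_mean(yearly, d) for d in config.decades}
        pairs = list(zip(config.decades, config.decades[1:]))
        if config.first_to_last and len(config.decades) > 2:
            pairs.append((config.decades[0], config.decades[-1]))
        tick("decadal_means")

        # 2. velocity fields per decade pair
        fields = {}
        for d0, d1 in pairs:
            key = f"{d0[0]}-{d0[1]}_to_{d1[0]}-{d1[1]}"
            entry = {}
            if "gradient" in config.methods:
                entry["gradient"] = gradient_velocity(
                    means[tuple(d0)], means[tuple(d1)], min_grad=config.min_grad
                )
            if "match" in config.methods:
                mc = dataclasses.replace(config.match, seed=seeds[0])
                entry["match"] = match_velocity(means[tuple(d0)], means[tuple(d1)], mc)
            fields[(tuple(d0), tuple(d1))] = entry
            for method, vf in entry.items():
                path = os.path.join(config.out_dir, f"velocity_{method}_{key}.nc")
                vf.save(path)
                manifest["outputs"].setdefault("velocity", []).append(path)
        tick("velocity_fields")

        # 3. DEM
        dem = None
        if config.elevation:
            if config.dem_path is not None:
                dem = GriddedField.load(config.dem_path)
            else:
                ref = next(iter(means.values()))
                dem = make_dem(config.dem_kind, ref.lat, ref.lon, slope=config.dem_slope)
        tick("dem")

        # 4. records
        if config.species_scenario is not None:
            years = range(config.decades[0][0], config.decades[-1][1])
            first_pair = fields[(tuple(pairs[0][0]), tuple(pairs[0][1]))]
            if config.advection == "prescribed":
                vel = config.prescribed_velocity
            elif config.advection == "gradient_field":
                vel = first_pair["gradient"]
            else:
                vel = first_pair.get("match") or first_pair["gradient"]
            scen = dataclasses.replace(config.species_scenario, seed=seeds[1])
            records = make_species_records(scen, vel, years)
        else:
            records = read_records_csv(config.records_csv)
        tick("records")

        # 5. tracks + comparison per pair
        all_rows = []
        for d0, d1 in pairs:
            tracks = build_tracks(records, d0, d1, dem=dem, mode=config.mode)
            key = f"{d0[0]}-{d0[1]}_to_{d1[0]}-{d1[1]}"
            tpath = os.path.join(config.out_dir, f"tracks_{key}.csv")
            write_tracks_csv(tracks, tpath)
            manifest["outputs"].setdefault("tracks", []).append(tpath)
            entry = fields[(tuple(d0), tuple(d1))]
            rows = build_comparison(
                tracks,
                entry.get("gradient"),
                entry.get("match"),
                dem=dem,
                split_lon=config.split_lon,
            )
            all_rows.append(rows)
        comparison = pd.concat(all_rows, ignore_index=True) if all_rows else pd.DataFrame()
        cpath = os.path.join(config.out_dir, "comparison.csv")
        comparison.to_csv(cpath, index=False, float_format="%.8f")
        manifest["outputs"]["comparison"] = cpath
        tick("comparison")

        # 6. statistics
        components = ("lon", "lat", "elev") if config.elevation else ("lon", "lat")
        table = fit_table(
            comparison,
            methods=config.methods,
            components=components,
            outlier_threshold=config.outlier_threshold,
        )
        spath = os.path.join(config.out_dir, "fits.csv")
        table.to_csv(spath, index=False, float_format="%.8f")
        manifest["outputs"]["fits"] = spath

        mixed_rows = []
        for method in config.methods:
            for comp in components:
                try:
                    mr = mixed_fit(comparison, comp, method)
                except ValueError:
                    continue
                mixed_rows.append(
                    {
                        "method": method,
                        "component": comp,
                        "slope": mr.slope,
                        "slope_se": mr.slope_se,
                        "z": mr.z,
                        "p": mr.p,
                        "group_var": mr.group_var,
                        "n_obs": mr.n_obs,
                        "n_groups": mr.n_groups,
                        "converged": mr.converged,
                    }
                )
        mpath = os.path.join(config.out_dir, "mixed.csv")
        pd.DataFrame(mixed_rows).to_csv(mpath, index=False, float_format="%.8f")
        manifest["outputs"]["mixed"] = mpath

        heading_rows = []
        for method in config.methods:
            diffs = comparison[f"heading_diff_{method}"]
            try:
                hs = heading_summary(diffs)
            except ValueError:
                continue
            heading_rows.append(
                {
                    "method": method,
                    "circ_mean_deg": hs.circ_mean_deg,
                    "circ_sd_deg": hs.circ_sd_deg,
                    "n": hs.n,
                }
            )
        hpath = os.path.join(config.out_dir, "headings.csv")
        pd.DataFrame(heading_rows).to_csv(hpath, index=False, float_format="%.8f")
        manifest["outputs"]["headings"] = hpath
        tick("statistics")
    except Exception as exc:
        marker = os.path.join(config.out_dir, "FAILED")
        with open(marker, "w") as fh:
            fh.write(f"{type(exc).__name__}: {exc}\n")
        raise

    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
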