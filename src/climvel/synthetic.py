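"""Synthetic inputs with the statistical structure the analysis assumes.

The generator stands in for the real observational stack (volunteer bird
counts, trawl-survey presence records, reanalysis temperature fields and a
global DEM) so the whole pipeline is testable offline:

* gridded yearly temperature fields with parallel, curved or locally flat
  isotherms plus a secular warming trend;
* DEM grids with known slopes;
* species observation records whose true range centroid is advected by a
  known velocity field, with tunable tracking factor, positional noise and
  engineered inclusion-filter failures.

Everything is driven by explicit seeds; identical scenarios and seeds
produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .geo import KM_PER_DEG, displace_km
from .velocity import GriddedField, VelocityField, velocity_at

FIELD_KINDS = ("parallel", "curved", "flat_patch", "composite")
DEM_KINDS = ("flat", "linear_slope", "ridge")

RECORD_COLUMNS = ["species_id", "site_id", "year", "lat", "lon", "count", "presence"]


@dataclass
class FieldScenario:
    """Closed-form temperature-field scenario.

    The field is built from a meridional base gradient ``a`` (degC per km
    northward), a secular warming rate ``b`` (degC per yr), and optional
    longitudinal structure:

    * ``parallel``:   psi = psi0 - a*d(lat) + b*t  (t = years since start)
    * ``curved``:     adds ``curve_amp * sin(curve_wavenumber * lon)``,
      bending the isotherms while leaving their northward drift uniform
    * ``flat_patch``: parallel, but constant inside a disc of
      ``patch_radius_cells`` cells (zero gradient there)
    * ``composite``:  curved isotherms plus a longitudinally modulated
      warming rate, so the true isotherm displacement varies in space
    """

    name: str = "parallel"
    lat_min: float = 35.0
    lat_max: float = 50.0
    lon_min: float = -120.0
    lon_max: float = -95.0
    spacing: float = 0.5
    base_value: float = 10.0
    gradient: float = 0.01          # degC per northward km
    warming: float = 0.02           # degC per yr
    curve_amp: float = 2.0          # degC
    curve_wavenumber: float = 0.4   # rad per degree longitude
    patch_center: Optional[Tuple[float, float]] = None
    patch_radius_cells: float = 4.0
    warming_modulation: float = 0.5
    warming_wavenumber: float = 0.2  # rad per degree longitude
    year_start: int = 1960
    year_end: int = 1980            # exclusive

    def __post_init__(self):
        if self.name not in FIELD_KINDS:
            raise ValueError(f"unknown scenario {self.name!r}")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.year_end <= self.year_start:
            raise ValueError("empty year range")
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ValueError("degenerate extents")

    def grid(self) -> Tuple[np.ndarray, np.ndarray]:
        lat = np.arange(self.lat_min, self.lat_max + 0.5 * self.spacing, self.spacing)
        lon = np.arange(self.lon_min, self.lon_max + 0.5 * self.spacing, self.spacing)
        return lat, lon

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end)

    def evaluate(self, year: float) -> np.ndarray:
        """Field values for one year (closed form, exact)."""
        lat, lon = self.grid()
        t = float(year) - self.year_start
        y_km = KM_PER_DEG * (lat - self.lat_min)          # northward distance
        base = self.base_value - self.gradient * y_km[:, None]
        vals = np.broadcast_to(base, (lat.size, lon.size)).copy()
        if self.name in ("curved", "composite"):
            vals += self.curve_amp * np.sin(self.curve_wavenumber * lon)[None, :]
        if self.name == "composite":
            rate = self.warming * (
                1.0 + self.warming_modulation * np.sin(self.warming_wavenumber * lon)
            )
            vals += rate[None, :] * t
        else:
            vals += self.warming * t
        if self.name == "flat_patch":
            clat, clon = self.patch_center or (
                0.5 * (self.lat_min + self.lat_max),
                0.5 * (self.lon_min + self.lon_max),
            )
            r_cells = np.hypot(
                (lat[:, None] - clat) / self.spacing, (lon[None, :] - clon) / self.spacing
            )
            inside = r_cells <= self.patch_radius_cells
            centre_val = (
                self.base_value
                - self.gradient * KM_PER_DEG * (clat - self.lat_min)
                + self.warming * t
            )
            vals[inside] = centre_val
        return vals


def make_temperature_series(scenario: FieldScenario) -> List[Tuple[int, GriddedField]]:
    """One :class:`GriddedField` per year of the scenario."""
    lat, lon = scenario.grid()
    out = []
    for year in scenario.years:
        vals = scenario.evaluate(year)
        out.append((year, GriddedField(vals, lat, lon, period=(year, year + 1))))
    return out


def make_dem(
    kind: str,
    lat: np.ndarray,
    lon: np.ndarray,
    slope: float = 5.0,
    crest_lat: Optional[float] = None,
    crest_height: float = 2000.0,
) -> GriddedField:
    """A DEM grid (elevation in m; negative values are depths).

    ``flat``: all zeros.  ``linear_slope``: elevation = slope (m/km) times
    the northward distance from the south edge.  ``ridge``: a tent profile
    peaking at ``crest_lat`` so the elevation-difference sign flips across
    the crest.
    """
    if kind not in DEM_KINDS:
        raise ValueError(f"unknown DEM kind {kind!r}")
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if kind == "flat":
        elev = np.zeros((lat.size, lon.size))
    elif kind == "linear_slope":
        y_km = KM_PER_DEG * (lat - lat[0])
        elev = np.broadcast_to(slope * y_km[:, None], (lat.size, lon.size)).copy()
    else:
        crest = 0.5 * (lat[0] + lat[-1]) if crest_lat is None else crest_lat
        dist_km = KM_PER_DEG * np.abs(lat - crest)
        elev = np.broadcast_to(
            (crest_height - slope * dist_km)[:, None], (lat.size, lon.size)
        ).copy()
    return GriddedField(elev, lat, lon)


@dataclass
class SpeciesScenario:
    """Synthetic species-record scenario.

    Each species holds a true centroid advected yearly at ``tracking`` times
    the local velocity (plus an optional per-species constant velocity bias,
    the random intercept of the mixed-model analyses).  Every year a cloud
    of ``sites_per_species`` sites is drawn i.i.d. Gaussian (sd
    ``noise_sd_km``) around the true centroid; each site yields
    ``obs_per_site_year`` records in birds mode (counts Poisson, clipped to
    >= 1) or the species yields ``obs_per_year`` presence records in marine
    mode.  ``fail_sparse_fraction`` of species are under-reported in the
    first year (4 reports birds / 2 marine, below the inclusion floors) and
    ``fail_site_fraction`` of each remaining species' sites get only one
    observation that year, so the inclusion filters see genuine negatives.
    """

    n_species: int = 50
    mode: str = "birds"               # "birds" | "marine"
    sites_per_species: int = 8
    obs_per_site_year: int = 2        # birds mode
    obs_per_year: int = 4             # marine mode
    count_mean: float = 10.0
    tracking: float = 1.0
    noise_sd_km: float = 20.0
    species_bias_sd_kmyr: float = 0.0
    fail_sparse_fraction: float = 0.0
    fail_site_fraction: float = 0.0
    lat_range: Tuple[float, float] = (38.0, 47.0)
    lon_range: Tuple[float, float] = (-117.0, -98.0)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("birds", "marine"):
            raise ValueError("mode must be 'birds' or 'marine'")
        if not 0.0 <= self.tracking <= 1.0:
            raise ValueError("tracking factor must lie in [0, 1]")
        if self.noise_sd_km < 0:
            raise ValueError("noise sd must be non-negative")


VelocitySource = Union[Tuple[float, float], VelocityField]


def _local_velocity(velocity: VelocitySource, lat: float, lon: float) -> Tuple[float, float]:
    if isinstance(velocity, VelocityField):
        e, n, _ = velocity_at(velocity, lat, lon)
        return e, n
    e, n = velocity
    return float(e), float(n)


def make_species_records(
    scenario: SpeciesScenario,
    velocity: VelocitySource,
    years: Sequence[int],
) -> pd.DataFrame:
    """Observation records for every species and year.

    ``velocity`` is either a prescribed (east, north) km/yr vector or a
    :class:`VelocityField` looked up (nearest node) at the current true
    centroid, updated yearly.  Raises if a species is initialized outside a
    supplied velocity field's domain.
    """
    years = list(years)
    if not years:
        raise ValueError("empty year sequence")
    rng = np.random.default_rng(scenario.seed)
    n_fail_sp = int(round(scenario.fail_sparse_fraction * scenario.n_species))
    n_fail_sites = int(round(scenario.fail_site_fraction * scenario.sites_per_species))
    fail_year = years[0]

    if isinstance(velocity, VelocityField):
        for name, (lo, hi) in (("lat", scenario.lat_range), ("lon", scenario.lon_range)):
            axis = velocity.lat if name == "lat" else velocity.lon
            if lo < axis[0] or hi > axis[-1]:
                raise ValueError("species domain extends outside the velocity field")

    rows: List[tuple] = []
    for s in range(scenario.n_species):
        sp = f"sp{s:03d}"
        sparse = s < n_fail_sp
        clat = rng.uniform(*scenario.lat_range)
        clon = rng.uniform(*scenario.lon_range)
        bias = (
            rng.normal(0.0, scenario.species_bias_sd_kmyr, size=2)
            if scenario.species_bias_sd_kmyr > 0
            else np.zeros(2)
        )
        for year in years:
            if sparse and year == fail_year:
                n_records = 4 if scenario.mode == "birds" else 2
                emit_sites = [(f"{sp}_site{k:02d}", 1) for k in range(n_records)]
            elif scenario.mode == "birds":
                emit_sites = []
                for k in range(scenario.sites_per_species):
                    failing_site = (not sparse) and k >= scenario.sites_per_species - n_fail_sites
                    n_obs = 1 if (failing_site and year == fail_year) else scenario.obs_per_site_year
                    emit_sites.append((f"{sp}_site{k:02d}", n_obs))
            else:
                emit_sites = [(f"{sp}_obs", scenario.obs_per_year)]

            for site_id, n_obs in emit_sites:
                for _ in range(n_obs):
                    de, dn = rng.normal(0.0, scenario.noise_sd_km, size=2)
                    plat, plon = displace_km(clat, clon, de, dn)
                    if scenario.mode == "birds":
                        count = max(1, int(rng.poisson(scenario.count_mean)))
                        rows.append((sp, site_id, year, plat, plon, count, 1))
                    else:
                        rows.append((sp, site_id, year, plat, plon, np.nan, 1))
            ve, vn = _local_velocity(velocity, clat, clon)
            clat, clon = displace_km(
                clat,
                clon,
                scenario.tracking * ve + bias[0],
                scenario.tracking * vn + bias[1],
            )
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if scenario.mode == "marine":
        df["count"] = np.nan
    return df


def write_records_csv(records: pd.DataFrame, path) -> None:
    """CSV with the canonical header; count column empty in marine mode."""
    out = records.copy()
    out["count"] = out["count"].map(lambda c: "" if pd.isna(c) else str(int(c)))
    out.to_csv(path, index=False, float_format="%.6f")


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records CSV missing columns: {missing}")
    return df


def write_temperature_series(series, directory, var: str = "temperature") -> List[str]:
    """One NetCDF file per year under ``directory``; returns the paths."""
    import os

    os.makedirs(directory, exist_ok=True)
    paths = []
    for year, f in series:
        path = os.path.join(directory, f"{var}_{year}.nc")
        f.save(path, var=var)
        paths.append(path)
    return paths
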