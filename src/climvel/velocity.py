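"""Climate-velocity estimators on regular latitude-longitude grids.

Two estimators of the horizontal displacement rate of isopleths (e.g.
isotherms) between two decadal-mean scalar fields are provided:

``gradient_velocity``
    The classical ratio of the temporal rate of change to the spatial
    gradient magnitude, directed down-gradient.  Cells whose gradient
    magnitude falls below a floor are masked and zeroed, because the raw
    ratio blows up where the field is locally flat.

``match_velocity``
    A Monte-Carlo iterative convergence scheme: a per-node displacement
    field is grown by proposing local random deformations of the grid and
    keeping only those that bring the warped initial field closer to the
    final field, with a shear penalty that keeps the displacement field
    spatially regular.

Fields are stored as :class:`GriddedField`; velocities as
:class:`VelocityField` with an explicit validity mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import xarray as xr

from .geo import KM_PER_DEG

_SPACING_TOL = 1e-9


def _check_regular(coord: np.ndarray, name: str) -> float:
    if coord.ndim != 1 or coord.size < 2:
        raise ValueError(f"{name} must be 1-d with at least 2 entries")
    steps = np.diff(coord)
    if np.any(steps <= 0):
        raise ValueError(f"{name} must be strictly increasing")
    if steps.max() - steps.min() > _SPACING_TOL:
        raise ValueError(f"{name} spacing is not regular")
    return float(steps[0])


@dataclass
class GriddedField:
    """A scalar field (degC, or metres for DEMs) on a regular lat-lon grid.

    Parameters
    ----------
    values : (nlat, nlon) array
    lat, lon : 1-d coordinate arrays, degrees, strictly monotonic.
    period : optional (start_year, end_year) half-open window the field
        represents; its midpoint anchors time differences.
    mask : optional boolean validity mask (True = valid).
    """

    values: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    period: Optional[Tuple[float, float]] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if self.lat.size > 1 and self.lat[1] < self.lat[0]:
            self.lat = self.lat[::-1].copy()
            self.values = self.values[::-1].copy()
            if self.mask is not None:
                self.mask = np.asarray(self.mask)[::-1].copy()
        self.dlat = _check_regular(self.lat, "lat")
        self.dlon = _check_regular(self.lon, "lon")
        if self.values.shape != (self.lat.size, self.lon.size):
            raise ValueError("values shape does not match coordinates")
        valid = self.values if self.mask is None else self.values[np.asarray(self.mask, bool)]
        if not np.all(np.isfinite(valid)):
            raise ValueError("unmasked field values must be finite")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    @property
    def midpoint(self) -> float:
        if self.period is None:
            raise ValueError("field has no period")
        return 0.5 * (self.period[0] + self.period[1])

    @property
    def label(self) -> str:
        if self.period is None:
            return "unlabelled"
        return f"{self.period[0]:g}-{self.period[1]:g}"

    def same_grid(self, other: "GriddedField") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lat, other.lat, atol=_SPACING_TOL)
            and np.allclose(self.lon, other.lon, atol=_SPACING_TOL)
        )

    def contains(self, lat: float, lon: float) -> bool:
        return (
            self.lat[0] - _SPACING_TOL <= lat <= self.lat[-1] + _SPACING_TOL
            and self.lon[0] - _SPACING_TOL <= lon <= self.lon[-1] + _SPACING_TOL
        )

    # --- NetCDF I/O (scipy backend; classic NetCDF) -------------------
    def to_dataset(self, var: str = "temperature", units: str = "degC") -> xr.Dataset:
        ds = xr.Dataset(
            {var: (("lat", "lon"), self.values, {"units": units})},
            coords={"lat": self.lat, "lon": self.lon},
        )
        if self.period is not None:
            ds.attrs["period_start"] = float(self.period[0])
            ds.attrs["period_end"] = float(self.period[1])
        return ds

    def save(self, path, var: str = "temperature", units: str = "degC") -> None:
        self.to_dataset(var=var, units=units).to_netcdf(path, engine="scipy")

    @classmethod
    def load(cls, path, var: Optional[str] = None) -> "GriddedField":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        if var is None:
            candidates = [v for v in ds.data_vars if ds[v].ndim == 2]
            if len(candidates) != 1:
                raise ValueError(f"cannot infer variable among {list(ds.data_vars)}")
            var = candidates[0]
        period = None
        if "period_start" in ds.attrs:
            period = (float(ds.attrs["period_start"]), float(ds.attrs["period_end"]))
        return cls(ds[var].values, ds["lat"].values, ds["lon"].values, period=period)


@dataclass
class MatchConfig:
    """Free parameters of the Monte-Carlo iterative convergence loop.

    ``iteration_budget`` and ``stall_limit`` default to 400x and 20x the
    number of grid nodes; ``proposal_scale`` is the Gaussian step standard
    deviation in grid-cell fractions; ``shear_weight`` multiplies the
    (cell-size normalized, hence dimensionless) shear penalty.
    """

    iteration_budget: Optional[int] = None
    proposal_scale: float = 0.25
    shear_weight: float = 0.5
    stall_limit: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if self.iteration_budget is not None and self.iteration_budget <= 0:
            raise ValueError("iteration budget must be positive")
        if self.proposal_scale <= 0:
            raise ValueError("proposal scale must be positive")
        if self.shear_weight < 0:
            raise ValueError("shear weight must be non-negative")

    def resolved(self, n_nodes: int) -> Tuple[int, int]:
        budget = self.iteration_budget or 400 * n_nodes
        stall = self.stall_limit or 20 * n_nodes
        return budget, stall


@dataclass
class VelocityField:
    """Per-node horizontal displacement rates (km/yr) with a validity mask."""

    east: np.ndarray
    north: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    valid: np.ndarray
    method: str = "gradient"
    dt: float = float("nan")
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.east = np.asarray(self.east, dtype=float)
        self.north = np.asarray(self.north, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.east.shape == self.north.shape == self.valid.shape):
            raise ValueError("component/mask shapes differ")
        if not (np.all(np.isfinite(self.east)) and np.all(np.isfinite(self.north))):
            raise ValueError("velocity components must be finite everywhere")
        bad = ~self.valid
        if np.any(self.east[bad] != 0.0) or np.any(self.north[bad] != 0.0):
            raise ValueError("masked-invalid nodes must have zero components")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.east, self.north)

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {
                "v_east": (("lat", "lon"), self.east, {"units": "km/yr"}),
                "v_north": (("lat", "lon"), self.north, {"units": "km/yr"}),
                "valid": (("lat", "lon"), self.valid.astype(np.int8)),
            },
            coords={"lat": self.lat, "lon": self.lon},
            attrs={"method": self.method, "dt_years": float(self.dt)},
        )
        return ds

    def save(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def load(cls, path) -> "VelocityField":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        return cls(
            ds["v_east"].values,
            ds["v_north"].values,
            ds["lat"].values,
            ds["lon"].values,
            ds["valid"].values.astype(bool),
            method=str(ds.attrs.get("method", "unknown")),
            dt=float(ds.attrs.get("dt_years", float("nan"))),
        )


def decadal_mean(
    yearly: Iterable[Tuple[int, GriddedField]], window: Tuple[float, float]
) -> GriddedField:
    """Node-wise mean of the yearly fields with year in [start, end)."""
    start, end = window
    if end <= start:
        raise ValueError("window must satisfy start < end")
    selected = [f for (year, f) in yearly if start <= year < end]
    if not selected:
        raise ValueError(f"no yearly fields in window [{start}, {end})")
    first = selected[0]
    for f in selected[1:]:
        if not first.same_grid(f):
            raise ValueError("yearly fields are on different grids")
    mean = np.mean([f.values for f in selected], axis=0)
    return GriddedField(mean, first.lat, first.lon, period=(float(start), float(end)))


def spatial_gradient(f: GriddedField) -> Tuple[np.ndarray, np.ndarray]:
    """Spatial gradient (d/d_east_km, d/d_north_km) via central differences.

    Degree-space differences are converted to km with ``KM_PER_DEG``
    meridionally and ``KM_PER_DEG * cos(lat)`` zonally; edges use one-sided
    differences.
    """
    if f.lat.size < 3 or f.lon.size < 3:
        raise ValueError("gradient requires at least a 3x3 grid")
    d_dlat = np.gradient(f.values, f.lat, axis=0)
    d_dlon = np.gradient(f.values, f.lon, axis=1)
    gy = d_dlat / KM_PER_DEG
    gx = d_dlon / (KM_PER_DEG * np.cos(np.radians(f.lat))[:, None])
    return gx, gy


def _dt_years(f0: GriddedField, f1: GriddedField) -> float:
    dt = f1.midpoint - f0.midpoint
    if dt <= 0:
        raise ValueError("final field must postdate the initial field")
    return float(dt)


def gradient_velocity(
    f0: GriddedField, f1: GriddedField, min_grad: float = 1e-4
) -> VelocityField:
    """Gradient-method climate velocity between two period-mean fields.

    The velocity is ``rate * (-grad psi) / |grad psi|^2`` with the rate and
    gradient evaluated so that warming on a poleward-cooling field yields a
    poleward vector.  Nodes with ``|grad psi| < min_grad`` (degC/km) are
    masked invalid and set exactly to zero instead of blowing up.
    """
    if not f0.same_grid(f1):
        raise ValueError("fields are on different grids")
    if min_grad <= 0:
        raise ValueError("min_grad must be positive")
    dt = _dt_years(f0, f1)
    rate = (f1.values - f0.values) / dt
    gx, gy = spatial_gradient(f0)
    g2 = gx * gx + gy * gy
    ok = np.sqrt(g2) >= min_grad
    if f0.mask is not None:
        ok &= np.asarray(f0.mask, bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        east = np.where(ok, -rate * gx / g2, 0.0)
        north = np.where(ok, -rate * gy / g2, 0.0)
    return VelocityField(east, north, f0.lat, f0.lon, ok, method="gradient", dt=dt)


def match_velocity(
    f0: GriddedField, f1: GriddedField, config: Optional[MatchConfig] = None
) -> VelocityField:
    """Monte-Carlo iterative convergence velocity between two fields.

    A displacement field D (km per node, initialized to zero) is refined by
    greedy stochastic descent: each iteration perturbs one node's
    displacement by an isotropic Gaussian step (whose standard deviation is
    drawn log-uniformly between 2% and 100% of ``proposal_scale`` cell
    sizes, so the walk can take both coarse and fine steps) and keeps the
    move iff the objective

        E(D) = misfit(D) + shear_weight * shear(D)

    strictly decreases.  ``misfit`` backward-warps the initial field (f0
    sampled bilinearly at node - D, clamped to the nearest edge outside the
    grid) and sums squared differences to the final field; ``shear`` sums
    squared neighbour-pair displacement differences, normalized by the mean
    cell size so the penalty is dimensionless.  The loop stops at the
    iteration budget or after ``stall_limit`` rejected proposals in a row.
    Deterministic for a fixed seed.
    """
    if not f0.same_grid(f1):
        raise ValueError("fields are on different grids")
    if not (np.all(np.isfinite(f0.values)) and np.all(np.isfinite(f1.values))):
        raise ValueError("fields must be finite for matching")
    config = config or MatchConfig()
    dt = _dt_years(f0, f1)

    nlat, nlon = f0.shape
    n_nodes = nlat * nlon
    budget, stall_limit = config.resolved(n_nodes)

    lat = f0.lat
    lon = f0.lon
    lat0 = float(lat[0])
    lon0 = float(lon[0])
    dlat = f0.dlat
    dlon = f0.dlon
    F0 = f0.values
    F1 = f1.values

    coslat = np.cos(np.radians(lat))
    h_north = KM_PER_DEG * dlat                      # meridional cell size, km
    h_east = KM_PER_DEG * coslat * dlon              # zonal cell size per row, km
    h_mean = 0.5 * (h_north + float(h_east.mean()))  # shear normalization
    inv_h2 = 1.0 / (h_mean * h_mean)
    lam = config.shear_weight

    De = np.zeros((nlat, nlon))
    Dn = np.zeros((nlat, nlon))

    max_i = nlat - 1
    max_j = nlon - 1

    def sample_f0(la: float, lo: float) -> float:
        # bilinear with edge clamping
        x = (la - lat0) / dlat
        y = (lo - lon0) / dlon
        if x < 0.0:
            x = 0.0
        elif x > max_i:
            x = float(max_i)
        if y < 0.0:
            y = 0.0
        elif y > max_j:
            y = float(max_j)
        i0 = int(x)
        j0 = int(y)
        if i0 > max_i - 1:
            i0 = max_i - 1
        if j0 > max_j - 1:
            j0 = max_j - 1
        fx = x - i0
        fy = y - j0
        f00 = F0[i0, j0]
        f01 = F0[i0, j0 + 1]
        f10 = F0[i0 + 1, j0]
        f11 = F0[i0 + 1, j0 + 1]
        return (
            f00 * (1 - fx) * (1 - fy)
            + f01 * (1 - fx) * fy
            + f10 * fx * (1 - fy)
            + f11 * fx * fy
        )

    def misfit_term(i: int, j: int, de: float, dn: float) -> float:
        la = lat[i] - dn / KM_PER_DEG
        lo = lon[j] - de / (KM_PER_DEG * coslat[i])
        r = sample_f0(la, lo) - F1[i, j]
        return r * r

    mis = np.empty((nlat, nlon))
    for i in range(nlat):
        for j in range(nlon):
            mis[i, j] = misfit_term(i, j, 0.0, 0.0)
    misfit0 = float(mis.sum())
    energy = misfit0  # shear(0) = 0

    rng = np.random.default_rng(config.seed)
    scale = config.proposal_scale
    sd_n = scale * h_north

    objective_trace = [energy]
    accepted = 0
    iteration = 0
    stall = 0
    chunk = 4096
    while iteration < budget and stall < stall_limit:
        n_draw = min(chunk, budget - iteration)
        nodes = rng.integers(0, n_nodes, size=n_draw)
        steps = rng.standard_normal((n_draw, 2))
        # log-uniform multi-scale step sizes in [0.02, 1] x proposal scale
        mults = np.exp(rng.uniform(math.log(0.02), 0.0, size=n_draw))
        steps *= mults[:, None]
        for t in range(n_draw):
            iteration += 1
            node = nodes[t]
            i = node // nlon
            j = node - i * nlon
            de_old = De[i, j]
            dn_old = Dn[i, j]
            de_new = de_old + steps[t, 0] * scale * h_east[i]
            dn_new = dn_old + steps[t, 1] * sd_n

            d_shear = 0.0
            if i > 0:
                e = De[i - 1, j]
                n_ = Dn[i - 1, j]
                d_shear += (de_new - e) ** 2 + (dn_new - n_) ** 2 - (de_old - e) ** 2 - (dn_old - n_) ** 2
            if i < max_i:
                e = De[i + 1, j]
                n_ = Dn[i + 1, j]
                d_shear += (de_new - e) ** 2 + (dn_new - n_) ** 2 - (de_old - e) ** 2 - (dn_old - n_) ** 2
            if j > 0:
                e = De[i, j - 1]
                n_ = Dn[i, j - 1]
                d_shear += (de_new - e) ** 2 + (dn_new - n_) ** 2 - (de_old - e) ** 2 - (dn_old - n_) ** 2
            if j < max_j:
                e = De[i, j + 1]
                n_ = Dn[i, j + 1]
                d_shear += (de_new - e) ** 2 + (dn_new - n_) ** 2 - (de_old - e) ** 2 - (dn_old - n_) ** 2

            m_new = misfit_term(i, j, de_new, dn_new)
            delta = (m_new - mis[i, j]) + lam * d_shear * inv_h2
            if delta < 0.0:
                De[i, j] = de_new
                Dn[i, j] = dn_new
                mis[i, j] = m_new
                energy += delta
                objective_trace.append(energy)
                accepted += 1
                stall = 0
            else:
                stall += 1
            if stall >= stall_limit:
                break

    diagnostics = {
        "objective_trace": objective_trace,
        "misfit_initial": misfit0,
        "misfit_final": float(mis.sum()),
        "accepted_moves": accepted,
        "iterations": iteration,
    }
    valid = np.ones((nlat, nlon), dtype=bool)
    return VelocityField(
        De / dt, Dn / dt, lat, lon, valid, method="match", dt=dt, diagnostics=diagnostics
    )


def velocity_at(v: VelocityField, lat: float, lon: float) -> Tuple[float, float, bool]:
    """Velocity at the grid node nearest to (lat, lon), plus its validity.

    Nearest-node lookup (not interpolation) keeps the zeroed invalid nodes
    from bleeding into neighbouring values.  Raises if the point is outside
    the grid bounding box.
    """
    if not (v.lat[0] - _SPACING_TOL <= lat <= v.lat[-1] + _SPACING_TOL):
        raise ValueError(f"latitude {lat} outside field domain")
    if not (v.lon[0] - _SPACING_TOL <= lon <= v.lon[-1] + _SPACING_TOL):
        raise ValueError(f"longitude {lon} outside field domain")
    i = int(round((lat - v.lat[0]) / (v.lat[1] - v.lat[0])))
    j = int(round((lon - v.lon[0]) / (v.lon[1] - v.lon[0])))
    i = min(max(i, 0), v.lat.size - 1)
    j = min(max(j, 0), v.lon.size - 1)
    return float(v.east[i, j]), float(v.north[i, j]), bool(v.valid[i, j])
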