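"""Pairing species shifts with climate velocities and the statistical layer.

Each comparison row pairs one species' decadal shift velocities with the
climate velocities (gradient and Monte-Carlo-matched fields) sampled at
the species' initial-decade centroid.  On top of that sit per-component
ordinary least squares fits with outlier removal, linear mixed models with
a species random intercept for the aggregated decades, a joint multilinear
fit, and circular summaries of heading differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geo import displace_km, heading_deg, wrap_angle
from .ranges import sample_elevation
from .velocity import GriddedField, VelocityField, velocity_at

COMPONENTS = ("lon", "lat", "elev")
METHODS = ("gradient", "match")


def heading_difference(h_species, h_climate):
    """Wrapped heading difference (species minus climate) in [-180, 180).

    NaN inputs (undefined headings at zero velocity) propagate as NaN
    rather than being coerced to zero.
    """
    return wrap_angle(np.asarray(h_species, dtype=float) - np.asarray(h_climate, dtype=float))


def build_comparison(
    tracks: pd.DataFrame,
    vgrad: Optional[VelocityField],
    vmatch: Optional[VelocityField],
    dem: Optional[GriddedField] = None,
    split_lon: Optional[float] = -100.0,
    elev_displacement: str = "full_dt",
) -> pd.DataFrame:
    """One row per species x decade pair, pairing species and climate velocities.

    The climate velocity experienced by a species is the field value at the
    nearest node to its initial-decade centroid.  The climate elevational
    velocity is the DEM difference between the initial centroid and that
    centroid displaced along the climate vector (over the full decade
    offset by default, or over one year with ``elev_displacement="per_yr"``),
    divided by the same interval.  Rows at masked climate nodes carry a
    False validity flag for that method.
    """
    if elev_displacement not in ("full_dt", "per_yr"):
        raise ValueError("elev_displacement must be 'full_dt' or 'per_yr'")
    fields: Dict[str, Optional[VelocityField]] = {"gradient": vgrad, "match": vmatch}
    rows = []
    for _, tr in tracks.iterrows():
        lat0, lon0 = float(tr["lat0"]), float(tr["lon0"])
        row = {
            "species_id": tr["species_id"],
            "pair": f"{tr['decade0']}_to_{tr['decade1']}",
            "region": _region_label(lon0, split_lon),
            "sp_vlon": float(tr["v_lon_kmyr"]),
            "sp_vlat": float(tr["v_lat_kmyr"]),
            "sp_velev": float(tr["v_elev_myr"]),
            "sp_heading": float(tr["heading_deg"]),
        }
        for method, fieldv in fields.items():
            if fieldv is None:
                row[f"{method}_vlon"] = np.nan
                row[f"{method}_vlat"] = np.nan
                row[f"{method}_velev"] = np.nan
                row[f"{method}_heading"] = np.nan
                row[f"{method}_valid"] = False
                continue
            ve, vn, ok = velocity_at(fieldv, lat0, lon0)
            row[f"{method}_vlon"] = ve
            row[f"{method}_vlat"] = vn
            row[f"{method}_valid"] = ok
            mag = float(np.hypot(ve, vn))
            row[f"{method}_heading"] = heading_deg(ve, vn) if mag > 0 else np.nan
            if dem is not None:
                dt = fieldv.dt if elev_displacement == "full_dt" else 1.0
                dlat, dlon = displace_km(lat0, lon0, ve * dt, vn * dt)
                try:
                    e1 = sample_elevation(dem, dlat, dlon)
                    e0 = sample_elevation(dem, lat0, lon0)
                    row[f"{method}_velev"] = (e1 - e0) / dt
                except ValueError:
                    row[f"{method}_velev"] = np.nan
                    row[f"{method}_valid"] = False
            else:
                row[f"{method}_velev"] = np.nan
        for method in METHODS:
            row[f"heading_diff_{method}"] = float(
                heading_difference(row["sp_heading"], row[f"{method}_heading"])
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _region_label(lon: float, split_lon: Optional[float]) -> str:
    if split_lon is None:
        return "all"
    return "west" if lon <= split_lon else "east"


@dataclass
class FitResult:
    """Per-component linear fit of species velocity on climate velocity."""

    slope: float
    slope_se: float
    intercept: float
    r: float
    p: float
    n_used: int
    n_removed: int


def _component_xy(
    rows: pd.DataFrame, component: str, method: str
) -> Tuple[np.ndarray, np.ndarray]:
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    suffix = {"lon": "vlon", "lat": "vlat", "elev": "velev"}[component]
    sub = rows[rows[f"{method}_valid"].astype(bool)]
    x = sub[f"{method}_{suffix}"].to_numpy(dtype=float)
    y = sub[f"sp_{suffix}"].to_numpy(dtype=float)
    finite = np.isfinite(x) & np.isfinite(y)
    return x[finite], y[finite]


def component_fit(
    rows: pd.DataFrame,
    component: str,
    method: str,
    outlier_threshold: float = 1000.0,
    elev_threshold: Optional[float] = None,
    intercept: bool = True,
) -> FitResult:
    """OLS of the species velocity component on the climate component.

    Horizontal components drop rows where either side exceeds
    ``outlier_threshold`` km/yr in magnitude; the elevational component is
    only thresholded if ``elev_threshold`` is given.  Requires at least 3
    surviving points.
    """
    x, y = _component_xy(rows, component, method)
    thr = elev_threshold if component == "elev" else outlier_threshold
    if thr is not None:
        keep = (np.abs(x) <= thr) & (np.abs(y) <= thr)
    else:
        keep = np.ones(x.size, dtype=bool)
    n_removed = int((~keep).sum())
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("fewer than 3 points after outlier removal")
    if intercept:
        res = sps.linregress(x, y)
        slope, se, icpt, r, p = res.slope, res.stderr, res.intercept, res.rvalue, res.pvalue
    else:
        import statsmodels.api as sm

        fit = sm.OLS(y, x[:, None]).fit()
        slope = float(fit.params[0])
        se = float(fit.bse[0])
        icpt = 0.0
        r = float(sps.pearsonr(x, y).statistic)
        p = float(fit.pvalues[0])
    return FitResult(float(slope), float(se), float(icpt), float(r), float(p), int(x.size), n_removed)


@dataclass
class MixedResult:
    """Linear mixed model: species velocity ~ climate velocity, random
    intercept per species, fitted by maximum likelihood."""

    slope: float
    slope_se: float
    z: float
    p: float
    intercept: float
    group_var: float
    n_obs: int
    n_groups: int
    converged: bool


def mixed_fit(rows: pd.DataFrame, component: str, method: str) -> MixedResult:
    """Fit the aggregated-decades mixed model for one component and method.

    Non-convergent or singular fits are reported with ``converged=False``
    rather than raised.
    """
    import statsmodels.api as sm

    suffix = {"lon": "vlon", "lat": "vlat", "elev": "velev"}[component]
    sub = rows[rows[f"{method}_valid"].astype(bool)].copy()
    sub = sub[np.isfinite(sub[f"{method}_{suffix}"]) & np.isfinite(sub[f"sp_{suffix}"])]
    groups = sub["species_id"]
    if groups.nunique() < 2:
        raise ValueError("mixed model needs at least 2 species")
    endog = sub[f"sp_{suffix}"].to_numpy(dtype=float)
    exog = sm.add_constant(sub[f"{method}_{suffix}"].to_numpy(dtype=float))

    def _ols_fallback() -> MixedResult:
        # singular/unidentifiable random effect: pooled OLS, flagged
        ols = sm.OLS(endog, exog).fit()
        return MixedResult(
            float(ols.params[1]),
            float(ols.bse[1]),
            float(ols.params[1] / ols.bse[1]),
            float(ols.pvalues[1]),
            float(ols.params[0]),
            0.0,
            int(endog.size),
            int(groups.nunique()),
            False,
        )

    if groups.value_counts().max() < 2:
        # one observation per species: the intercept variance cannot be
        # separated from the residual and ML estimates are degenerate
        return _ols_fallback()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(endog, exog, groups=groups)
            fit = model.fit(reml=False)
            converged = bool(getattr(fit, "converged", True))
        except Exception:
            return _ols_fallback()
    slope = float(fit.fe_params[1])
    se = float(fit.bse_fe[1])
    if not (np.isfinite(slope) and np.isfinite(se) and se > 0):
        return _ols_fallback()
    z = slope / se if se > 0 else float("nan")
    p = float(2.0 * sps.norm.sf(abs(z)))
    return MixedResult(
        slope,
        se,
        float(z),
        p,
        float(fit.fe_params[0]),
        float(np.squeeze(fit.cov_re)),
        int(endog.size),
        int(groups.nunique()),
        converged,
    )


def multilinear_fit(rows: pd.DataFrame, method: str, response: str = "lat") -> pd.DataFrame:
    """Joint OLS of one species component on all three climate components.

    Returns a coefficient table (term, coef, se, p) with a
    ``rank_deficient`` attribute flag in ``DataFrame.attrs``.
    """
    import statsmodels.api as sm

    sub = rows[rows[f"{method}_valid"].astype(bool)].copy()
    cols = [f"{method}_vlon", f"{method}_vlat", f"{method}_velev"]
    ysuf = {"lon": "vlon", "lat": "vlat", "elev": "velev"}[response]
    keep = np.isfinite(sub[cols]).all(axis=1) & np.isfinite(sub[f"sp_{ysuf}"])
    sub = sub[keep]
    if len(sub) < 5:
        raise ValueError("fewer than 5 valid rows")
    X = sm.add_constant(sub[cols].to_numpy(dtype=float))
    y = sub[f"sp_{ysuf}"].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    table = pd.DataFrame(
        {
            "term": ["intercept", "climate_vlon", "climate_vlat", "climate_velev"],
            "coef": fit.params,
            "se": fit.bse,
            "p": fit.pvalues,
        }
    )
    table.attrs["rank_deficient"] = int(np.linalg.matrix_rank(X)) < X.shape[1]
    return table


@dataclass
class HeadingSummary:
    circ_mean_deg: float      # NaN when the resultant vanishes
    circ_sd_deg: float
    mean_defined: bool
    n: int
    bin_edges: np.ndarray
    counts: np.ndarray


def heading_summary(diffs, n_bins: int = 36) -> HeadingSummary:
    """Circular mean/sd and histogram of heading differences.

    Undefined (NaN) differences are excluded; an empty remainder raises.
    The circular sd is ``sqrt(-2 ln R)`` converted to degrees.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("all heading differences undefined")
    rad = np.radians(d)
    C = np.cos(rad).mean()
    S = np.sin(rad).mean()
    R = float(np.hypot(C, S))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    if R < 1e-12:
        return HeadingSummary(float("nan"), float("nan"), False, int(d.size), edges, counts)
    mean = float(wrap_angle(np.degrees(np.arctan2(S, C))))
    sd = float(np.degrees(np.sqrt(-2.0 * np.log(R))))
    return HeadingSummary(mean, sd, True, int(d.size), edges, counts)


def fit_table(
    rows: pd.DataFrame,
    methods=METHODS,
    components=COMPONENTS,
    outlier_threshold: float = 1000.0,
) -> pd.DataFrame:
    """Slope/SE/r/p/n table over decade pairs (plus 'all'), per method x component."""
    pairs = sorted(rows["pair"].unique())
    out = []
    for label, sub in [(p, rows[rows["pair"] == p]) for p in pairs] + [("all", rows)]:
        for method in methods:
            for comp in components:
                try:
                    fr = component_fit(sub, comp, method, outlier_threshold=outlier_threshold)
                except ValueError:
                    continue
                out.append(
                    {
                        "pair": label,
                        "method": method,
                        "component": comp,
                        "slope": fr.slope,
                        "slope_se": fr.slope_se,
                        "r": fr.r,
                        "p": fr.p,
                        "n_used": fr.n_used,
                        "n_removed": fr.n_removed,
                    }
                )
    return pd.DataFrame(out)
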