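import numpy as np
import pytest

import climvel as cv


@pytest.fixture(scope="session")
def parallel_scenario():
    """Linear meridional gradient (0.01 degC/km) with uniform 0.02 degC/yr
    warming; the gradient-method closed form is b/a = 2 km/yr north."""
    return cv.FieldScenario(name="parallel", gradient=0.01, warming=0.02)


@pytest.fixture(scope="session")
def parallel_means(parallel_scenario):
    series = cv.make_temperature_series(parallel_scenario)
    return (
        cv.decadal_mean(series, (1960, 1970)),
        cv.decadal_mean(series, (1970, 1980)),
    )


@pytest.fixture(scope="session")
def grid_coords():
    lat = np.arange(35.0, 50.001, 0.5)
    lon = np.arange(-120.0, -94.999, 0.5)
    return lat, lon


@pytest.fixture(scope="session")
def sheared_velocity_field(grid_coords):
    """A prescribed northward field whose speed varies slowly with
    longitude, so regressions of species on climate velocity are
    non-degenerate."""
    lat, lon = grid_coords
    north = 2.0 + 1.0 * np.sin(0.15 * (lon + 107.0))[None, :] * np.ones((lat.size, 1))
    east = np.zeros_like(north)
    return cv.VelocityField(east, north, lat, lon, np.ones_like(north, dtype=bool),
                            method="gradient", dt=10.0)


@pytest.fixture(scope="session")
def bird_records():
    """50-species bird fixture with engineered filter failures."""
    scenario = cv.SpeciesScenario(
        n_species=50,
        mode="birds",
        tracking=1.0,
        noise_sd_km=15.0,
        fail_sparse_fraction=0.1,
        fail_site_fraction=0.25,
        seed=11,
    )
    return cv.make_species_records(scenario, (0.5, 2.0), range(1960, 1980))


@pytest.fixture(scope="session")
def marine_records():
    scenario = cv.SpeciesScenario(
        n_species=50,
        mode="marine",
        tracking=1.0,
        noise_sd_km=15.0,
        fail_sparse_fraction=0.12,
        seed=12,
    )
    return cv.make_species_records(scenario, (0.5, 2.0), range(1960, 1980))


def brute_force_filter_birds(records, decade0, decade1):
    """Independent nested-loop oracle for the bird inclusion criteria."""
    years = list(range(*decade0)) + list(range(*decade1))
    rows = records[records["year"].isin(years)]
    species_ok = set()
    for sp in rows["species_id"].unique():
        sub = rows[rows["species_id"] == sp]
        if all((sub["year"] == y).sum() >= 5 for y in years):
            species_ok.add(sp)
    pair_ok = set()
    for sp in species_ok:
        sub = rows[rows["species_id"] == sp]
        for site in sub["site_id"].unique():
            ssub = sub[sub["site_id"] == site]
            if all((ssub["year"] == y).sum() >= 2 for y in years):
                pair_ok.add((sp, site))
    surviving = rows[[ (r.species_id, r.site_id) in pair_ok for r in rows.itertuples() ]]
    final_species = set()
    for sp in surviving["species_id"].unique():
        sub = surviving[surviving["species_id"] == sp]
        if all((sub["year"] == y).sum() >= 5 for y in years):
            final_species.add(sp)
    return surviving[surviving["species_id"].isin(final_species)]


def brute_force_filter_marine(records, decade0, decade1):
    years = list(range(*decade0)) + list(range(*decade1))
    rows = records[records["year"].isin(years)]
    keep = set()
    for sp in rows["species_id"].unique():
        sub = rows[rows["species_id"] == sp]
        if all((sub["year"] == y).sum() >= 3 for y in years):
            keep.add(sp)
    return rows[rows["species_id"].isin(keep)]


def frechet_centroid_oracle(lats, lons, weights=None):
    """Brute-force minimizer of the weighted sum of squared great-circle
    distances (Nelder-Mead in lat/lon space)."""
    from scipy.optimize import minimize

    lats = np.asarray(lats, float)
    lons = np.asarray(lons, float)
    w = np.ones_like(lats) if weights is None else np.asarray(weights, float)

    def objective(x):
        la, lo = np.radians(x[0]), np.radians(x[1])
        pla, plo = np.radians(lats), np.radians(lons)
        cosd = np.sin(la) * np.sin(pla) + np.cos(la) * np.cos(pla) * np.cos(lo - plo)
        d = np.arccos(np.clip(cosd, -1.0, 1.0))
        return float((w * d**2).sum())

    x0 = [lats.mean(), lons.mean()]
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
    return float(res.x[0]), float(res.x[1])
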