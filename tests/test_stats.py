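import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import climvel as cv
from climvel.stats import fit_table


def make_rows(x, y, method="gradient", species=None, pair="p0", x_elev=None, y_elev=None):
    """Assemble a minimal comparison frame for one method and component."""
    n = len(x)
    species = species if species is not None else [f"sp{i:03d}" for i in range(n)]
    return pd.DataFrame(
        {
            "species_id": species,
            "pair": pair,
            "region": "west",
            "sp_vlon": np.zeros(n),
            "sp_vlat": y,
            "sp_velev": y_elev if y_elev is not None else np.zeros(n),
            "sp_heading": np.zeros(n),
            f"{method}_vlon": np.zeros(n),
            f"{method}_vlat": x,
            f"{method}_velev": x_elev if x_elev is not None else np.zeros(n),
            f"{method}_heading": np.zeros(n),
            f"{method}_valid": True,
            f"heading_diff_{method}": np.zeros(n),
        }
    )


def ols_oracle(x, y):
    """Closed-form simple linear regression."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    slope = ((x - xm) * (y - ym)).sum() / sxx
    icpt = ym - slope * xm
    resid = y - icpt - slope * x
    n = x.size
    se = np.sqrt((resid**2).sum() / (n - 2) / sxx)
    r = ((x - xm) * (y - ym)).sum() / np.sqrt(sxx * ((y - ym) ** 2).sum())
    return slope, icpt, se, r


class TestComponentFit:
    def test_identity_line(self):
        x = np.arange(10, dtype=float)
        fr = cv.component_fit(make_rows(x, x), "lat", "gradient")
        assert fr.slope == pytest.approx(1.0) and fr.r == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 3, 40)
        y = 0.7 * x + rng.normal(0, 1, 40)
        fr = cv.component_fit(make_rows(x, y), "lat", "gradient")
        slope, icpt, se, r = ols_oracle(x, y)
        assert fr.slope == pytest.approx(slope, rel=1e-10)
        assert fr.intercept == pytest.approx(icpt, rel=1e-10)
        assert fr.slope_se == pytest.approx(se, rel=1e-10)
        assert fr.r == pytest.approx(r, rel=1e-10)

    def test_outlier_threshold_removes_rows(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 1500.0])
        y = x.copy()
        fr = cv.component_fit(make_rows(x, y), "lat", "gradient")
        assert fr.n_removed == 1 and fr.n_used == 4

    def test_outlier_removal_idempotent(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 100, 50), [2000.0, -5000.0]])
        y = x + rng.normal(0, 10, 52)
        rows = make_rows(x, y)
        fr1 = cv.component_fit(rows, "lat", "gradient")
        kept = (np.abs(x) <= 1000) & (np.abs(y) <= 1000)
        fr2 = cv.component_fit(make_rows(x[kept], y[kept]), "lat", "gradient")
        assert fr1.slope == pytest.approx(fr2.slope, rel=1e-12)
        assert fr1.n_used == fr2.n_used

    def test_elevation_exempt_from_horizontal_threshold(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 1500.0])
        rows = make_rows(np.zeros(5), np.zeros(5), x_elev=x, y_elev=x)
        fr = cv.component_fit(rows, "elev", "gradient")
        assert fr.n_removed == 0 and fr.n_used == 5

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 2, 200)
        y = 0.5 * x + rng.normal(0, 0.2, 200)
        fr = cv.component_fit(make_rows(x, y), "lat", "gradient")
        assert abs(fr.slope - 0.5) < 3 * fr.slope_se

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError, match="3 points"):
            cv.component_fit(make_rows([1.0, 2.0], [1.0, 2.0]), "lat", "gradient")

    def test_no_intercept_option(self):
        x = np.arange(1.0, 11.0)
        fr = cv.component_fit(make_rows(x, 2 * x + 1), "lat", "gradient", intercept=False)
        assert fr.intercept == 0.0
        assert fr.slope == pytest.approx(np.sum(x * (2 * x + 1)) / np.sum(x * x))


class TestHeadingDifference:
    def test_wrap_example(self):
        assert cv.heading_difference(350.0, 10.0) == pytest.approx(-20.0)

    def test_equal_headings_zero(self):
        assert cv.heading_difference(123.0, 123.0) == 0.0

    def test_antipodal_boundary_convention(self):
        assert cv.heading_difference(0.0, 180.0) == -180.0

    def test_nan_propagates(self):
        assert np.isnan(cv.heading_difference(np.nan, 10.0))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6))
    def test_always_in_range_and_idempotent(self, a, b):
        d = cv.heading_difference(a, b)
        assert -180.0 <= d < 180.0
        assert cv.wrap_angle(d) == pytest.approx(d, abs=1e-9)


class TestHeadingSummary:
    def test_all_zero(self):
        hs = cv.heading_summary(np.zeros(50))
        assert hs.circ_mean_deg == 0.0 and hs.circ_sd_deg == 0.0

    def test_antipodal_cancellation_mean_undefined(self):
        hs = cv.heading_summary([90.0, -90.0])
        assert not hs.mean_defined and np.isnan(hs.circ_mean_deg)

    def test_von_mises_sample_recovers_mean(self):
        rng = np.random.default_rng(3)
        sample = np.degrees(rng.vonmises(np.radians(20.0), 4.0, 500))
        hs = cv.heading_summary(sample)
        assert abs(hs.circ_mean_deg - 20.0) < 3.0

    def test_histogram_covers_domain(self):
        hs = cv.heading_summary(np.linspace(-179, 179, 100), n_bins=12)
        assert hs.counts.sum() == 100
        assert hs.bin_edges[0] == -180.0 and hs.bin_edges[-1] == 180.0

    def test_all_undefined_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            cv.heading_summary([np.nan, np.nan])


class TestMixedFit:
    def test_recovers_slope_with_random_intercepts(self):
        rng = np.random.default_rng(8)
        n_sp, n_rep = 60, 4
        species = np.repeat([f"sp{i:03d}" for i in range(n_sp)], n_rep)
        bias = np.repeat(rng.normal(0, 0.5, n_sp), n_rep)
        x = rng.normal(0, 2, n_sp * n_rep)
        y = 1.0 * x + bias + rng.normal(0, 0.2, n_sp * n_rep)
        rows = make_rows(x, y, species=species)
        mr = cv.mixed_fit(rows, "lat", "gradient")
        assert abs(mr.slope - 1.0) < 3 * mr.slope_se
        assert mr.group_var > 0.05
        assert mr.n_groups == n_sp and mr.n_obs == n_sp * n_rep

    def test_degenerates_to_ols_on_perfect_line(self):
        x = np.tile(np.arange(10.0), 3)
        species = np.repeat(["a", "b", "c"], 10)
        rows = make_rows(x, x, species=species)
        mr = cv.mixed_fit(rows, "lat", "gradient")
        assert mr.slope == pytest.approx(1.0, abs=1e-6)

    def test_type_one_error_rate_under_null(self):
        # single observation per species, pure noise: the fixed-effect test
        # should be approximately nominal at alpha = 0.05
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.normal(0, 1, 200)
            y = rng.normal(0, 1, 200)
            mr = cv.mixed_fit(make_rows(x, y), "lat", "gradient")
            rejections += mr.p < 0.05
        assert 0.01 <= rejections / n_rep <= 0.10

    def test_needs_two_species(self):
        rows = make_rows(np.arange(5.0), np.arange(5.0), species=["a"] * 5)
        with pytest.raises(ValueError, match="2 species"):
            cv.mixed_fit(rows, "lat", "gradient")


class TestMultilinearFit:
    def test_orthogonal_regressors_exact_recovery(self):
        n = 64
        rng = np.random.default_rng(9)
        x1 = rng.normal(0, 1, n)
        x2 = rng.normal(0, 1, n)
        x3 = rng.normal(0, 1, n)
        y = 2.0 * x1 - 1.0 * x2 + 0.5 * x3
        rows = make_rows(x2, y, x_elev=x3)
        rows["gradient_vlon"] = x1
        table = cv.multilinear_fit(rows, "gradient", response="lat")
        coefs = dict(zip(table["term"], table["coef"]))
        assert coefs["climate_vlon"] == pytest.approx(2.0, abs=1e-8)
        assert coefs["climate_vlat"] == pytest.approx(-1.0, abs=1e-8)
        assert coefs["climate_velev"] == pytest.approx(0.5, abs=1e-8)
        assert not table.attrs["rank_deficient"]

    def test_single_axis_effect_leaves_others_null(self):
        rng = np.random.default_rng(10)
        n = 200
        x_lat = rng.normal(0, 2, n)
        x_lon = rng.normal(0, 2, n)
        x_elev = rng.normal(0, 2, n)
        y = 0.8 * x_lat + rng.normal(0, 0.5, n)
        rows = make_rows(x_lat, y, x_elev=x_elev)
        rows["gradient_vlon"] = x_lon
        table = cv.multilinear_fit(rows, "gradient", response="lat").set_index("term")
        for term in ("climate_vlon", "climate_velev"):
            assert abs(table.loc[term, "coef"]) < 3 * table.loc[term, "se"]

    def test_collinear_regressors_flagged(self):
        x = np.arange(20.0)
        rows = make_rows(x, x, x_elev=2 * x)
        rows["gradient_vlon"] = 3 * x
        table = cv.multilinear_fit(rows, "gradient", response="lat")
        assert table.attrs["rank_deficient"]


class TestBuildComparison:
    @pytest.fixture()
    def setup(self, grid_coords):
        lat, lon = grid_coords
        north = np.full((lat.size, lon.size), 2.0)
        v = cv.VelocityField(np.zeros_like(north), north, lat, lon,
                             np.ones_like(north, bool), method="gradient", dt=10.0)
        tracks = pd.DataFrame(
            [
                {
                    "species_id": "sp000", "decade0": "1960-1970",
                    "decade1": "1970-1980", "lat0": 40.0, "lon0": -110.0,
                    "lat1": 40.2, "lon1": -110.0, "v_lon_kmyr": 0.0,
                    "v_lat_kmyr": 2.1, "v_elev_myr": 10.0,
                    "heading_deg": 0.0, "magnitude_kmyr": 2.1,
                },
                {
                    "species_id": "sp001", "decade0": "1960-1970",
                    "decade1": "1970-1980", "lat0": 41.0, "lon0": -98.0,
                    "lat1": 41.1, "lon1": -98.0, "v_lon_kmyr": 0.0,
                    "v_lat_kmyr": 1.0, "v_elev_myr": 5.0,
                    "heading_deg": 0.0, "magnitude_kmyr": 1.0,
                },
            ]
        )
        return tracks, v, lat, lon

    def test_region_split_at_meridian(self, setup):
        tracks, v, lat, lon = setup
        rows = cv.build_comparison(tracks, v, None, split_lon=-100.0)
        assert list(rows["region"]) == ["west", "east"]

    def test_flat_dem_zero_climate_elevation_velocity(self, setup):
        tracks, v, lat, lon = setup
        dem = cv.make_dem("flat", lat, lon)
        rows = cv.build_comparison(tracks, v, None, dem=dem)
        np.testing.assert_allclose(rows["gradient_velev"], 0.0, atol=1e-12)

    def test_linear_dem_chain_rule(self, setup):
        tracks, v, lat, lon = setup
        dem = cv.make_dem("linear_slope", lat, lon, slope=5.0)
        rows = cv.build_comparison(tracks, v, None, dem=dem)
        # northward 2 km/yr over 5 m/km slope climbs 10 m/yr
        np.testing.assert_allclose(rows["gradient_velev"], 10.0, rtol=1e-6)

    def test_masked_node_flagged_invalid(self, setup):
        tracks, v, lat, lon = setup
        valid = v.valid.copy()
        east, north = v.east.copy(), v.north.copy()
        i = int(round((40.0 - lat[0]) / 0.5))
        j = int(round((-110.0 - lon[0]) / 0.5))
        valid[i, j] = False
        east[i, j] = north[i, j] = 0.0
        vm = cv.VelocityField(east, north, lat, lon, valid, method="gradient", dt=10.0)
        rows = cv.build_comparison(tracks, vm, None)
        assert not rows.loc[0, "gradient_valid"]
        assert rows.loc[1, "gradient_valid"]
        with pytest.raises(ValueError, match="3 points"):
            cv.component_fit(rows, "lat", "gradient")


class TestFitTable:
    def test_table_has_pairwise_and_aggregate_rows(self):
        rng = np.random.default_rng(11)
        frames = []
        for pair in ("1960-1970_to_1970-1980", "1970-1980_to_1980-1990"):
            x = rng.normal(0, 2, 30)
            frames.append(make_rows(x, x + rng.normal(0, 0.1, 30), pair=pair))
        rows = pd.concat(frames, ignore_index=True)
        table = fit_table(rows, methods=("gradient",), components=("lat",))
        assert set(table["pair"]) == {
            "1960-1970_to_1970-1980", "1970-1980_to_1980-1990", "all",
        }
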