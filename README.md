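# climvel

Climate-change **velocity fields** compared against **species range
shifts**, for spatial ecologists and climate-impact modellers.

When a temperature field ψ warms, its isotherms move. Two estimators of
that motion are implemented on regular lat–lon grids:

* **Gradient method** — the classical velocity index
  `v = (∂ψ/∂t)·(−∇ψ)/‖∇ψ‖²`: temporal rate of change over spatial
  gradient, directed down-gradient. Fast and local, but it assumes
  isotherms shift perpendicular to themselves and it blows up where the
  field is flat (such cells are masked and zeroed here).
* **Monte-Carlo iterative matching** — a stochastic grid-deformation
  registration: random local displacements of grid nodes are accepted iff
  they bring the warped initial field closer to the final field while a
  shear penalty keeps the displacement field spatially regular. It makes
  no perpendicularity assumption and stays finite everywhere.

On the species side, observation records (counts or presence) are passed
through survey inclusion filters, reduced to per-decade **weighted
geodesic centroids**, and converted to per-axis velocities — longitudinal
and latitudinal km/yr and, via a DEM, elevational m/yr (depths negative).
A statistics layer pairs each species with the climate velocity at its
initial centroid and reports per-decade OLS fits (slope ± SE, Pearson r,
1000 km/yr outlier threshold), aggregated linear mixed models with a
species random intercept, joint multilinear fits, circular heading
statistics, and east/west regional splits.

A synthetic-data generator (temperature scenarios with parallel, curved
or locally flat isotherms; DEMs with known slopes; species advected by a
known velocity field with tunable tracking factor and noise) makes the
whole pipeline testable offline, with brute-force oracles for the filters
and centroids.

## Worked example

Curved isotherms with longitudinally varying warming; species perfectly
track the matched field; both estimators are then scored against the
observed latitudinal shifts:

```python
import climvel as cv

scenario = cv.FieldScenario(name="composite", lat_max=49.7, lon_max=-105.3)
series = cv.make_temperature_series(scenario)
m0 = cv.decadal_mean(series, (1960, 1970))
m1 = cv.decadal_mean(series, (1970, 1980))

vgrad = cv.gradient_velocity(m0, m1)
vmatch = cv.match_velocity(m0, m1, cv.MatchConfig(seed=0))

species = cv.SpeciesScenario(n_species=40, tracking=1.0, noise_sd_km=8.0, seed=0,
                             lat_range=(38.0, 47.0), lon_range=(-117.0, -108.0))
records = cv.make_species_records(species, vmatch, range(1960, 1980))
tracks = cv.build_tracks(records, (1960, 1970), (1970, 1980), mode="birds")
rows = cv.build_comparison(tracks, vgrad, vmatch, split_lon=None)

for method in ("match", "gradient"):
    fit = cv.component_fit(rows, "lat", method)
    print(f"{method:9s} lat slope = {fit.slope:.3f} +/- {fit.slope_se:.3f}, "
          f"r = {fit.r:.3f}, n = {fit.n_used}")
```

prints

```
match     lat slope = 0.981 +/- 0.035, r = 0.977, n = 40
gradient  lat slope = 0.723 +/- 0.045, r = 0.935, n = 40
```

i.e. against species that genuinely follow the matched field, the
matching estimator recovers the shift nearly 1:1 (slope 0.98, r 0.98)
while the gradient estimator — whose vectors tilt down-gradient on curved
isotherms — under-predicts it (slope 0.72) with a weaker correlation.
On a `parallel` scenario the two estimators agree, as they must.

## Command line

A thin CLI wraps the library:

```sh
climvel simulate --scenario curved --years 1960 1980 -o sim/
climvel velocity --method match --initial d0.nc --final d1.nc --seed 1 -o v.nc
climvel centroids --records records.csv --decade0 1960 1970 --decade1 1970 1980 -o tracks.csv
climvel compare --tracks tracks.csv --gradient vg.nc --match vm.nc -o out/
climvel run --config config.yaml --seed 1 -o out/    # whole pipeline
climvel validate --config config.yaml
```

Fields travel as NetCDF (`lat`/`lon` dims; velocities `v_east`/`v_north`
in km/yr plus a 0/1 `valid` mask), records and result tables as CSV, and
every `run` writes a `manifest.json` echoing config, seed and versions.
Reruns with the same config and master seed are byte-identical.

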