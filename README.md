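# shelfshift

Assemblage-level climate-response analysis for bottom-trawl surveys.

Marine species with similar *bathy-thermal* niches — characteristic
depth, surface temperature (SST), and bottom temperature (BT) — tend to
respond to warming in similar ways. `shelfshift` implements the full
analysis chain for testing that idea on haul-level trawl-survey data
from a shelf system with two contrasting sub-regions (a semi-enclosed
northern gulf and an open southern shelf):

1. **Survey I/O** — validated haul and catch tables, a rare-species
   filter (species caught in fewer than 10 distinct years are removed),
   and the temporal scheme: four roughly decadal periods (1968–1978,
   1979–1989, 1990–2000, 2001–2012) and nine five-year blocks.
2. **Niche clustering** — per period, each species is summarized by its
   abundance-weighted mean depth/SST/BT, then clustered with both
   k-means and complete-linkage hierarchical clustering (k = 4,
   validated by connectivity, compactness, Dunn and silhouette).
   Labels are depth-ordered; *core species* are those co-assigned by
   both methods to the same label in ≥ 3 of 4 periods.
3. **Shift geometry** — biomass-weighted centroids in along-/cross-
   shelf coordinates per five-year block; shift bearing and haversine
   distance between the first and last decadal period; Rayleigh tests
   of bearing uniformity per assemblage; OLS (optionally truncated-
   normal) regressions of centroid latitude and depth on time.
4. **Thermal envelopes / climate velocity** — per species, a
   delta-lognormal GAM (binomial presence + Gaussian log-biomass, each
   with penalized spline smooths of SST and BT plus stratum and mean
   annual abundance). Prediction-weighted centroid slopes are the
   taxon-specific climate velocities (°N/yr, m/yr), compared with the
   observed slopes by OLS and contrasted across assemblages with
   Kruskal–Wallis tests.
5. **Habitat area** — weighted kernel densities of assemblage biomass
   and predicted thermal habitat on an equal-area grid; "core" area =
   cells above mean + 1 SD; and the mixed-effects model

   `kernel_area ~ thermal_area + biomass + (1 | region/season)`

   asking whether range extent follows thermal habitat or abundance.

A seeded synthetic survey generator with *analytic* ground truth
(prescribed isotherm velocities, known niche structure and assemblage
labels) makes every stage verifiable without any data download.

## Worked example

Run the whole pipeline on the default synthetic two-region world
(45 years, 70 hauls/yr/region, ~2 °C of warming over the series, four
assemblages of six species per region):

```python
from shelfshift import pipeline

bundle = pipeline.run_all(pipeline.RunConfig(seed=1))
print(bundle["tables"]["circular_north_fall"].round(3))
```

```
 assemblage  n  rbar  mean_bearing     z     p
          1  3 0.996       243.334 2.978 0.035
          2  3 0.999       261.094 2.997 0.034
          3  4 0.706       214.769 1.995 0.136
          4  4 0.509       336.850 1.036 0.378
```

The shallow northern assemblages shift coherently west-southwest
(mean bearings 243° and 261°, Rayleigh p < 0.05): warming pushes their
habitat toward the cool southwestern corner of the semi-enclosed gulf.
In the open southern region the same table shows a northeast shift
(mean bearing ≈ 26°), following the along-shelf temperature gradient —
the qualitative regional contrast the method is designed to resolve.

Per-species climate velocities sit next to the observed rates:

```python
print(bundle["tables"]["velocity_south_fall"]
      [["species", "pred_lat_slope", "obs_lat_slope"]].head(4).round(4))
```

```
species  pred_lat_slope  obs_lat_slope
  S1-00          0.0335         0.0315
  S1-01          0.0298         0.0279
  S1-02          0.0333         0.0334
  S1-03          0.0317         0.0352
```

i.e. these species are shifting north at ≈ 0.03 °N/yr, closely
tracking their thermal-envelope velocity.

The same stages are exposed as a CLI:

```sh
shelfshift simulate --seed 1 --out out/      # synthetic survey + truth
shelfshift all --config run.yaml --out out/  # full bundle + manifest
```

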