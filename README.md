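# scrubshift

Temporal and directional scrub-cover change analysis from UAV-photogrammetry
surface models.

## The problem

Scrub — transitional woody vegetation between ground vegetation and woodland,
operationally defined here purely by height (1–5 m) — is a habitat that UK
reserve managers actively keep in balance: too little and its shelter and food
value is lost, too much and open grassland succeeds to woodland. Consumer-drone
photogrammetry gives centimetre-scale surface models cheaply, and repeated
surveys can show not just *how much* scrub a site carries but *where* it grew
or was lost and *what it came from or turned into* — which is what distinguishes
deliberate clearance from unwanted succession into trees.

`scrubshift` starts where photogrammetric processing ends. Its inputs per
survey epoch are a **digital surface model** (DSM) and a **digital terrain
model** (DTM) as single-band georeferenced GeoTIFFs, plus optionally a site
boundary / exclusion polygons (GeoJSON) and field-measured verification points
(CSV). From these it computes:

1. **Vegetation height (canopy height model)** — per cell, CHM = DSM − DTM;
   negative photogrammetric noise clamped to 0.
2. **Height-band classification** — GROUND = [0, 1) m, SCRUB = [1, 5] m,
   TREES = (5, ∞) m, with class codes ground 100 / scrub 10 / trees 50.
3. **Cover accounting** — scrub area, percent of site
   (area ÷ site area × 100), stand delineation (connected components,
   8-adjacency by default) and stand size statistics; plus hypothetical
   stand-removal scenarios.
4. **Growth/loss mapping** — older scrub layer minus newer: +1 loss,
   −1 growth, 0 unchanged; rendered red/green/grey.
5. **Directional change** — older class codes minus newer, giving a unique
   code per transition (ground→scrub 90, ground→trees 50, trees→scrub 40,
   scrub→trees −40, trees→ground −50, scrub→ground −90; no-change nulled),
   with per-transition areas and site percentages.
6. **Succession vs reduction** — transitions aggregated into movement toward
   taller vegetation versus toward open habitat, the framing that matches
   open-habitat management goals.
7. **Ground verification** — raster heights and band assignments checked
   against field-measured points, reporting the largest over- and
   underestimate.

Because no survey rasters are distributed with the package, a seeded
synthetic-scene generator (`scrubshift.scenes`) builds multi-epoch DSM/DTM
pairs — smooth sloped terrain, blob/ellipse/rectangle patches of known height,
scripted transitions, optional bounded height noise — together with an exact
ground-truth ledger used as the oracle throughout the test suite.

## Worked example

Generate the built-in two-epoch demo island (heavy scripted clearance between
2019 and 2021) and run the full analysis:

```python
from scrubshift import EpochConfig, SiteConfig, generate_scene, run_site
from scrubshift.scenes import preset_two_site_demo, write_scene

spec = preset_two_site_demo()[1]
surveys, truth = generate_scene(spec)
write_scene(surveys, truth, "demo/fixtures")          # DSM/DTM GeoTIFF pairs

config = SiteConfig(
    name="demo-island",
    epochs=[EpochConfig(e, f"demo/fixtures/dsm_{e}.tif",
                        f"demo/fixtures/dtm_{e}.tif") for e in ("2019", "2021")],
    output_dir="demo/out",
    denominator_area_m2=spec.site_area_m2,
)
bundle = run_site(config)
```

which prints (via the snippet in `scrubshift.cli run`):

```
2019: scrub 99.75 m2 (15.96%), 3 stands
2021: scrub 39.25 m2 (6.28%), 3 stands
growth 12.00 m2 (1.92%), loss 72.50 m2 (11.60%)
pp diff -9.68, relative -60.65%
succession 5.62% / reduction 94.38%
```

Reading: of the 625 m² site, scrub covered 99.75 m² (15.96 %) in 2019 and
39.25 m² (6.28 %) in 2021 — a 9.68 percentage-point drop, a 60.65 % relative
decrease. 72.5 m² of scrub was lost (11.6 % of the site) against 12 m² of new
scrub; 94.38 % of all scrub-involving change moved toward open habitat
(reduction), matching the scripted clearance. `demo/out/` also holds the
per-epoch cover and stand CSVs, the change and transition GeoTIFFs and PNG
maps, and `bundle.json` with every number at full precision plus every
parameter used.

The same stages are available as shell commands:

```bash
scrubshift simulate --outdir fixtures/          # demo scenes + truth ledgers
scrubshift chm --dsm dsm.tif --dtm dtm.tif --out chm.tif
scrubshift classify --chm chm.tif --out classes.tif
scrubshift cover --mask scrub.tif --site-area 169270
scrubshift run --config site.yaml               # the whole pipeline
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's reference quantity from
scratch — it builds one-cell older/newer surveys with band-typical heights
drawn from the seeded generator, classifies them, and reads the code that the
transition encoder emits for a ground→scrub cell:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The JSON output maps each target id to the value measured at run time.
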