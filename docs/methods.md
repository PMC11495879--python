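# Methods

This note records the scientific and numerical choices behind `scrubshift`:
what the pipeline computes, the conventions adopted where standard GIS practice
leaves more than one defensible option, what the synthetic scenes do and do not
emulate, and the package's known limits.

## Vegetation height and classification

**Canopy height model.** Per cell, CHM = DSM − DTM, in 64-bit floating point
(verification errors are meaningful at centimetre scale, so heights are never
carried in reduced precision). Nodata in either input propagates. Because both
surfaces come from the same reconstruction, any vertical datum offset (e.g.
altitudes referenced to the drone's launch position) cancels in the difference;
no datum correction is applied or needed.

**Negative heights.** Photogrammetric noise can place the surface below the
terrain. Heights below ground are physically meaningless, so negative CHM
values are clamped to 0 by default (`clamp_negative=True`), which places those
cells in the ground band. The raw difference is available with the clamp off.

**Height bands.** GROUND = [0, 1) m, SCRUB = [1, 5] m, TREES = (5, ∞) m.
The closure at 1 m is not arbitrary: field verification points deliberately
straddle that boundary (ground vegetation measured at 0.984 and 0.991 m, scrub
at 1.015 and 1.04 m), which forces exactly-1 m to the scrub side. The 5 m
closure is unconstrained by any measurement; it is assigned to scrub so the
stated "1–5 m" range is inclusive on both ends. Every finite non-negative
height maps to exactly one band (the partition is a tested invariant).

**Class codes.** Ground 100, scrub 10, trees 50 by default. The point of these
particular values is that all six ordered pair differences
({90, 50, 40, −40, −50, −90}) are distinct and nonzero, so a single subtraction
encodes the full transition matrix. User-supplied codes are validated for this
collision-freeness at construction — a code map that silently broke transition
decoding would corrupt every directional result downstream.

## Clipping and alignment

**Cell inclusion.** A cell belongs to a polygon iff its *centre* is inside,
with boundary-touching centres counting as inside (closed test). This is the
common GIS semantics, is deterministic, and preserves partitions (a cell can
never be claimed by both the boundary's inside and outside). Clipping only
writes nodata — retained values are untouched and the transform is unchanged —
so it is idempotent.

**No reprojection.** All inputs to one analysis must already share a CRS tag;
mismatches are errors, and reprojection is considered preprocessing. This
keeps the raster core free of projection machinery.

**Cross-epoch grids.** Epochs are flown at different ground sample distances,
so change arithmetic needs a common grid. The pipeline aligns to the
*coarsest* epoch's grid, block-averaging the finer CHM (nodata-aware mean of
contributing source cells) *before* classification. Averaging continuous
heights is well defined; averaging class codes is not, so classes are never
resampled. `nearest` is available as an alternative for workflows that need
it, and upsampling with `block_average` is rejected rather than silently
interpolated.

**Denominator.** Cover percentages divide by a single site denominator:
an explicitly configured area (sites are commonly quoted against an official
reserve area, e.g. 169,270 m², or a clipped study area, e.g. 167,156.45 m²),
else the boundary polygon's area, else the clipped raster's data area. Change
percentages use the same denominator even though change rasters exclude cells
nodata in either epoch — every percentage in one analysis refers to the same
site area.

## Stands, change and shares

**Stands.** Maximal connected components of scrub cells. Connectivity defaults
to 8 (a corner touch joins a stand — the more inclusive ecological reading of
a contiguous patch) and may be set to 4. Stand ids are deterministic:
consecutive from 1 in row-major order of each stand's first cell. Stand area
is cell count × cell area exactly, and the table total is computed as total
cell count × cell area so the accounting identity holds without float
summation error.

**Subtraction order.** Older − newer, everywhere. For 0/1 scrub presence
grids this yields +1 = loss, −1 = growth (growth carries a negative raw value
internally and is relabelled at the reporting layer); for class codes it
yields the transition table above, with 0 (no change) set to nodata.

**Succession vs reduction.** Succession = {ground→scrub, scrub→trees},
reduction = {scrub→ground, trees→scrub}; shares are each side's area over
their sum. Ground↔trees transitions are always *computed and reported* but by
default *excluded from the shares*, because site reports of scrub change are
normally framed around scrub-involving transitions; a flag
(`include_ground_tree_shares`) adds ground→trees to succession and
trees→ground to reduction. The shares always sum to 100 when any change in the
basis exists.

**Rounding.** Confined entirely to the presentation layer (CSVs at 6 dp,
human-readable summaries at 2 dp, matching how such results are reported);
`bundle.json` and all return values carry full precision. Re-running on
identical inputs yields byte-identical outputs.

## Ground verification

Raster height is sampled at the cell containing each field point (band
membership is a per-cell property in this pipeline, so interpolation would
test a quantity the classification never sees). The report counts band
mismatches, and gives the largest overestimate (raster − measured, where
positive) and underestimate — the two consistent-error bounds usually quoted —
plus the full per-point signed error table, which is strictly more informative
and costs nothing. Points outside the extent or on nodata are flagged in the
table, never silently dropped.

## Synthetic scenes

The generator emulates the *geometry and arithmetic* of paired-epoch
photogrammetric surveys, not their optics:

* **Terrain** — a plane (default slope ~0.15 m/m, echoing a steep bank site
  whose elevation spans tens of metres) plus seeded low-frequency Gaussian-
  smoothed bumps (default amplitude 1.2 m). A non-flat terrain is essential:
  it exercises the DSM−DTM cancellation rather than letting CHM equal DSM.
* **Patches** — ellipse / rectangle / random-blob footprints with a programmed
  height; scrub patches 1–5 m, tree patches above 5 m. Footprints of patches
  present in the same epoch must be disjoint, otherwise generation fails —
  overlapping truth would be ambiguous.
* **Epoch scripts** — per patch: appear, persist, clear to ground, grow to
  trees (default 6.5 m), explicit height, or height drift. These produce exact
  per-transition cell counts in the truth ledger.
* **Noise** — optional, DSM-only, *bounded uniform* (not Gaussian), defaulting
  off; the bound constants shipped (`+0.016 m / −0.04 m`) are the verified
  over/underestimate bounds from real ground verification, the only error
  information such surveys report. Bounded noise inside the band margins
  provably cannot change any patch cell's class, which is tested.
* **Determinism** — one explicit seed in the spec, `numpy.random.default_rng`,
  no global state; identical spec + seed gives bit-identical rasters through
  the GeoTIFF writer.

The truth ledger (class grids, per-patch areas, stand counts via an
independent BFS, per-transition cell counts) is computed from the patch
geometry directly, not through the analysis pipeline, so end-to-end equality
of pipeline output and ledger is a genuine two-route check.

**What a green test does not establish:** the scenes contain no
reconstruction artefacts (doming, melted edges, shadow holes), no
co-registration error between epochs, no DTM error under canopy, and no
spatially correlated noise. Green tests establish the *accounting* is exact
given correct surface models; they say nothing about photogrammetric quality.

## Numerical and degenerate-input choices

* Heights float64 end to end; class and change rasters int16.
* Nodata sentinels: −9999.0 (heights), 255 (class codes), both configurable;
  change rasters use −128 and transition rasters −32768 internally.
* Empty scrub masks: 0 stands, 0 m², 0.00 % — not an error. Zero or negative
  site denominators, non-binary masks, mismatched grids/CRS/code maps,
  multi-band GeoTIFFs: errors, each naming the offending input.
* A boundary polygon disjoint from the raster extent is an error rather than
  an empty result (it is almost certainly a units or CRS mistake).
* Relative change from a zero-area older epoch is NaN, not an exception.
* The one-cell example in `scripts/acceptance.py` draws its band-typical
  heights from the seeded generator so the emitted transition code is computed
  by the pipeline at run time, not restated.

## Known limitations

* No reprojection, no multi-band imagery, no point clouds; single-band
  GeoTIFF + GeoJSON only.
* Stand identity is not tracked across epochs (a stand that splits counts as
  new stands); no shape metrics beyond area.
* Only two-epoch change analyses (consecutive pairs and oldest-vs-newest);
  no >2-epoch trajectory modelling.
* The printed relative-change figures in some historical site reports differ
  from recomputation by a few hundredths of a percent because they were
  computed from unrounded internals; this package always computes from full
  precision and reports what it computes.
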