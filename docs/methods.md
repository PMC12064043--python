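# Methods

This note documents the accounting procedures, the synthetic-data model,
the numerical conventions and the design choices made where the published
accounting practice leaves the design open.

## Accounting frame

All accounts are compiled per socio-ecological landscape unit (SELU): a
sub-watershed labelled by its dominant land-cover group. The grouping
table (class → SELU group) is configuration; the default maps village to
Human footprint, rice/sugar-cane/crops to Agricultural landscape,
savannah and shrubland to Shrubland, the two dry-forest densities to
Forest landscape, the three mangrove densities to Mangrove Landscape,
phragmites/raffia/inland water to Wetland, and tan/barren to Estuary.
Exact area ties are broken by a fixed priority order (Forest > Mangrove >
Wetland > Shrubland > Agricultural > Estuary > Human footprint) —
conservative toward natural classes and deterministic under pixel
reordering. SELU geometry is one unit per watershed and never changes
between dates; only the label may flip.

## Land-cover account

Internally everything is exact pixel counts; hectares are produced by a
single multiplication with the pixel area, and rounding happens only at
presentation. A pixel that is nodata at either date is excluded at both,
keeping the opening and closing universes identical. The default flow
rules are destination-driven with origin overrides (see
`landcover.FlowRules`); since published accounts do not print the
cell-level mapping, every cell is overridable via YAML. Stock closure
(`closing = opening + F − C`) is an identity of the data structure, not a
post-hoc check.

## Water account

Volumes are in 1000 m³/yr. The total-outflow row W3 sums *all* supplied
`W3_x` line items rather than a fixed list, because published W3 totals
exceed the sum of the commonly printed four components — unprinted
components exist and must not be silently dropped. W3_2 (transfers)
defaults to zero; it appears only inside the W6 formula. W14 (composite
health) is an input: no formula for it is published; the synthetic
generator emits 0.95.

The actual-evapotranspiration estimate scales period precipitation by a
climatological ratio. The ratio printed in the accounting literature,
`Pavg/ETravg`, yields ETr > P whenever the climate is wetter than its
evaporative demand, which contradicts the quantity's meaning; the default
orientation is therefore the inverted ratio `ETravg/Pavg`, with the
as-printed orientation available (`orientation="as-printed"`) and a
warning logged when it inflates ETr beyond P. The discrepancy is
documented rather than silently fixed.

## Carbon account

Masses in tonnes C. As with water, C1/C2/C3/C4 sum whatever component
lines are supplied. C10_1 (net accessible inflow) is an input line; the
helper `max(0, C2 − C5)` is provided for synthetic data but not applied
to user inputs. Underground (root) carbon is treated as static between
dates — no root-stock flow is generated. CEH defaults to 1.

## Index conventions shared by the three accounts

* Use indices (W13, SCU, EISU) are capped ratios `min(1, resource/use)`;
  a zero denominator (no use at all) maps to 1, and a negative numerator
  clamps to 0.
* Internal unit values (W15, CIUV, EIIUV) combine a use index with a
  health index. The published tables consistently equal the **arithmetic
  mean** of the two (never their product, despite prose describing a
  multiplication), so the mean is the default; `combiner="product"` is
  available.
* Total columns: volumes and masses sum across SELUs; indices average
  (unweighted) across SELUs.
* All downstream multiplications chain at full precision; two-decimal
  index values are presentation only.

## Infrastructure account

GBLI is the area-weighted mean of per-class greenness weights (0–100).
Default weights place water/barren/village at 0–20, crops at 45–55,
savannah/shrubland at 65–70 and forest/mangrove at 75–95, so that forest
SELUs land in the 80–90 range typical of published accounts; the table is
configuration.

The fragmentation index is the mean of three components, each normalized
to [0, 1] so that an intact landscape scores 1 (the published practice
averages the three but does not state normalizations; these are this
package's declared choices, overridable):

* effective mesh size `meff = Σ Aᵢ²/A_total` (Jaeger), normalized by the
  SELU area — patches are 4-connected components of the habitat-class
  mask;
* patch count, as `1/N_patches` (1 for a single patch);
* tree-cover : basin-area ratio, clamped to [0, 1].

HNVI is an input zoning layer (multiplier ≥ 1), not derived from
protection categories; the SELU value is the mean multiplier over its
pixels, and the river HNVI reuses it (published river and land values
coincide in every SELU). River fragmentation is `1/(1 + n_dams)` per
watershed. RAWI uses log base 10 (configurable); segments are clipped to
the SELU polygon with contribution proportional to the clipped length.

NLEP is computed per pixel and then summed —
`Σ gbli·hnvi·fi/100 × pixel_area` — because SELU-mean LEP × area is not,
in general, equal to the pixel aggregate; NREP is `REP × area/100`. These
aggregation orders are declared conventions. TEIP = NLEP + NREP. The
per-year TEIP adjustment is a declared calibration scalar pair applied
uniformly to all SELUs; its derivation is not published, so the library
default is neutral (1.0, 1.0) and the calibration of the bundled
reference dataset (1.12869, 1.08544 — fitted once from the constant
within-year adjusted/raw ratios) is carried with that dataset.

## Capability account

`ECU_P = (CIUV + W15 + EIIUV)/3` per SELU; capabilities are the
accessible resources scaled by ECU_P, and TEC is their sum. EIIUV is
computed once from the inter-date infrastructure account and used for
both dates' ECU_P. Per-SELU percentages in the balance table round to
integers; the debt/credit label follows the sign of ΔTEC. Capability
requires a shared SELU frame across dates (the watershed partition);
relabelled dominant land cover does not change the frame.

## Synthetic scene generator

The generator emulates a dry-tropical protected-area landscape and is the
test substrate for every spatial operation:

* **Land cover** grows contiguous patches by randomized multi-source
  flood fill (seeded heap), because fragmentation metrics are
  meaningless on i.i.d. noise; every palette class receives at least one
  seed point.
* **Watersheds** are Voronoi cells of random seed points snapped to
  pixel boundaries — an exact partition with irregular shapes, no DEM
  required.
* **Rivers** form a random spanning tree over watershed centroids
  draining to the outlet nearest the grid edge; discharge accumulates
  with the number of upstream watersheds, so it decreases upstream, and
  scales with the period's precipitation.
* **Protection zones** are rectangles in fractional grid coordinates
  carrying a multiplier ≥ 1.
* **Line items** are deterministic functions of land-cover composition,
  river geometry and climate: precipitation and evapotranspiration
  volumes follow directly from depth × area (1 mm·ha = 10 m³), runoff
  uses a 0.35 coefficient on own and upstream area, abstraction scales
  with village and agricultural area, carbon stocks and NPP come from
  the per-class density table, withdrawals from per-hectare harvest
  rates, and the protection-limitation index interpolates from 0.7
  (unprotected) to 0.1 (fully protected). No extra noise is injected:
  with identical rasters and climate at both dates every account is
  identical and the ecological balance is exactly zero, which is the
  invariant the end-to-end tests assert.

Default conditions: 96×96 pixels of 0.0225 ha (15 m), the 16-class
nomenclature, 7 watersheds, 1554 mm/yr average precipitation with period
values 1554 mm (opening) and 1453 mm (closing), 1300 mm/yr average
evapotranspiration, one protection zone at weight 1.14. Tests use smaller
grids (20–48 px side) to keep the suite fast.

What the generator does **not** emulate: classification error and mixed
pixels, seasonal compositing, DEM-consistent hydrology (Voronoi cells are
not drainage basins), groundwater dynamics, bathymetry, and household
survey noise in the use items. Passing tests therefore demonstrate the
correctness of the accounting arithmetic and aggregation on known truth,
not the fidelity of any remote-sensing or field workflow.

## Bundled reference dataset

`enca.datasets` carries the published accounts of the Mahavavy-Kinkony
Complex protected area (Madagascar, 350,762 ha, accounting period
2013–2018): the land-cover stock/flow table, water and carbon line items,
infrastructure index inputs and the capability tables. Published integer
tables round their internals, so recomputed sums can differ from printed
rows by a few units; the regression tests assert derived volumes within
that printed drift (±3) and indices exactly at two decimals. Two explicit
residual lines (C2_9, C3_9) reconcile component sums with published
totals, and the protection index C10_2 is stored at the precision implied
by the published C10/C10_1 ratio.

## Numerical and degenerate-input conventions

* Rasters: ESRI ASCII grids (integer class codes, explicit nodata);
  vectors: GeoJSON; tables: CSV. Everything round-trips exactly.
* Empty (all-nodata) watersheds are flagged and excluded from accounts.
* `EISU` is undefined for a zero adjusted opening TEIP and raises.
* Effective mesh size of an empty habitat mask contributes 0 to FI.
* A zero opening TEC leaves the balance percentage undefined (None) with
  the label still reported.
* All randomness flows from a single integer seed
  (`numpy.random.default_rng`); scenario pixel choice is additionally
  keyed by a hash of the scenario so different scenarios draw
  independent, reproducible streams.

## Known limitations

* The fragmentation normalizations and the NLEP/NREP aggregation orders
  are declared conventions; published values for these quantities are
  carried as dataset inputs, not re-derived from pixels.
* The TEIP adjustment scalar is calibration, not model.
* W14, CEH and EHI (health indices) are exogenous inputs throughout.
* River geometry in the generator is schematic (centroid-to-centroid
  reaches), adequate for index arithmetic but not for hydrographic
  analysis.
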