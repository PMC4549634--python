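# Methods

## Problem and model

Presence-only occurrence records from open biodiversity databases carry no
notion of survey effort: absence of a record confounds "species absent" with
"nobody looked". The package quantifies the second possibility per grid
cell, using a *reference taxonomic group* as a surrogate for effort. The
assumption is behavioural: observers are fond of groups (birds, butterflies),
not individual species, and a whole group surveyed by the same methods
shares the same spatial bias. Many reports of *any* group member in a cell
therefore raise the credibility that a missing focal-species record there is
a true absence.

Three deliberate restrictions shape everything downstream:

1. **Raw data only.** Scores are computed from per-cell summaries of the
   records themselves — no covariates, no interpolation, no model fitting.
   This keeps scores comparable across taxa and regions and keeps the
   assumption count minimal.
2. **Same-methodology rule.** The reference group must not mix survey
   methods (e.g. butterflies *sensu stricto* vs. moths within Lepidoptera);
   mixing breaks the shared-bias assumption. The package takes the group
   label as given and filters on it; composing a defensible group is the
   analyst's task.
3. **Focal-species exclusion and long time frames.** When the output will
   correct background bias for the focal species' own model, that species is
   removed from the reference group (`FilterSpec.exclude_taxa`); long date
   windows damp temporal variability in effort. Both are filters, not
   defaults — date bounds are inclusive at both ends.

## Effort and the three transforms

Per-cell effort `x_i` is either the raw count `N_i` or the species
observation index `O_i = N_i / R_i` (0 where `N_i = 0`). The index suits
list-keeping observer cultures (birders): it measures observations per
observed species, so `O_i ≥ 1` wherever anything was seen. The choice is
the caller's; provenance always records which was used.

- `I_i = 1 − x_i / x_m` (normalization) and
  `I_i = 1 − ln(x_i + 1)/ln(x_m + 1)` (log-normalization) rescale against
  the dataset maximum `x_m`, taken over the valid, in-region cells of the
  supplied layer only — never a global constant — so both are sensitive to
  the spatial/temporal extent of the dataset. The logarithm is natural; the
  added unit sends empty cells to exactly 1. Log-normalization lies at or
  below normalization everywhere (concavity), with equality only at 0 and
  `x_m`, which is what makes it the right choice for long-right-tailed count
  distributions.
- `I_i = O50 / (x_i + O50)` (half-ignorance) ignores `x_m` entirely. `O50`
  (> 0, effort units) is the effort at which the score is exactly 0.5 — the
  analyst's statement of how much a single observation is worth. Larger
  `O50` decays slower. Because scores depend only on the cell's own effort,
  appending better-sampled cells never changes existing scores; this is the
  algorithm to use when comparing datasets with different maxima.

Degenerate all-zero layers raise an error for the two normalizing forms
(`x_m = 0` leaves the formula undefined) but legitimately return all ones
for half-ignorance. Scores are clamped to [0, 1] after computation purely to
absorb floating-point rounding; the clamp is asserted to move nothing by
more than 1e−12.

## Gridding conventions

The grid is regular and axis-aligned in projected planar coordinates; the
extent is expanded outward at construction to whole multiples of the cell
size. Cell membership is the half-open square `[x0, x0+s) × [y0, y0+s)`,
with points on the global top/right edge of the extent assigned to the last
row/column, so every in-extent point lands in exactly one cell. Arrays use
image convention (row 0 = north). Records outside the extent, or outside
the optional region polygon (cell membership = centroid inside polygon),
are counted and surfaced, never silently dropped; the conservation identity
`ΣN + out_of_extent + out_of_region = n_records` is tested. Identical
records count separately — the data are reports, not events — with an
explicit `dedupe_records` opt-in. Taxon names are normalized lexically
(trim, collapse whitespace, casefold) with no synonym resolution, which
would require an external taxonomic backbone.

Resolution matters: refining cells redistributes counts without changing
their total, and scores at different resolutions are not comparable.
Choosing a resolution relevant to the species' biology is left to the user.

## File formats

Rasters are single-band float64 GeoTIFFs written and read with `tifffile`,
with the geotransform in ModelPixelScale/ModelTiepoint tags, the CRS
identifier in a GeoKeyDirectory (plus citation string), and NoData as a
declared sentinel (default −9999) in the GDAL_NODATA tag; in memory NoData
is always an explicit boolean mask, never sentinel arithmetic. Reading with
an expected grid enforces exact extent/resolution/CRS equality — misaligned
layers are an error, never silently resampled. Region polygons are GeoJSON
or WKT (invalid geometry is repaired with `make_valid`). Pre-summarized
per-cell tables use columns `cell_x, cell_y` (cell lower-left corner),
`n_obs, n_species`, with `n_species ≤ n_obs` enforced row-wise.

## Downstream conventions

Masking removes cells with `I` *strictly greater* than the threshold;
pseudo-absence selection keeps cells with `I ≤` threshold (and zero focal
records, inside the region). The conventions are complementary so the two
partitions tile the focal-absent region at a shared threshold. The Bernoulli
prior layer evaluates `p_i = 1 − (1 − I_i + 0.5·I_i)`, algebraically
`0.5·I_i`; it emits probabilities only — sampling outcomes belongs to the
caller's estimation loop, and the layer is meant to parameterize priors for
cells without focal observations.

## Synthetic data generator

`ignomap.simulate` emulates opportunistic recording: a cell-level intensity
surface (uniform baseline + isotropic Gaussian observer hotspots evaluated
at cell centroids), multinomial allocation of a fixed record total across
cells, uniform point placement within the cell, taxa drawn proportionally to
per-species detectability, and uniform dates in the scenario window. The
reference scenario is a 20 × 20 grid of 1 km cells, three hotspots of
weights 8/5/3 and spreads 2–3 km over a 0.2 baseline, and a ten-species
pool with geometrically spread detectabilities (1–20×) so common species
dominate reports — magnitudes chosen once as a plausible opportunistic
butterfly-recording landscape. At 50,000 records the end-to-end check
(sample → grid → score) requires Spearman ρ > 0.9 between certainty and
true intensity for every algorithm.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: observer-level clustering in time (visits, trips),
detection differences across habitats, spatial variation in species
composition, misidentification, and coordinate uncertainty. The generator
validates the pipeline's mechanics and ranking behaviour, not the ecological
fidelity of any particular ignorance threshold.

## Problem sizes

Tests run on grids up to 20 × 20 with up to 50,000 simulated records, 100
randomized gridding instances against a brute-force oracle, and 10⁶ random
scores for the prior identity; the full suite completes in a few seconds.

## Known limitations

- No reprojection: coordinates must arrive in the grid's CRS; the CRS string
  is metadata only.
- No shapefile reader: region masks are GeoJSON/WKT.
- Edge cells are in/out by centroid; partially covered boundary cells are
  all-or-nothing.
- The `counts` effort route through the CLI stores a placeholder richness
  (1 where N > 0) when only an N raster is supplied; the species observation
  index requires the real richness raster or summary table.
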