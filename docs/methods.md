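# Methods

This note documents the models implemented in `kelpcanopy`, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical conventions chosen where the underlying procedure leaves
them open.

## Geometry and rasters

All geometry is planar Euclidean in a projected CRS (meters); geographic
coordinates and reprojection are out of scope. Rasters are north-up,
0-based, center-registered: the center of cell (row, col) is at
`origin + ((col+0.5)·px, −(row+0.5)·px)`. Missing values are NaN, distinct
from 0 (absent kelp). Rasters are stored as TIFF with a JSON sidecar
carrying the grid (origin, pixel size, CRS id); reflectance is quantized to
int16 at scale 1e-4, so round-trips are exact at that fixed-point
resolution. The 10 m consensus grid nests exactly 3×3 into the 30 m
analysis grid (shared origin); block-mean resampling averages the non-NaN
members of each 3×3 block and is missing only when all nine are.

The coastline is an ordered polyline cut into consecutive 1 km arclength
segments, with interpolated vertices at the cut points so segment lengths
sum exactly to the polyline length; only the final segment may be short.
Distances (the 120 m / 4.5 km window, segment assignment) are measured to
full segment geometry — edges, not midpoints or vertices — and segment ties
break to the lower id.

## Spectral branch (decision tree + MESMA)

Candidate screening is a CART (Gini, default `max_depth` 5, seeded) over
the six reflectance bands plus NDVI, trained on labeled pixels from a
synthetic scene; a fixed no-training rule (NDVI > 0 and NIR > 2× median
offshore NIR) is provided as a fallback. Training labels call a pixel a
*candidate* at true fraction ≥ 0.05 — deliberately below the 13%
presence threshold — so the screen has essentially perfect recall at the
threshold and the fraction estimate, not the screen, decides presence.

MESMA evaluates one two-endmember model per water endmember:
`s ≈ f·k + (1−f)·w`, sum-to-one enforced, `f` unconstrained (negative and
>1 estimates are retained; the > 300% filter depends on them). The
least-squares `f` has the closed form `⟨s−w, k−w⟩/‖k−w‖²`; the model with
minimum 6-band reconstruction RMSE wins, ties to the lower water id, and a
water endmember equal to the kelp endmember is rejected as degenerate.
Presence is `f ≥ 0.13`, boundary inclusive.

Water endmembers (default n = 30 per scene) are sampled uniformly
(seeded) from unmasked ocean more than 1 km offshore after excluding
NIR-bright outliers above the offshore 95th percentile. When the screen
has already run, its candidate mask is additionally excluded: in regions
where beds extend past 1 km offshore, kelp-mixed spectra otherwise enter
the water library and bias every fraction low (we observed up to a 14%
area deficit without the exclusion).

## Filter cascade

Rules run in the order distance → over-range → prevalence → tide
correlation → spatial coherence, geometry first so the statistical rules
see only geometrically plausible pixels; the cascade is idempotent. All
boundary comparisons follow the strict inequalities of the rule
definitions (< 120 m, > 4.5 km, < 2%, > 300%, r < −0.25, r < 0.2).
Correlation rules use the fractional (not binary) series, require at least
5 paired observations, and never mask zero-variance (undefined) series.
Prevalence applies only to pixels with at least one presence. Under the
coherence rule a kelp pixel compares against the mean fraction series of
all other kelp pixels within 5 km; a pixel with no neighbor in that radius
is masked — a lone 30 m kelp pixel 5 km from any other kelp is almost
surely a false positive. The per-rule audit counts pixels newly masked by
each rule (pixels already all-missing are not re-counted).

## Citizen-science branch

Tiles are 1.5 km × 1.5 km (2.25 km²); each is annotated by 15 independent
users. A cell receives one vote per user whose union of polygons covers
the cell center, so overlapping polygons from one user never double-count.
Consensus presence is votes ≥ tau (default 8), cleaned by removing votes
on land or > 4.5 km offshore — nearshore votes are retained, since human
annotators exploit spatial context that per-pixel spectra lack. Composites
resample to 30 m (binarizing the block mean at > 0, i.e. any kelp in the
block) and average by July–June year or austral quarter; an interval is
dropped when under 25% of applicable (ocean, ≤ 4.5 km) pixels were
observed at least once. Threshold optimization binarizes at each tau in
1..15, resamples the same way, pools the confusion counts over matchups
and maximizes MCC (exact integer arithmetic; defined 0 when a denominator
factor vanishes; ties to the lower tau).

## Validation

Sources are compared on per-segment kelp-pixel counts restricted to the
same 120 m – 4.5 km window the spectral branch uses, with zero-count
segments retained to avoid selection bias. R² is the squared Pearson
correlation of the paired aggregates (identical to OLS R² for simple
regression, free intercept); RMSE is also expressed as a percentage of the
expert aggregate range; bias is mean(test − expert).

## Timeseries and environment

Annual intervals run July–June and are labeled by the June year; seasons
are austral quarters (DJF, MAM, JJA, SON). Per sensor per interval the
area is 900 m² × the mean per-scene kelp-pixel count; the multisensor
merge weights each sensor by its scene count, which equals the pooled
per-scene mean. Trends are OLS on interval index with a two-sided t-test;
a constant series has slope 0 and p = 1 by convention, and an exactly
linear one p = 0. The synthetic nitrate proxy is a least-squares line of
nitrate on temperature with predictions clipped at zero; annual
environmental drivers are July–June means of monthly clipped predictions
from SST. Lag correlations (lags 0 or 1 only — giant kelp fronds turn
over within about a year, so longer memory is implausible) are Pearson r
with the t-transform p-value and require ≥ 5 overlapping intervals;
per-segment correlations z-score each segment's series first, which leaves
r unchanged but matches how standardized canopy extents are reported.
Neither trend nor correlation inference corrects for serial
autocorrelation; for strongly autocorrelated series the reported p-values
are anti-conservative. This is a known limitation.

## Synthetic data: what it emulates, and what it does not

Scenes are linear kelp/water mixtures: beds are elliptical with a flat-top
profile (exactly the peak fraction inside 60% of the radius, linear ramp
to zero at the edge), so noiseless scenes contain both pure and mixed
pixels and unmix exactly. Reflectance noise is i.i.d. Gaussian per band
(default sd 0.005, a plausible surface-reflectance noise level at these
signal levels); confusers are NIR-bright glint pixels, spectrally flat
debris patches, and cloud blobs. Bed dynamics follow a multiplicative
AR(1) on the log scale; an optional tide-artifact bed has apparent
fraction max(0, 0.5 − 0.4·tide) to exercise the tidal filter. Tides are
semidiurnal (12.42 h) with 0.5 m amplitude (~1 m range). Annotators
outline the convex hull of each true patch (humans draw rounded vectors,
not pixel outlines), jittered by a boundary sd, detect each patch with a
probability non-decreasing in patch area, add false-positive polygons at a
Poisson rate per tile, and optionally outline debris decoys. In-situ
temperature–nitrate pairs follow N = a + b·T + ε with defaults a = 45
μmol/kg, b = −2.4 μmol/kg/°C, ε sd = 4.6 μmol/kg over T ∈ [5, 19] °C —
cold subantarctic water with nitrate scatter near 13% of the nitrate
range. The annual canopy driver is standardized nitrate lagged one year
plus Gaussian noise of variance 1.367, so its population lag-1 correlation
with nitrate is 1/√2.367 = 0.650.

Passing tests on these data demonstrate algorithmic correctness, not
real-image performance: the generator has no atmospheric-correction
residuals, no sensor point-spread function or band-response differences,
no bottom reflectance or turbid plumes in the nearshore, spatially white
noise, and annotators far simpler than real crowds. One visible
consequence: with the default near-perfect annotators the MCC-optimal
consensus threshold sits at the top of the range (every user over-draws
bed edges slightly and misses nothing), whereas the planted-error study —
kelp patches detected at 0.7 per user against debris decoys at 0.3, whose
Binomial(15, ·) vote distributions cross between 7 and 8 — has its
population MCC optimum at 8 and is recovered there in ≥ 90% of seeds.

## Problem sizes

Tests and the pipeline default to 60–100 pixel square grids (1.8–3 km of
coast, 3–5 segments), 8–24 scene dates, and 12–35 environment years; the
lag-correlation study uses 500 replicates of 35-year series. These sizes
give each statistical check comfortable power while keeping any single
test in seconds.

## Known limitations

- No autocorrelation correction in trend/correlation inference (above).
- Linear mixing with a single fixed kelp endmember; no glint or cloud
  endmember classes beyond the water library.
- The decision-tree screen is a trainable stand-in with the same role as
  published screens, not a re-derivation of any specific published rule
  set.
- The 25% composite completeness rule interprets its denominator as
  applicable ocean pixels of the region; other readings (tiles, days) are
  possible.
- Coastline distance and segment assignment assume a projected CRS; no
  geodesic support.
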