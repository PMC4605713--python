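# Methods

## Model and procedure

The package computes analog-based velocity of climate change on gridded
data.  Let $x_i \in \mathbb{R}^p$ be the bioclimatic variables of cell
$i$ with centroid coordinates $(\lambda_i, \phi_i)$, observed for a
current period and, per GCM $g$, a future period.

1. **Ordination.**  Variables are centered and scaled to unit standard
   deviation on the fit basis and projected onto principal components
   ($z_i = L^\top (x_i - \mu)/\sigma$), so Euclidean distance on the
   scores approximates a Mahalanobis distance on the raw variables.
   Components are retained while their variance fraction exceeds
   `min_fraction` (default 0.02).  By default the transform is fitted on
   the pooled current + future cells so that novel future climates have
   well-defined scores; a `current_only` basis is available and the
   choice is recorded in the model object.  Constant variables are
   dropped with a warning (synthetic edge cases produce them); component
   signs follow the largest-magnitude-loading-positive convention so
   results are reproducible across linear-algebra backends.
2. **Binning.**  Retained axes are cut into equal-width bins
   ($\mathrm{code}_k = \lfloor (z_k - f w)/w \rfloor$, width $w$ = 2 PCA
   units by default, offset fraction $f$).  Cells are analogous iff all
   codes match.  The same width on every axis makes an axis's resolution
   proportional to the variance it explains.
3. **Matching.**  For each source cell the *exact* nearest same-bin
   target cell is found (targets grouped by bin code; within-bin
   distances computed in blocks; ties broken by lowest target cell id).
   Distances are haversine on a sphere of radius 6371 km between cell
   centroids; a planar mode (grid indices × cell size) exists for
   constructions with closed-form geometry.  An approximate search is
   deliberately not used: exactness is what makes the brute-force oracle
   tests meaningful, and the grids involved are small enough.
4. **Offset averaging.**  Replicate $j$ of `n_offsets` (default 100)
   uses $f = j/n$ on all axes simultaneously.  Per cell, distances are
   averaged over replicates that found an analog and divided by
   `years_between`; the fraction of replicates without an analog is
   reported as the no-analog probability.  Cells without any analog stay
   NaN — assigning them an arbitrarily high velocity would obscure the
   patterns, so disappearing (forward) and novel (backward) climates are
   always tabulated separately.
5. **Ensembling.**  Per-GCM velocity fields are averaged per cell over
   members with defined velocity; the sample sd (n−1) across members and
   the mean member no-analog probability accompany the mean.

**Biotic velocity** replaces "same climate bin" by "suitable for species
s": forward assigns each current-range cell the distance to the nearest
future-suitable cell (0 if the cell itself remains suitable), backward
the reverse; distance / `years_between` gives km/yr.  Species whose
future suitable set is empty under a GCM carry no finite distance; they
are excluded from velocity means and captured by the **disappearance
probability**: per cell, over (species currently suitable there) × GCMs,
the fraction of combinations with an empty future range.  A probability
rather than a count keeps the metric from tracking current richness
gradients (duplicating every species leaves it unchanged — tested).  The
disappearance metric is range-wide, mirroring the definition of
disappearing climates as bins absent from the future census; a site-level
loss variant (`site_loss_probability`) is provided separately.  Taxon
aggregation first averages each species over GCMs per cell, then takes
mean and sample sd across species; the across-GCM sd is the sd over GCMs
of the per-GCM across-species mean.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `bin_width` | 2 | PCA units | balances information loss (broad bins → zero velocities) against no-analog domination (narrow bins); `bin_width_sensitivity` reproduces that trade-off curve |
| `n_offsets` | 100 | — | removes bin-origin artifacts; averaged distances are stable to ~1/n |
| `years_between` | 110 | years | midpoint 1975.5 of a 1961–1990 normal to midpoint 2085.5 of 2071–2100; the divisor is configurable because period labels alone do not fix it |
| `min_fraction` | 0.02 | — | retention rule for PCA axes |
| `min_area_km2` | 200 | km² | protected areas at or below this are excluded from the quadrant assessment |
| `cell_size_km` | 50 | km | grid resolution of all synthetic worlds |

## Summaries layer

Spearman correlations (average ranks, pairwise NaN dropping; no-analog
cells are excluded and the exclusion is the caller's visible NaN count).
Latitudinal profiles use a Gaussian GAM with a cubic B-spline basis
(default df 25) fitted by penalized IRLS; the penalty weight is chosen by
generalized cross-validation over a log-spaced grid unless fixed.  A
constant response short-circuits to the constant (the penalized fit is
degenerate there).  Zonal distributions use Gaussian KDE with Silverman's
bandwidth; `by_cell` summarizes per-cell values, `by_species` per-species
zone means.  Bivariate classes cut each axis at its empirical 1/3 and 2/3
quantiles (type-7) of log-transformed values — the log affects only the
labels since class membership is invariant to monotone transforms; ties
resolve to the lower class; class index = 3(row−1)+column.  The PA
quadrant axes are medians across retained protected areas (the units of
the assessment), not across cells; a PA at the median counts as "low".
The variance decomposition reports three scalars, all with the n−1
estimator: spatially averaged per-cell sd across species, spatially
averaged per-cell sd across GCM means, and the spatial sd of per-cell
means.

## Synthetic worlds: what they emulate and what they do not

The generator produces the *statistical structure* the analysis assumes,
not climate realism.  Temperature is base + latitude gradient + lapse
rate (−6.5 °C/km, the standard environmental rate) × elevation + fixed
noise; precipitation has orographic and zonal structure; remaining
variables are fixed linear mixes of temperature, precipitation and
latitude, giving the strongly collinear, temperature-dominant first PCA
axis the method expects.  Pseudo-GCM futures differ only in mean warming,
fractional precipitation change and spatially uncorrelated temperature
noise; no circulation realism is claimed, and the correlation design is a
free choice of this package — it does not emulate any particular GCM
archive.  Species are rectangular climate envelopes (suitable iff every
variable is within center ± halfwidth); real niche models are nonlinear
and asymmetric, but biotic velocity consumes only binary maps, so any
generator with controlled range shifts suffices.  Eight variables rather
than 37 keep tests fast; the pipeline accepts any $p \ge 2$.

Consequently, passing tests demonstrate the *method's* correctness —
oracle-exact matching, closed-form limits, census conservation, imposed
shift recovery — not that real-world velocity magnitudes would be
reproduced; those depend on the external data.

Useful closed forms built into the generator and used as ground truth:
a niche of halfwidth $h$ on a linear gradient $g$ under warming $\Delta$
occupies a band of width $2h/g$ that shifts $\Delta/g$; when
$2h/g \le \Delta/g$ the current and future bands are disjoint and every
range cell's displacement is exactly the imposed shift.  On a linear
score gradient of $g$ units/km with uniform shift $\Delta$, the
offset-averaged forward analog distance is $(\Delta - w/2)/g$ plus half a
cell (a bin of width $w$ spans $w/g$ km of gradient, and the nearest
in-bin cell sits at its near edge); as $w \to 0$ this approaches the
local-velocity closed form $\Delta/(g\,T)$ km/yr, attained exactly once
$w$ falls below the per-cell score step.

## Numerical choices and degenerate inputs

Exact nearest-neighbour ties go to the lowest target cell id.  Chord
distances in the spherical embedding are converted to arcs with
`2R asin(c/2R)`, clipped into the domain.  Bin codes use `floor` on
float scores; the offset-equivalence property is exact for dyadic
inputs and statistical otherwise.  NaN is the only missing-value
representation end to end; readers map the ASCII-grid nodata value to
NaN and never to 0.  Single-member ensembles and single-GCM aggregates
report sd 0 where one value is defined and NaN where none is.  PCA on
fewer cells than variables warns (rank-deficient) but proceeds; an
all-constant matrix errors.

## Known limitations

No land-use barriers, dispersal kernels or corridor delineation — the
velocity is a straight-line requirement, not a path.  No map projections
or CRS handling: grids are regular lon/lat lattices and congruence is an
explicit contract.  Rasters are ESRI ASCII grids (one band per file);
protected areas are cell masks, not polygons.  Zone rasters are inputs
(latitude bands in the generator); no climate-classification algorithm is
included.  The local gradient-based velocity appears only inside tests as
a closed-form oracle, not as a product feature.

## Problem sizes

The default demo (`scripts/acceptance.py`) uses a 100×100 grid, 8
variables, 3 pseudo-GCMs, 50 species and 20 offsets — sizes chosen so
the full pipeline and its property tests run in about a minute while
still exercising every code path at non-trivial scale.
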