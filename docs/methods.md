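# Methods

This note documents the models, the synthetic data they are tested on,
the numerical choices, and the limits of what the test suite shows.

## Raster model and geometry

A `Grid` is a dense matrix with the geotransform of its top-left corner;
row 0 is northernmost, cells are square, and nodata is held as NaN in
memory and written back with the grid's sentinel. Cell centers sit at
`(xmin + (col+0.5)·cell, ymax − (row+0.5)·cell)` and every point-in-cell
test uses half-open intervals `[edge, edge+cell)`, so a point on a shared
edge belongs to exactly one cell and latitude-band counts partition the
map with no double counting. Distances are planar Euclidean in map
units; the package treats the unit opaquely (degrees on geographic
rasters, meters on projected ones) and performs no reprojection or
resampling — input layers must be co-registered. Esri ASCII grid is the
mandatory interchange format; values are written with the shortest
exact decimal representation so read–write round trips are
byte-identical. Nodata propagates through every arithmetic operation,
and any operation mixing grids intersects their nodata masks.

A degenerate rescale (constant grid) maps all cells to 0 with a warning
rather than raising, so batch runs survive degenerate synthetic layers.

## Synthetic landscapes

The generator produces every input the pipeline consumes, with known
ground truth:

- **Environmental stacks.** Each layer is white noise convolved with a
  uniform kernel of radius `smoothing_radius` (spatial autocorrelation),
  linearly mixed across layers by a user matrix (pairwise correlation),
  then standardized. Kernel smoothing was chosen over variogram-based
  simulation: it is dependency-light and sufficient for recovery tests.
- **Truth surfaces.** Per-cell `logistic(intercept + Σ b₁v + b₂v²)` from
  a declared coefficient table, so the fitted model can be compared to
  the surface that generated the data.
- **Occurrences.** Cells drawn without replacement with probability
  proportional to suitability × sampling bias, placed at cell centers —
  at most one record per cell, mirroring standard per-cell thinning.
- **Land cover.** Smoothed noise thresholded at the quantile matching
  the requested forest fraction, giving spatially coherent patches.
- **Future series.** Additive per-layer drift per period (no climate-
  model emulation; the pipeline consumes any co-registered series).
- **Demography.** Per-site adult and juvenile densities with means
  linear in site suitability plus Gaussian noise, floored at zero.

All generators are bit-deterministic given their seed. The default
study conditions are a 60×60 grid with 6 predictors (one planted pair
correlated at 0.9 to exercise screening), 150 occurrences per species,
forest fraction 0.6, a 4-period declining series, and 16 demographic
sites stratified by suitability *value* (not cell rank) so every
suitability category receives sites even though most of a logistic
landscape sits at low suitability. Recovery tests use a stronger
100×100 condition: two active predictors (linear +4, quadratic −3,
intercept −3), three inactive ones, 500 presences, 5,000 background
cells — chosen so that presences are concentrated enough for a correct
model to separate them cleanly, the regime the method is designed for.

What the generator does **not** emulate: real bioclimatic covariance
structure, anisotropy, gradients tied to topography, observation error
in coordinates, or temporal autocorrelation in the future series.
Passing recovery tests therefore show the estimator is correct for data
from its own model family on autocorrelated fields, not that real-world
predictions are accurate.

## Suitability model

The presence-background model is the exponential (Gibbs) family
`q(x) ∝ exp(λ·f(x))` normalized over a background sample. Features are
linear, quadratic, and pairwise-product transforms (no hinge/threshold
features; that keeps the optimizer simple and the objective strictly
smooth + L1). Features are standardized to background mean 0 / SD 1;
constant features get unit scale and stay at λ = 0.

Fitting minimizes `log Z − mean_p(λ·f) + (β/√m)·Σ|λ_j|` with m the
presence count. The √m scaling mirrors the lasso-style default of the
classic MaxEnt tool; without it a unit penalty on standardized features
overwhelms the per-presence likelihood and shrinks every coefficient to
zero. β defaults to 1.0. The optimizer is a cyclic proximal-Newton
coordinate sweep: per coordinate, a soft-thresholded Newton step from
the Gibbs mean and variance of that feature, with per-step backtracking
(halving, up to 20 times) so the objective never increases. Convergence
is declared when a full cycle improves the objective by less than 1e−8
relative, with a 10⁴-cycle cap. The objective is convex, so runs from
different starting points agree at the optimum (checked to 1e−6
relative); the default start is λ = 0, which also guarantees the
reported training gain over the uniform null model is nonnegative.

Prediction: raw output `exp(λ·f − log Z)` sums to one over the fitting
background; logistic output `r·e^H/(1+r·e^H)` uses the entropy H of the
fitted background distribution and is the scale all downstream
thresholds assume. Background defaults to 10,000 cells or all cells if
fewer, drawn without replacement (optionally bias-weighted); presences
are thinned to one per cell before any split so replicate splits cannot
leak duplicated cells. Background may include presence cells, the usual
presence-background convention.

Diagnostics: percent contribution accumulates the objective decrease of
each coordinate update (product features split evenly between their two
variables); permutation importance is the drop in training AUC when one
predictor's values are shuffled jointly across presences and background,
floored at zero and normalized to 100; jackknife refits with each
variable alone and excluded; response curves sweep one predictor over
its background range with the others at background means.

## Evaluation and thresholding

AUC is the rank (Mann–Whitney) statistic with ties counted ½. The
prediction rule is "present when score ≥ threshold" — stated explicitly
because TSS is undefined without it. The MTSS search evaluates every
unique score as a candidate threshold and resolves ties toward the
smallest threshold (larger suitable area — the conservative choice for
risk screening). Replicate evaluation takes the MTSS from the training
presences and reports TSS of the held-out presences at that threshold.

Above MTSS, the continuous map is split into three equal-width classes
(poor / medium / highly suitable); below it is unsuitable. Equal-width
tertiles of [MTSS, 1] are a declared convention — no GIS "natural
breaks" are emulated — and the boundaries are exposed through the
categorical map itself.

## Overlap and the risk score

Overlap of the two species' presence–absence maps is the cellwise AND;
proportional overlap divides shared suitable pixels by the suitable
pixel count of the smaller map. The invasion-risk score on crop-suitable
cells adds three components and rescales the sum to [0, 1]: the snail's
categorical suitability rescaled to [0, 1] (the category coding would
otherwise dominate the two bounded terms — the components are
individually normalized before the unweighted sum), the binary
forest/transformed land-cover map, and proximity to snail records
(1 − rescaled distance, closest = 1). The high/low-risk split for
latitude-band counts defaults to 0.5 and is configurable.

## Dispersal automaton

Suitability enters on the integer 0–1000 scale (1000 × logistic,
rounded), with `rcThreshold = 600` as the default colonizability cut.
Per step: (a) occupied cells below threshold are decolonized (they may
be recolonized later — no permanent-extinction flag, the simplest
consistent rule); (b) each open suitable cell is colonized with
probability `1 − Π(1 − propagule_prod·kernel(d))` over mature sources in
range, computed by log-space convolution; (c) each mature cell attempts
a long-distance event with probability `lddFreq` toward one uniformly
chosen eligible cell at rounded distance in `[lddMinDist, lddMaxDist]`;
(d) ages increment, new colonists start at age 1, maturity is
`age ≥ iniMatAge`. Distance between cells is Euclidean between centers
in cell units, kernels indexed by rounded distance — so the default
single-entry kernel (probability 1 at distance 1) reaches the full
8-neighborhood. That default reflects a poor disperser: one cell per
step and no long jumps unless LDD is configured.

The published parameterization this automaton defaults to sets
`lddMinDist = 2, lddMaxDist = 0`, which is self-contradictory
(max < min); the package reads it as "LDD disabled", warns, and lets
config override it. Barrier cells (transformed land = 1) can never be
occupied. Three scenarios bracket reality: *unlimited* (every suitable
cell occupied each period, barriers ignored), *none* (initial cells
persist while suitable), and the *constrained* automaton with
`dispSteps` steps per period and `replicates` stochastic runs averaged
into a consensus frequency map. Whether suitability should scale the
colonization probability above the threshold is left as binary
eligibility, the minimal reading.

## Demographic validation

Sites carry quadrat counts of adults and juveniles; each is assigned the
suitability category of its cell, and groups of categories are compared
with a Welch (unequal-variance) two-sample t-test on site-level values —
Welch because sites per category are rarely balanced. Juveniles-per-
adult is undefined at adult-free sites; such records are excluded from
that parameter with a reported count rather than an imputed value.

## Pipeline and reproducibility

Stages communicate only through plain-text artifacts (ASCII grids,
CSV, JSON), so each is independently re-runnable. One global seed feeds
every stage through a stable per-stage sub-seed (CRC32 of the stage
name XOR the seed, mod 2³¹), making each stage's random stream
independent of which other stages run. Configs are validated against
the full default schema (unknown keys rejected), a resolved snapshot is
written next to the outputs, and the manifest lists each artifact's
SHA-256 — two runs with identical config and seed are bit-identical.

Problem sizes in the shipped tests: unit tests mostly use 40×40
landscapes with sub-second fits; recovery and calibration checks use
the 100×100 / 500-presence / 5,000-background condition; the automaton
invariants use twenty 50×50 landscapes with the default parameters; the
reproducibility check runs the full 60×60 default pipeline twice. These
sizes were chosen as the smallest at which the statistical properties
under test are stable.

## Known limitations

- No reprojection, resampling, or great-circle distances; inputs must
  be pre-aligned, and map units are opaque.
- No hinge/threshold/categorical features, and no emulation of the Java
  MaxEnt tool's version-specific regularization tables; fitted values
  will differ from that tool even on identical data.
- The automaton omits propagule-production age curves, seed banks, and
  suitability-scaled colonization probabilities.
- GeoTIFF I/O is not provided; Esri ASCII grids are the interchange
  format.
- The synthetic demography draws site means independently; it does not
  model quadrat-level overdispersion or spatial dependence between
  sites.
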