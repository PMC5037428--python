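# Methods

This note documents the models, defaults and numerical choices behind
`gridspread`, and what the synthetic tests do and do not establish
about real-data analyses.

## Grids and surfaces

All stages share a regular planar lattice (`LatticeGrid`, km units) with
row-major, 0-based indexing, row 0 at the top, and cell centres at
`origin + (index + 0.5) · cell_size`. Coordinates are assumed to come
from an equal-area projection applied upstream; the package performs no
reprojection, geodesic distances or datum handling. Per-cell values
(`Surface`) carry missingness as NaN in memory and a nodata sentinel
(default −9999) on disk; missingness propagates (a cell missing in any
regression input is excluded from fitting — complete-case analysis on a
fixed cell set).

Aggregation from the fine simulation grid (default 10 km) to the
analysis grid (default factor 10, i.e. 100 km blocks) is the zonal
mean over non-missing fine cells; a ragged final block is averaged over
whatever cells it has. Topographic heterogeneity uses the zonal range
(block max − min) of elevation, the conventional relief summary per
analysis cell. Climate anomalies are contemporary minus paleo (several
paleo layers, e.g. two LGM circulation models, are averaged first);
positive anomalies mean the present is warmer/wetter. The analysis cell
set keeps cells with land fraction strictly above 0.5.

## Spread model and accessibility

The dispersal stage is a stochastic cellular model on the suitability
map: a cell is occupied at t+1 iff its 3×3 neighbourhood (8 neighbours
plus itself) held an occupied cell at t *and* a Bernoulli(s) trial
succeeds. Consequences worth stating:

* an occupied cell with s < 1 can go locally extinct — persistence and
  colonisation share the same trial;
* origin cells are exempt (they model an external source pool and stay
  occupied throughout);
* grid edges truncate neighbourhoods; there is no wraparound;
* cells with s = 0 are never occupied, so barriers are absolute.

Accessibility summarises the first-occurrence time per replicate as
`(T + 1 − t_first)/(T + 1)` (0 if never reached) and averages over
replicates (default 10, configurable). This normalised-earliness
summary was chosen because it is monotone in how early a cell is
reached, bounded in [0, 1], exactly 1 on origins and exactly 0 on the
never-colonised set — the properties the downstream regression actually
uses. Other summaries of the same simulation (occupancy probability,
raw occurrence counts) would serve the same role; they are monotone
transformations of similar information and the rank-based screen is
insensitive to that choice.

Scenario suitabilities (region precedence desert > forest > corridor >
default): DISP1 all land 1; DISP2 desert 0; DISP3 desert 0, forest 0.2;
DISP4 desert 0, forest 0.2, corridor 1, other land 0.5.

**Iteration counts.** The governing rule is *the minimum number of
iterations that allows spread across the whole domain*. At continental
scale (a ~10 km grid of Africa) that rule yields 700 iterations for the
s = 1 scenarios and 1000 for the half-suitability background of DISP4;
those values are kept as `DEFAULT_ITERATIONS` and used verbatim via
`iterations='reference'`. On any other domain the same rule is applied
directly: `minimum_iterations` computes the largest Dijkstra distance
from the origins with per-cell entry cost 1/s (the expected waiting
time for a Bernoulli(s) colonisation), and `scenario_battery` uses it
by default. Applying the constants instead of the rule to a small
domain would leave every reachable cell colonised long before T and
collapse the scenarios into near-identical rank patterns.

Replicate streams derive from `numpy.random.SeedSequence(seed).spawn`,
so runs are deterministic given the seed and replicates are
independent. A replicate stops early once every cell 8-connected to the
origins through positive suitability has been reached (no further first
occurrences are possible).

## Envelope SDM, evaluation, stacking

The envelope (surface range envelope) model bounds each predictor by
the empirical q and 1−q quantiles of the training presences
(linear-interpolation quantile rule, q default 0.025 — the conventional
default of envelope implementations; the source analyses do not print
theirs). Prediction is the inclusive conjunction across predictors.
Species with fewer than 5 records are not modelled (`TooFewRecordsError`);
their observed cells enter the richness stack directly.

Evaluation reports sensitivity, specificity, TSS = sensitivity +
specificity − 1, and AUC (rank statistic over a continuous score when
available, else over the binary map). Pseudo-absences for synthetic
evaluations are drawn uniformly from land cells without presences, 1:1
with presences, seeded. A TSS-maximising threshold utility
(`best_tss_threshold`, ties toward the lowest threshold) supports
binarising continuous SDM output, and consensus maps are the cellwise
intersection of two binary maps.

Richness stacking uses the presence-anywhere rule: a species
contributes to a coarse cell iff at least one fine cell of its range
(or observed set) falls inside it. The interface accepts externally
produced binary maps, so machine-learning SDM output can be slotted in
place of the envelope model.

## Regression conventions

The response (species richness per cell) stays on its raw scale.
Predictors are transformed where the field's convention says so
(log(x+1) for dry-season precipitation; log(x+1) of absolute values for
the LGM precipitation anomaly — the sign is not restored, so that term
measures anomaly magnitude), then centred, and each design column —
including polynomial columns — is z-scored so coefficients are
standardized effect sizes. Polynomial columns are built by squaring the
transformed, centred base column, then standardizing; backward-AIC
selection drops a square before its base and never removes a base while
its square remains. AIC uses the Gaussian form without the additive
constant, `n·ln(RSS/n) + 2(k+1)`; only differences matter for the
selection path. Collinearity screening first resolves pairs with
|Spearman r| > 0.70 (dropping the member with the larger mean absolute
correlation to the other terms; ties resolved by column order), then
drops terms with VIF above 5, worst first, recording every drop.
Variance partitioning fits OLS on every union of predictor groups and
reports all subset R² values; the unique fraction of a group is
R²(all) − R²(all minus group).

## Spatial statistics

Moran's I uses `(n/S0)·z'Wz/z'z`; inference is a two-sided permutation
test (default 999 permutations, +1-corrected p, null expectation
−1/(n−1), mandatory seed). The analysis convention is 8-nearest-
neighbour weights for Moran's I and a distance-band for the SAR model;
both constructors are provided. The default band distance is the median
over cells of the distance to the 8th nearest neighbour (the threshold
at which the median cell gains all 8 neighbours — on a 110 km lattice
this is ≈156 km); the alternative reading, the median of all
cell-to-neighbour distances, is exposed via `method='all'`.

The SAR error model `y = Xβ + u, u = λWu + ε` is fitted by maximum
likelihood: λ is profiled with bounded scalar optimisation of
`ll(λ) = −n/2(log 2πσ²(λ) + 1) + Σ log|1 − λω_i|` inside the feasible
interval set by the extreme eigenvalues ω of W (computed densely —
exactness over scalability; intended for n up to a few thousand), with
β and σ² from GLS at each λ. Coefficient p-values use the asymptotic
normal approximation from the GLS information matrix; the λ standard
error comes from the profile curvature. Residual Moran's I is computed
on the whitened innovations e = (I − λW)u, the quantity that should be
white under a correctly specified model (the raw residuals u remain
autocorrelated by construction). Pseudo-R² values are squared Pearson
correlations with the observed response: `r2_pred` from the trend Xβ̂
and `r2_full` from the full signal Xβ̂ + λ̂W(y − Xβ̂) (the one-step
signal predictor, not one-step-ahead cross-validation).

Principal-coordinate spatial filters double-centre the squared
pairwise-distance matrix (−½ J D² J) and return the leading
eigenvectors with positive eigenvalues, centred and unit-normalised.
Note that plain PCoA of 2-D planar coordinates has exactly two positive
eigenvalues, so at most two such filters exist; requesting more raises.

## Synthetic landscape and study conditions

The generator emulates the qualitative geography the method was built
for: a rectangular land mass (3-cell sea margin) entered from two
origin cells on its eastern edge; a vertical zero-suitability desert
band at 0.30–0.45 of the width crossing every land row except where two
transverse corridor bands (near 0.08 and 0.50 of the height) cut
through it; a forest block in the south-central east. The desert blocks
straight-line spread from the origins; the corridors are the only
passages west. Climate surfaces are smooth analytic gradients (a
temperature bump and precipitation deficit centred on the desert,
north–south gradients, a seasonality wave) plus seeded Gaussian noise;
topography is six random Gaussian mountain patches (amplitudes
800–2500 m, ~40 km footprint) over a rough 300 m baseline. The default
domain is 120×100 fine cells with aggregation factor 10 — large enough
for distinct barrier/corridor topology, small enough for seconds-scale
simulation (the resulting analysis table has ~116 land cells).

Richness responses are linear in z-scored predictors with Gaussian
errors, either i.i.d. or SAR-correlated. Default standardized effect
sizes mirror the magnitudes reported for the continental analysis this
package reimplements (accessibility 0.54, maximum temperature −0.15,
precipitation seasonality −0.32, topographic range 0.55). Noise scales
were fixed from the intended variance split, not from test outcomes:
σ = 0.9 (i.i.d.) and σ = 0.6 with λ = 0.8 (SAR; the SAR filter
amplifies innovation variance about twofold on the study weights) both
put the linear trend near half of the response variance. Gaussian noise
on the richness scale matches the untransformed-response OLS
convention; a Poisson response is deliberately not the default path.

**What the synthetic tests show — and what they don't.** Passing the
suite establishes that the simulator matches exact enumeration, that
the estimators recover known data-generating parameters at the stated
replication levels, and that the pipeline identifies the true scenario
when one exists. It does not establish anything about taxonomy,
occurrence-record quality, SDM truthfulness on real climates, or the
realism of any particular suitability scenario; the synthetic climate
has no temporal dynamics, species are independent envelopes (no
interactions), and suitability is static through time.

## Numerical details and edge cases

* Quantiles: linear interpolation (numpy's default), stated because
  envelope bounds at small n depend on the rule.
* Constant vectors: Spearman and Moran's I raise instead of returning
  NaN.
* Singular designs: the OLS fit names the offending columns; perfectly
  collinear VIF terms report infinity.
* Backward selection stops when no single drop lowers AIC by more than
  1e-10 (tie = keep).
* λ estimates within 1e-4 of the feasible boundary trigger a warning.
* Weights validation: no self-neighbours, positive weights,
  row-standardized rows sum to 1 within 1e-12; isolated cells in a
  distance band are flagged with a warning and returned.
* Test problem sizes (n = 400 lattices, 20–100 seed replications,
  20,000 Monte-Carlo replicates on the enumeration strip) were chosen
  so the whole suite runs in well under a minute per stage on one CPU.

## Known limitations

* Dense eigendecomposition limits SAR fitting to desk-scale n (no
  sparse log-determinant approximations); SAR lag/mixed variants are
  out of scope.
* Rasters are exchanged as ESRI ASCII text or plain single-band TIFF;
  georeferencing tags and multi-band imagery are not handled.
* The spread model has no dispersal kernel beyond the 3×3
  neighbourhood, no demographic structure, and no time-varying
  suitability.
* Ties between models with equal AIC resolve toward the larger model;
  a different tie-break could select differently on degenerate data.
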