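# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic cohort does and does not
emulate, and the numerical choices a maintainer should know about.

## Coordinates and rasters

All spatial work happens in a local azimuthal equidistant projection
(km) about the gannet colony.  Distances from the colony are exact by
construction and pairwise distances within a 500-km disc are correct to
well under 1 %; plain equirectangular with a fixed `cos(ref_lat)` was
rejected because its east–west scale error reaches several percent a few
degrees from the reference latitude.  The inverse is closed-form, and a
round-trip moves a point by less than a meter.

Every environmental layer lives on one master grid (default 4-km cells,
matching the resolution of standard monthly SST products); fisheries
log-books are first rasterized on their native grids (10×10 nautical
miles for purse-seiners, 20×20 for trawlers; cell value = summed annual
tonnes, covariate = log(tonnes+1)) and then resampled nearest-neighbour
to the master grid.  Extraction is nearest-cell; points on land or
off-grid yield an explicit missing flag, never a silent zero.  Rasters
are stored as ESRI ASCII text grids.

## Trajectory descriptors

Tracks are linearly reinterpolated to 1-min fixes in projected space;
gaps longer than 10 min split a track into bursts that are never
interpolated across.  Two descriptors feed behavioral classification:

- **Smoothed speed**: the mean speed of the two steps entering and the
  two steps leaving the focal fix (the four steps connecting fixes
  i−2…i+2).  The window is symmetric about the fix, so the descriptor is
  invariant under time reversal — the asymmetric five-step alternative
  (three leaving, two entering) was rejected for breaking that symmetry.
- **Turning angle at constant step length**: with r = the track's median
  step length, the backward anchor is the first fix (scanning backward)
  at distance ≥ r from the focal; the forward anchor is the last
  consecutive forward fix still inside the circle (the fix just before
  the forward crossing; when the first forward fix is already outside,
  that crossing fix is used — otherwise straight equal-step travel would
  have no anchor).  The reported angle is π minus the vertex angle, so
  straight travel gives 0 and an exact reversal π.  A
  `convention="first_outside"` switch uses the first fix beyond the
  circle on the forward side instead.

Day/night is the sign of solar elevation from the NOAA solar-position
formulas (no refraction; the boundary is configurable but defaults to
the horizon rather than civil twilight, the parsimonious choice).

## Segmentation-clustering

The series (smoothed speed, turning angle), standardized per track, is
modeled as contiguous segments, each assigned to one of three classes
with class-specific diagonal-Gaussian emission.  For fixed class
parameters the optimal K-segmentation is found exactly by dynamic
programming on per-class cumulative log-likelihoods; class parameters
are then re-estimated from the assigned points (classification-EM) and
the loop repeats until labels stabilize (≤ 8 sweeps).  Class parameters
are initialized from a seeded Gaussian mixture fit (10 restarts by
default).  K is chosen by a BIC-style criterion, −2ℓ + λ(K−1)·log n with
λ = 3 — conservative enough that a single Gaussian regime yields one
segment while well-separated regimes are split at the true breakpoint.
Minimum segment length is 5 fixes (5 min at the native resolution).

For series longer than 600 fixes the DP runs on blocks of `Lmin` fixes
and every boundary is then refined exactly within ± one block — on
synthetic trips this approximation costs < 1 % per-fix accuracy and cuts
the cost of a 1,500-fix trip to well under a second.  The exact program
is used below that length and in all oracle tests (where DP equals
exhaustive enumeration).

States are relabeled deterministically by ascending mean raw speed:
rest < forage < commute.  A trip rests *at the colony* iff every
night-period fix lies within 1 km of the colony (configurable); any
offshore night fix makes it rest-at-sea; trips without night fixes get
no tactic and are excluded from diel analyses.  A bird's tactic is the
majority over its trips.

## Weighted use–availability RSF

Used fixes (case 1, weight 1) are contrasted against available points
(case 0, weight W = 1000) in a binomial GLMM whose linear predictor has
a random intercept per individual with variance fixed at σ₀² = 10⁶
(never estimated — asserted after every fit) and a diagonal random slope
per covariate with estimated variances.  This is the
infinitely-weighted-likelihood construction under which logistic
regression approximates the inhomogeneous-Poisson use-availability
model; exp(β̂ᵀx) is then a relative occurrence probability.  Covariates
are centered and scaled over the table and the transform is stored with
the model, so raster predictions and raw-scale coefficients round-trip
exactly.

Estimation: for given variance components the joint penalized
likelihood is maximized over (fixed effects, random effects) by damped
Newton iterations; the marginal likelihood of the free variances is the
Laplace approximation at that mode, optimized on the log scale by
Nelder–Mead.  Wald covariance comes from the fixed-effect block of the
inverse joint precision.  Coefficients exceeding 50 on the standardized
scale flag (quasi-)separation and mark the fit non-converged.  With a
single individual, or with all variances driven to zero, the fit reduces
to plain weighted logistic regression (verified against statsmodels GLM
to 10⁻⁴).

Increasing W tenfold beyond 1000 moves coefficients by < 0.02, so the
weight is effectively "infinite" at its default.  Collinearity screening
(pairwise |r| plus VIF = 1/(1−R²) from regressing each covariate on the
rest) precedes every fit, with stage-specific |r| bounds (0.61 predator,
0.62 forager, 0.4 diel) and VIF < 2 throughout.

**Availability.** Predator (seal) models draw 5 uniform random points
per used fix inside the sea-clipped 95 % isopleth of a Gaussian-kernel
utilization distribution (Silverman bandwidth; smallest-area pixel set
holding 95 % of kernel mass).  Forager (gannet) models instead simulate
10 habitat-blind tracks per observed trip from a VAR(1) fitted to the
trip's step increments — same duration, start point and speed structure,
innovations from the fitted Gaussian, shore-landing innovations redrawn
up to 100 times then reflected — and run the same segmentation on them;
their daytime foraging fixes are the available sample.  A caveat
documented by measurement: because ~5 % of used fixes fall outside the
95 % isopleth, UD-based availability slightly attenuates coefficients
(a bathymetry coefficient of 0.4 recovered at ≈ 0.25).  The estimator
itself is unbiased: with availability drawn over the generative range
the same design recovers 0.40 ± 0.01.  Parameter-recovery tests
therefore sample availability from the generator's known at-sea range
(`seal_recovery_dataset`), while the pipeline keeps the UD design.

## Fearscape

Each colony's predicted scores are binned into ten equal-count classes
over that colony's own UD-masked extent (quantile bins are robust to the
skew of exponential scores; equal-interval bins are available via
config), then combined across colonies by pixel-wise maximum — a
conservative "worst colony wins" risk surface — separately for day and
night models.  Day points read the day raster and night points the
night raster; the percent nocturnal risk reduction is
100·(mean day index − mean night index)/mean day index.

## Validation

Folds split individuals, never points: leave-one-individual-out for the
predator models, five 80/20 folds by individual for the forager model.
Per fold the model is refit on training individuals, all available rows
are scored as the landscape reference and decile-binned, the test
individuals' used fixes are placed in those bins, and Spearman's r is
computed between bin rank (1…10) and area-adjusted frequency
f_b = (point share)/(pixel share), dropping empty bins with a flag;
r̄ₛ averages the folds.  Because binning depends only on score order,
r̄ₛ is invariant to any strictly monotone transform of the scores.

## Diel model

For rest-at-sea birds, daytime foraging fixes (y = 1) and nighttime
resting fixes (y = 0) enter a mixed logistic regression with random
intercepts for bird and year (both variances estimated — no
availability weighting at this stage) on period-matched seal index,
SST, and the two catch covariates.  Each predictor may be linear or a
natural cubic spline with df = 4 (truncated-power natural basis;
boundary knots at the data range, interior knots at the quartiles;
linear beyond the boundary, second derivative zero there — verified
against scipy's natural CubicSpline space to 10⁻⁸).  All 2⁴ form
combinations are ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1).

The two grouping variances are estimated once, on the all-linear
candidate, and held at those values while the 16 forms are ranked: they
describe grouping structure that is essentially independent of the
fixed-effect forms, and sharing them removes optimizer jitter from AICc
differences (the estimated variances still count in every candidate's
k).  Response curves hold the other covariates at their standardized
means, use delta-method bands on the linear predictor, and report x in
original units, flagging extrapolation beyond the training range.

## Summaries

Group means (distance to shore, seal index, SST, …) come from an
intercept-only linear mixed model with random intercepts for individual
and year (statsmodels MixedLM; a single year drops the year term with a
note; degenerate samples fall back to between-individual means);
min/max are raw ranges.  The nocturnal offshore shift is, per bird,
mean distance-to-shore of night resting minus of day foraging (positive
= farther offshore at night), summarized over birds by the same mixed
estimator.

## Synthetic study system

The generator emulates the study's structure at two scales (full: 3
predator colonies / 25 seals / 197 birds; test: 3 colonies / 15 seals /
16 birds on a smaller grid — all tests and the acceptance script run at
test scale so the whole suite stays in minutes on one CPU).  Land is the
x < 0 half-plane; bathymetry deepens offshore at 8 m/km with smooth
multiplicative roughness; slope is its finite-difference gradient;
monthly SST warms offshore at 0.3 °C per 13 km (so the configured mean
night shift produces a ≈ +0.3 °C difference) plus a small monthly term.
Purse-seine catches concentrate inshore (exponential, 12-km scale),
trawl catches over the shelf break (Gaussian at 65 km) — giving the diel
model's recoverable sign structure (foraging with purse-seiners,
resting over trawl grounds).

Seal fixes are sampled independently per colony from an intensity
∝ exp(βᵀx) over the colony's at-sea range (default β on the
range-standardized scale: dist_colony −0.8, bathymetry +0.4, slope 0;
raw-scale equivalents recorded in the manifest), with irregular 2–6 h
Argos-like timestamps — independence gives clean coefficient-recovery
tests, at the cost of not emulating serial autocorrelation.  Gannet
trips are built state-by-state at 1-min resolution (commute ≈ 38 ± 6
km/h with low heading noise, forage ≈ 9 ± 2.5 with high turning, rest
≈ 1 ± 0.4 drifting), start and end at the colony, choose forage centers
≈ 40 ± 10 km offshore nudged toward purse-seine intensity, and draw the
nocturnal tactic per bird (72 % rest at sea).  Rest-at-sea birds move,
at dusk, to a resting position whose distance to shore is the day's
mean foraging distance plus 13 ± 6 km: the mean matches the reported
diel shift while the wide per-night noise reproduces the broadly
overlapping day/night distributions seen in the real system — an
earlier near-deterministic offset (sd 2 km) made day and night
separable in covariate space and sent the diel model into
quasi-separation, which real data do not do.

What passing tests show — and do not.  Recovery tests demonstrate that
the estimators are correct under their own assumptions (independent
fixes, known availability, Gaussian behavioral regimes).  They do not
address Argos positional error, serial autocorrelation of fixes,
imperfect detection, or behavioral states that grade into each other;
on real tracks those will widen intervals and blur segment boundaries
beyond what the synthetic results suggest.

## Numerical conventions and limitations

- All randomness flows through `numpy` Generators seeded from a single
  run seed via `SeedSequence`; model reports record seed and config.
- Newton tolerance 10⁻⁹ on the penalized log-likelihood with step
  halving; variance search bounded by `maxfev` (fits warm-start from
  previous estimates inside cross-validation loops).
- Quantile bin edges are right-closed at interior edges so ties never
  send a higher score to a lower bin; constant rasters collapse to bin
  1 with a degeneracy flag.
- The end-to-end tactic and shift checks compare estimates with the
  *realized* generative values of the simulated cohort (computed from
  the generator's own labels), not the configured population values —
  a 16-bird cohort's realized mean shift can sit 2–3 km from the
  configured 13 km.
- Known limitations: no spatial autocorrelation structure in the RSFs,
  no step-selection (SSF) alternative, no Argos error model, diagonal
  (uncorrelated) random slopes, and Wald rather than profile intervals.
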