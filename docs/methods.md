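# Methods

`phenosurf` tests whether migrating geese time their movements to
environmental "onset waves" — the northward-advancing dates on which
temperature, vegetation and snow metrics cross biologically meaningful
levels — and models the daily probability of spring arrival and autumn
departure as a function of days since those onsets.  This note documents
the models, the defaults, the synthetic world used for validation, and the
numerical choices.

## Onset metrics (Dpre)

Nine node-level metrics, all expressed as 1-based day of year (DOY):

| metric | series | spring rule | autumn rule |
|---|---|---|---|
| LSTa | 8-day mean land-surface temperature | first day strictly > 0 °C | first day strictly < 0 °C |
| LSTn | 8-day nighttime LST | same | same |
| Ta | daily air temperature | same | same |
| Tcum | trailing 14-day sum of Ta | same | same |
| SOS / EOS | fitted NDVI season | day the curve reaches 50 % of annual amplitude, rising limb | falling limb |
| Greenup / Dormancy | fitted NDVI season | first local maximum of d(NDVI)/dt | last local minimum |
| Snow | 8-day snow-cover fraction | interpolated drop below 50 % cover after the annual maximum | first interpolated rise to ≥ 50 % |

Conventions and QC:

- "Exceeds" and "falls below" are strict inequalities; the first crossing
  is literal, with no persistence requirement.
- The trailing cumulative window includes the focal day (window
  `[d−13, d]`), so the statistic is known on day *d*; it is undefined for
  the first 13 days of the year.
- Autumn crossings are searched from DOY 183 so spring re-crossings cannot
  be picked up.
- Composite series (8-day LST and snow, 16-day NDVI) are linearly
  interpolated to daily resolution before thresholding; snow crossing days
  are located by linear interpolation between days and can be fractional.
- Spring snow melt is searched within the first half-year only.  The
  literal "first drop below 50 % after the annual maximum" rule breaks on
  noisy data because a late-December cover maximum can exceed the
  late-winter one and silently delete the melt date.  The
  `from_year_start` reading (first date cover ≤ 50 % from 1 January)
  remains available as `snow_spring_rule`; the two coincide for monotone
  melt curves.
- Spring Ta/Tcum onsets before DOY 30 are set missing (`qc_excluded`), the
  standard guard against sites that are effectively never frozen.
- Foraging buffers are the grid pixels whose centers lie within 5 km of
  the node, always including the pixel containing the node itself (so
  buffers stay usable on grids coarser than the buffer radius), minus
  water/forest/urban land-cover classes, minus LST pixels whose retrieval
  error is ≥ 2 °C at that time step.

## NDVI season fitting

Per pixel-year, a two-stage fit:

1. **Weighted Whittaker smoothing** of the 16-day composites: minimize
   `Σ wᵢ(yᵢ − zᵢ)² + λ Σ (Δ²z)²`.  Default `λ = 2` **on the 16-day grid**.
   A much larger penalty (λ ≈ 100 on 23 annual points) looks innocuous but
   flattens the season so severely that the 50 %-amplitude day lands ~60
   days early even on noiseless data; λ = 2 removes composite noise while
   keeping the rise/fall shape (measured SOS bias < 1.5 d).  λ is exposed
   in the config and must be rescaled if the composite step changes
   (`λ ∝ step⁴` for order 2).
2. **Asymmetric Gaussian season model** fitted to the smoothed curve by
   bounded nonlinear least squares:
   `f(t) = v0 + A·exp(−|(t−t_p)/σ_L|^{k_L})` for `t < t_p`, mirrored with
   `(σ_R, k_R)` on the right.  Multi-start initialization from the curve's
   peak and half-max crossings with starting exponents {2, 3, 1.5, 4};
   bounds σ ∈ [2, 250] d, k ∈ [1.2, 8].

Dates are closed-form in the fitted parameters:
`SOS/EOS = t_p ∓ σ(ln 2)^{1/k}` and
`Greenup/Dormancy = t_p ∓ σ((k−1)/k)^{1/k}` (the latter analytic for
k > 1, numeric on a 0.1-day grid otherwise).  A consequence worth knowing:
the inflection *precedes* the half-amplitude day only when
`(k−1)/k > ln 2`, i.e. k > 1/(1−ln 2) ≈ 3.26 (flat-topped seasons); for
k < 3.26 Greenup falls *after* SOS.  Both orderings are legitimate and the
package does not force one.

Pixel-year QC: spring dates before DOY 30 or after DOY 240, spring dates
later than their autumn counterparts, and pixels with annual mean
NDVI < 0.1 are blanked.  Buffer-level vegetation dates are the median over
valid pixels (mean available via config).

A precision caveat measured during validation: with noise of 5 % of the
seasonal amplitude, the ML estimator of the season peak `t_p` has an
asymptotic standard deviation of ≈ 2.2 days even on a daily grid (inverse
Fisher information; the peak trades off against width and kurtosis), and
correspondingly more on composite grids.  Threshold dates (SOS/EOS) are
much better determined than the peak itself.

## Track segmentation

A greedy spatial-run clusterer: consecutive fixes within 30 km
(`residency_radius_km`) of the running centroid form a stationary site.
Sites lasting strictly more than 2 days are stopover-eligible ("over two
days" is read strictly; a 2.0-day pause is a brief stop).  Season
assembly:

- wintering origin = longest residency before the summer window; spring
  departure = first fix after it; spring arrival = first fix of the
  summering residency (first residency > 20 d with midpoint DOY 105–280).
- a second long summer residency > 100 km from the breeding site and
  occupied before DOY 183 is a moult site and becomes the autumn origin
  (breeder vs non-breeder is inferred purely geometrically).
- autumn arrival = first fix of a terminal residency (> 10 d) that reaches
  the end of the track; if none exists the event is `complete = False`
  and its arrival date is absent.

Node filters: nodes south of the January 0 °C isotherm (default constant
latitude 33° N approximating the Qinling–Huai line; no published polyline
coordinates exist, so a polyline override is left to the user) are
removed; records whose *mean* daily fix count falls outside [2, 288] are
removed whole (the per-day-failure policy is configurable in spirit via
`fix_rate_policy`).  Spring nodes carry arrival DOY as Dobs, autumn nodes
departure DOY.  MCP home ranges are convex hulls with spherical
(fan-triangulated) areas.

## Surfer classification

Per species × group × season × metric cell (plus pooled `ALL` rows), a
maximum-likelihood linear mixed model `Dobs ~ Dpre` with random intercept
and slope for individuals nested within migration year; when every
individual has single-year data the grouping collapses to individual.  On
a singular fit the structure is simplified stepwise — drop the
slope–intercept correlation, drop the random slope, drop the nesting, and
as a terminal fallback plain least squares — recording each step.  Wald
normal-approximation CIs and p-values are used throughout (the choice of
denominator-degree-of-freedom method affects borderline calls; Wald is the
simplest defensible default and is documented rather than hidden).

Classes, evaluated in order (surfer takes precedence):

- **surfer** — slope p < 0.05, slope > 0, 0 < CI_low ≤ 1 ≤ CI_high, and
  intercept p > 0.05;
- **weak_surfer** — significant positive slope with CI inside (0, 1), or
  entirely above 1, or with a significant intercept;
- **non_surfer** — everything else; **not_estimable** — fewer than 5
  usable nodes or missing inference.

## Arrival/departure probability

Daily presence records per node visit.  Autumn: one record per presence
day (breeding-site visits enter the risk set at DOY 183), y = 1 on the
last presence day, only for visits with an observed departure.  Spring
arrival is coded as the mirror image over an approach window: y = 0 on the
10 days before arrival at the node, y = 1 on the arrival day.  Records are
daily, not per-fix, so high-rate tags are not overweighted.  Covariates
are days since each metric's onset at that node (`Dobs_day − Dpre`),
z-standardized within the fitted dataset.

Covariates are VIF-screened (iteratively drop the largest VIF until all
< 10; exact duplicates drop the later column), then all subsets of the
retained metrics — each entering as covariate + covariate × species — are
fitted as logistic mixed models with a random intercept per
individual-within-year and ranked by AIC (the exhaustive-AIC rule is the
package's own selection criterion).  The GLMM marginal likelihood is
integrated by adaptive Gauss–Hermite quadrature (15 nodes centred and
scaled at each cluster's Laplace mode) and maximized directly; on shared
test data the coefficients, random-intercept SD and log-likelihood agree
with lme4's `glmer` (nAGQ = 15) to ~10⁻⁵.  Coefficient CIs come from
2,000 draws of the multivariate-normal posterior approximation
(percentile 2.5/97.5); a covariate is significant when that CI excludes
zero.  Effect curves hold the other covariates at their means, set random
effects to zero, and carry a posterior-simulation band.  Marginal and
conditional R² use the latent-scale decomposition with logistic
distribution variance π²/3.

## Migration-date comparison

One Gaussian mixed model per endpoint (season × departure/arrival):
`date ~ species × group` with a year random intercept and an individual
variance component.  The interaction is dropped to additive when cells are
unreplicated, the design reduces to a single factor when species and group
are aliased, and when every random-effect group holds a single observation
(e.g. single-year cohorts) the model reduces to OLS — a mixed model fitted
there returns arbitrarily split variances and anti-conservative SEs
(measured type-I ≈ 15 % vs the nominal 5 %).  Marginal means are averaged
over the other factor with balanced weights; pairwise contrasts use the
studentized-range (Tukey) adjustment, applied separately within each
family, which for two levels reduces exactly to the unadjusted z-test.

## The synthetic world

No tracking data are public, so validation runs on a simulated corridor
(30–50° N) whose onsets are known in closed form.

- **Temperature**: `T(lat, d) = M(lat) − A·cos(2π(d − φ₀)/365) + ε`, with
  the latitudinal mean `M` chosen so the spring 0 °C upcrossing is exactly
  `a₀ + b(lat − lat_ref)` (defaults a₀ = 80 at 40° N, b = 2 d/deg,
  A = 20 °C, daily noise 1 °C) and the autumn downcrossing mirrors it
  southward.  Nighttime LST is offset −6 °C, giving distinct LSTa/LSTn
  onsets (≈ 18 d apart at these amplitudes).
- **Vegetation**: double-logistic NDVI seasons, either latitudinally
  graded (2 d/deg) or near-synchronous along the corridor — the regime the
  study system shows; synchronous is the default.  Baseline 0.15,
  amplitude 0.5, 16-day composites, noise sd 0.02.
- **Snow**: cover is a logistic function of local temperature crossing
  50 % near the 0 °C onset; `patchy` mode leaves 28 % of cells below 50 %
  all year (the share of snow-free sites the study region shows), `absent`
  leaves all.
- **Land cover**: static map with 10 % water and 5 % forest, masked in
  buffer extraction.
- **Agents**: winter in the south, climb through `n_stopovers` sites,
  emit fixes at 6/day with 0.3 km jitter, move at 60 km/h flight bouts
  (fine-scale flight is irrelevant downstream; only node timing matters).
  Two timing modes:
  - `cue_lag`: arrive at each node at the node's cue onset plus a lagged
    offset (lag mean 5 d, sd 3 d — placeholders, since no quantitative lag
    distributions are published), scaled by `surf_slope` (1 = perfect
    surfing).  Autumn mirrors spring with negative lags (depart before
    frost).
  - `hazard`: each day at a site, depart with probability
    `logit⁻¹(β₀ + Σ βₘ·(d − onsetₘ))`.  The study-system scenario uses
    spring β = (−4.5, +0.75·LSTa) and autumn
    β = (−5, +0.6·LSTn, −0.15·EOS).  This mode exists because a
    deterministic cue-plus-lag bird generates no *conditional* signal for
    a second covariate: the probability-model sign structure (positive
    temperature effect, negative senescence effect) is only recoverable
    when the generator's departure rule is itself such a hazard.
- **Null scenario**: calendar-driven migrants flying *directly* to the
  breeding grounds.  A calendar migrant with stopovers is not a null: its
  node dates rise with latitude at the mechanical rate
  stay-length/onset-spacing, which a mixed model correctly detects as a
  significant sub-unit slope.  Removing stopovers removes the latitudinal
  gradient in the dates, which is the only way "no cue use" maps to
  "no slope".

What the generator does **not** emulate: multi-year tag records (grids
support multiple years; agents migrate once), wind/precipitation,
energetics and breeding success, cloud-gap structure in composites, and
spatially correlated retrieval error.  Passing tests therefore show the
estimators recover known structure under idealized sampling, not that the
field estimates are unbiased.

## Problem sizes in the validation suite

Simulation scale was chosen to mirror a single-flyway tagging study:
paper-like runs use 4 cohorts × 8 individuals (≈ 180 spring + 180 autumn
node visits), surfer-recovery checks use 100 cells of 10–20 individuals,
mixed-model recovery uses 40 individuals × 3 nodes (LMM) and 400
individuals × 20 days (GLMM), and oracle checks use 1,000 random daily
series.

## Known limitations

- The onset extractor takes first crossings literally; on noisy daily
  series an early warm spell sets the date.  Smoothing is deliberately the
  caller's responsibility.
- One growing season per pixel-year; bimodal seasons surface only as high
  fit RMSE.
- The GLMM supports scalar random intercepts only (random slopes on daily
  0/1 site records rarely converge and are not attempted).
- The isotherm boundary is a constant latitude unless a user supplies
  coordinates.
- Terminal-wintering detection relies on the track extending past the
  final arrival; tags dying on arrival day yield `complete = False`.
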