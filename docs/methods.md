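# Methods

This note records the models, estimators, numerical conventions, and
design choices behind each stage of the pipeline, and what the synthetic
study conditions do and do not establish about real catalogs.

## Catalog model and inclusion rules

A fire record is a point event: planar coordinates in meters (the CRS is
recorded as an opaque tag; no geodesy is performed), a discovery date at
year/month precision (days are ignored if present), a burned area in
acres (> 0), a raw cause code from a closed 18-code vocabulary, and an
optional fuel type. Perimeters are deliberately out of scope: density
mapping and cell-presence assignment both consume occurrence points.

The cause vocabulary and its grouping into six groups — natural
(lightning), three human-caused subgroups (transportation: railroad,
vehicle, aircraft; activity: ten codes from equipment use to escaped
prescribed fire; construction: powerline, structure), miscellaneous, and
unknown — live in a versioned YAML file (`data/cause_codes.yaml`), so the
15→3 anthropogenic grouping is data, not code. Miscellaneous and unknown
stand outside the binary natural/human view and are excluded from
cause-stratified maps.

Archive inclusion rules are modeled by the fuel-dependent minimum-size
filter (10/30/300 acres for timber/brush/grass); records without a fuel
tag are held to the smallest listed floor. The large/small split uses the
≥ convention: a fire exactly at the threshold is large, consistent with
class-based size taxonomies in which a class contains its lower bound.
Unit conversion uses the international acre, 1 acre = 0.0040468564224 km²
exactly.

## Size distributions

All five families are parameterized exactly as their densities are
written in the fitting report (`sizedist` module docstring); in
particular the gamma scale parameter is a *rate* (1/acres) and the
lognormal parameters are the log-mean and log-sd. Estimators:

- **Pareto (Type I):** scale at the sample minimum, shape by the
  closed-form Hill estimator `α̂ = n / Σ ln(xᵢ/β̂)`.
- **Truncated Pareto:** conditional MLE — `H` at the sample maximum, `β`
  at the sample minimum, and the shape from the score equation
  `n/α + n rᵅ ln r / (1 − rᵅ) = Σ ln(xᵢ/β)`, `r = β/H`, solved by
  Brent's method on a bracketing log-grid (tolerance 1e-12). As `H → ∞`
  this reproduces the Hill estimator (tested at `H = 10¹² × max`).
- **Lognormal:** closed form on logs (MLE 1/n variance).
- **Gamma, Weibull:** numerical MLE via scipy with the location pinned
  at zero.

A Lomax (shifted-Pareto) variant is available as `family="lomax"` for
comparison with software that anchors the Pareto at zero; the pipeline
itself uses the Type I form throughout. Degenerate samples (zero spread,
all points at the minimum) raise a dedicated error rather than returning
boundary estimates. The fitting floor of 10 acres applied by the pipeline
mirrors the archive inclusion rule; it is a support convention, not an
inference step.

Goodness of fit uses the plain empirical statistics against the fitted
CDF — `KS = maxᵢ max(|i/n − F(x₍ᵢ₎)|, |(i−1)/n − F(x₍ᵢ₎)|)` and
`CvM = 1/(12n) + Σᵢ ((2i−1)/(2n) − F(x₍ᵢ₎))²` — with no
estimated-parameter (bootstrap) calibration, and `AIC = 2k − 2ℓ` with
k = 2 for every family: the truncation bound is pinned at the sample
maximum and not counted as a free parameter. These statistics order
candidate families; they are not calibrated p-values.

## Mean excess and threshold selection

The mean-excess curve evaluates `e(u) = mean(xᵢ − u | xᵢ > u)` at the
distinct ascending order statistics, truncated where fewer than
`min_exceedances` observations remain. Selection of the tail threshold is
a two-part change-point fit: for each candidate `u*` on a grid, one
straight line is fitted to curve points below `u*` and another to points
at or above it, and the candidate minimizing the total weighted residual
sum of squares wins, with ties (to float precision) broken toward the
smallest candidate.

Two numerical choices matter here. Each curve point is weighted by its
exceedance count — an inverse-variance proxy, since `e(u)` is a mean of
`n_exceed` excesses — so the erratic high-threshold end of the curve
cannot dominate the objective. And curves intended for selection should
be built with `min_exceedances ≈ 50` (`SELECTION_MIN_EXCEEDANCES`):
for tails with infinite variance (Pareto shape ≤ 2) the top of the curve
is noise at any weighting, and feeding it to the selector degrades the
change-point badly. The human analyst reads the same plot by ignoring
its sparse upper end; the weighting and floor encode that practice.
With these settings the canonical spliced scenario (graft at 500 acres)
is recovered to within one 50-acre grid step across seeds.

## Temporal trends

Annual series are zero-filled over the declared catalog period so
fire-free years are genuine zeros, and the frequency/burned-area totals
reconcile exactly with the catalog. The segmented regression fixes the
breakpoint (default 2000) and fits the two sides independently by OLS —
no continuity constraint, because the scientific question is how the two
eras' trends differ, not where a change occurred. Reported per segment:
slope, intercept, R², the two-sided slope t-test p-value, and a 95%
mean-prediction band (the band for the conditional mean, not for new
observations). Peak month is the month maximizing the across-year mean,
ties breaking to the earlier month; the season rule (first/last month
exceeding half the peak mean) is descriptive and configurable.

## Kernel density surfaces

The quartic kernel with hard search radius `R` is normalized so each
point contributes total mass `Pᵢ`; densities are per square meter (any
per-km² display scaling is presentation only). The raster uses a
top-left origin, row-major cells, and cell centers at
`(x₀ + (c+0.5)s, y₀ − (r+0.5)s)`; the extent is the point bounding box
padded by `R` and snapped outward to whole cells, so no kernel is
clipped. No edge correction is applied. The implementation accumulates
each point into its local window and matches a direct per-cell summation
oracle bit-for-bit.

The search radius is a free parameter. When not pinned, a rule-of-thumb
default is used: `R = 0.9 · min(SD, √(1/ln 2) · Dm) · n_eff^(−1/5)`,
with SD the weighted standard distance from the weighted mean center,
Dm the weighted median distance, and `n_eff = (Σw)²/Σw²`. The rule is
deterministic and scale-equivariant but is only a smoothing default —
analyses that matter should set `R` explicitly, and all tests do.

Hot-spot classes are quantile classes over the nonzero cells (zeros and
nodata stay unclassified), chosen because they are invariant under any
monotone rescaling of the density and need no map-specific break tuning.

## Covariate screen, PCA, and logistic model

The correlation screen computes pairwise Pearson r over jointly valid
cells with the N−1 covariance, then greedily removes variables until no
pair exceeds the threshold (default 0.5): at each step the candidate with
the largest mean |r| to the other retained variables is dropped, except
that variables named in `keep_rules` are spared unless every candidate is
protected. The default keep list (road distance over powerline distance,
housing over population density, the climate pair over elevation)
encodes the practitioner's preference for the more actionable member of
each redundant pair; the procedure is deterministic and returns a
removal log.

PCA standardizes by default (correlation-matrix decomposition), because
the covariate roster mixes incommensurate units — km, houses/km²,
degrees, percent cover, °C, hPa — and a covariance PCA would be
dominated by whichever variable happens to have the largest numeric
variance. The sign convention (largest-magnitude loading positive per
component) makes loadings reproducible.

Analysis cells are half-open squares `[x, x+s) × [y, y+s)` (default
s = 3 km) anchored at the window's lower-left corner, so cell membership
is a partition; presence is 1 iff any ignition point falls in the cell,
and covariates are means over the stack cells whose centers fall in it.
The logistic model is fitted by Newton scoring (IRLS) through
statsmodels, with Wald standard errors and two-sided p-values. A
singular Hessian — the footprint of complete or quasi-complete
separation — is reported on the result (`separation=True`, infinite
standard errors) with faintly ridge-penalized point estimates rather
than being swallowed. No spatial-autocorrelation correction is applied;
cells are treated as independent, which overstates precision where
ignitions cluster, and p-values should be read accordingly.

## Synthetic study conditions

The canonical scenario (`data/california_like.yaml`) fixes the study
conditions every end-to-end test runs under: 6336 fires over 2000–2019;
a six-group cause mix with a 24.15% lightning share; July-peaked month
weights; three Gaussian ignition hot spots in a 774 × 855 km window; a
12-variable covariate stack with strong road/powerline, housing/
population, and elevation/climate correlations (the elevation pair at
−0.6086 and −0.8359 forces the tmax–vpdmax entry to at least ≈0.08 for
positive definiteness; it is set to 0.15); and the ignition-presence
logistic coefficient vector, with the intercept set to −9.25 so the mean
presence probability is about 7% — the occupancy level of a 73,455-cell
statewide grid with ~5,200 burned cells.

Sizes follow a spliced law: a lognormal body (log-mean 5.0, log-sd 0.8)
truncated to [10, 500) acres, grafted at 500 acres onto a Pareto tail
with shape 2 and tail mass 0.1968. The body places appreciable mass just
below the splice point, which is what gives the mean-excess curve a
readable bend at the graft — a body with a thin upper end would be
linearly extrapolable from below and the change point would be genuinely
unidentifiable, defeating the scenario's purpose. Tail shape 2 keeps the
mean finite (mean-excess slope 1/(α−1) = 1) while remaining
infinite-variance, so the selector is exercised under realistic noise.
Fuel types are drawn only among those whose archive minimum the fire
meets, so generated catalogs satisfy the inclusion rule by construction.

Covariate rasters are white noise smoothed by a Gaussian filter to the
requested correlation length (periodic boundaries), then empirically
whitened and mixed through the Cholesky factor of the target correlation
matrix — so requested means, standard deviations, and cross-correlations
hold *exactly* in each generated sample, not just in expectation.

Every generator is a pure function of its configuration: sub-generators
are seeded at fixed documented offsets from the scenario seed, so adding
a generator never perturbs existing output, and equal seeds give
byte-identical catalogs, rasters, and pipeline tables.

What the synthetic conditions do **not** emulate: real geography and
boundaries (the window is a rectangle; real study regions have coastline
and masked cells), spatial coupling between ignition locations and the
covariate fields in the generated *catalog* (the presence grid is
coupled through the logistic model, but catalog points follow the
hot-spot mixture independently of the covariates), non-Gaussian covariate
marginals (housing density is skewed and nonnegative in reality),
temporal nonstationarity within the period, and measurement error in
burned areas. Passing tests therefore establish correctness of the
estimators and pipeline plumbing under known truth, not the robustness
of any scientific conclusion to real-data pathologies.

## Problem sizes and runtimes

The default test-and-reproduction conditions use the scenario's native
sizes: 6336-fire catalogs, 5234-observation fitting samples, a
258 × 285-cell 3-km stack (73,530 analysis cells) for the logistic
recovery, 50 replicates at n = 5000 for model-selection
self-consistency, and 500 m density rasters. The full pipeline runs in
about 20 s on one core; the reproduction script in a few seconds.

## Known limitations

- Reproduction of published fitted parameters from *real* archives is
  out of reach by construction (the archives are not redistributable),
  and published Pareto scale estimates can reflect a different estimator
  convention (Type I vs Lomax vs left-truncated likelihood) than the
  printed density implies; recovery is therefore demonstrated on seeded
  draws that use published values as generating truth.
- GOF statistics are uncalibrated for estimated parameters; rankings are
  meaningful, absolute values are not p-values.
- The change-point selector assumes a single body-to-tail transition;
  multi-kink mean-excess curves will return the best single split.
- KDE has no edge correction; density near a masked coastline would be
  biased low in real applications.
- The logistic model ignores spatial autocorrelation and reports
  anti-conservative standard errors on clustered data.
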