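# firestats

Spatio-temporal statistics for wildfire event catalogs: heavy-tailed
burned-area distribution fitting and threshold selection, annual trend and
seasonality analysis, weighted kernel-density hot-spot mapping, and
gridded logistic ignition-risk regression.

The package is aimed at fire ecologists and hazard analysts working with
point-based fire records (ignition location, discovery date, burned area,
cause code) of the kind kept in statewide fire-perimeter archives, where
fuel-dependent minimum-size rules (10 acres for timber, 30 for brush, 300
for grass fires) govern inclusion. Because such archives cannot be
redistributed, the package ships seeded synthetic generators that emulate
their statistical structure — heavy-tailed sizes, a July-peaked season, a
six-group cause mix, clustered ignition locations, and a 12-variable
covariate stack — so every stage of the analysis is testable end to end.

## The statistics at its core

**Fire-size distributions.** Burned areas `x` (acres) are fitted by
maximum likelihood under five heavy-tailed families — gamma, lognormal,
Weibull, Pareto (Type I, `f(x) = αβ^α / x^(α+1)` for `x ≥ β`), and the
truncated Pareto `f(x) = αβ^α x^(−α−1) / (1 − (β/H)^α)` on `[β, H]`.
The Pareto MLE is the closed-form Hill estimator; the truncated Pareto
uses the conditional MLE with `H` pinned at the sample maximum and the
shape solved from the score equation. Fits are ranked by AIC and by the
Kolmogorov–Smirnov and Cramér–von Mises statistics (smaller is better
for all three).

**Threshold selection.** The mean-excess function
`e(u) = E[x − u | x > u]` is linear in `u` for a generalized-Pareto
tail; the large-fire threshold is selected as the change point where the
empirical mean-excess curve becomes linear, by a two-part weighted
least-squares fit over a candidate grid.

**Trends and seasonality.** Annual counts and burned-area totals
(zero-filled) get independent OLS trend lines on the two sides of a fixed
breakpoint year (default 2000), with R², slope p-values, and 95%
mean-prediction bands; monthly profiles yield peak months and a
configurable season rule.

**Hot-spot mapping.** Ignition points are smoothed into density surfaces
with the quartic kernel
`f(x) = (1/R²) Σᵢ (3/π) Pᵢ (1 − (dᵢ/R)²)²` for `dᵢ < R`, where the
population field `Pᵢ` is 1 (occurrence density) or the burned area
(area-weighted density). Surfaces are classified into quantile-based
ordinal hot-spot classes and written as ESRI ASCII grids.

**Ignition-risk regression.** Co-registered covariate rasters pass a
Pearson screen (one variable dropped from each pair with `|r| > 0.5`),
PCA summarizes the survivors, and a binomial logistic model
`ln(P/(1−P)) = w₀ + w₁x₁ + … + wₙxₙ` relates cell-level ignition
presence (3 km cells) to cell-averaged covariates, with Wald inference.

## Worked example

```python
import numpy as np
from firestats import (
    california_like, gen_catalog, compare_families, mean_excess_curve,
    select_threshold, split_by_size, summarize_causes,
)
from firestats.sizedist import SELECTION_MIN_EXCEEDANCES

catalog = gen_catalog(california_like(seed=11))
print(f"{len(catalog)} fires, {catalog.period[0]}-{catalog.period[1]}")

summary = summarize_causes(catalog)
print(f"lightning share: {summary.percentages['natural']:.2f}%")

sizes = catalog.sizes[catalog.sizes >= 10].to_numpy()
ranking = compare_families(sizes)
for fit, gof in sorted(ranking.results, key=lambda fg: fg[1].aic):
    print(f"{fit.family:>16}: shape={fit.shape:8.4f} scale={fit.scale:9.3f} "
          f"AIC={gof.aic:10.1f} KS={gof.ks:.4f}")

curve = mean_excess_curve(sizes, min_exceedances=SELECTION_MIN_EXCEEDANCES)
sel = select_threshold(curve, [float(u) for u in range(100, 2001, 50)])
print(f"large-fire threshold: {sel.threshold:.0f} acres (tail slope {sel.slope:.2f})")

large, small = split_by_size(catalog, sel.threshold)
area = catalog.sizes.sum()
print(f"large fires: {100*len(large)/len(catalog):.2f}% of events, "
      f"{100*sum(r.size_acres for r in large)/area:.2f}% of burned area")
```

prints

```
6336 fires, 2000-2019
lightning share: 23.88%
       lognormal: shape=  5.2555 scale=    0.973 AIC=   84239.9 KS=0.0447
         weibull: shape=  0.9064 scale=  315.355 AIC=   86241.7 KS=0.1056
           gamma: shape=  1.0232 scale=    0.003 AIC=   86401.2 KS=0.1197
truncated_pareto: shape=  0.2236 scale=   10.006 AIC=   91836.1 KS=0.2912
          pareto: shape=  0.3387 scale=   10.006 AIC=   92992.5 KS=0.3558
large-fire threshold: 450 acres (tail slope 1.41)
large fires: 21.05% of events, 62.17% of burned area
```

The catalog here is the packaged "california-like" scenario: 6336 fires
over two decades whose sizes splice a lognormal body onto a Pareto tail
grafted at 500 acres. The mean-excess change point lands at 450 acres —
one 50-acre grid step from the generating graft — and the resulting
large-fire class holds about a fifth of events but well over half the
burned area, the signature concentration of heavy-tailed fire regimes.
(The lognormal tops the AIC ranking because the spliced generating law is
not itself any single candidate family.)

The same stages run from the shell:

```sh
firestats run-all --seed 11 -o run/
```

which writes the catalog, cause summary, per-period size fits,
mean-excess curve and threshold, annual series with segmented-trend
fits, peak months, six kernel-density rasters (unit and area-weighted ×
all/natural/human), the correlation matrix and retained-variable list,
PCA loadings, logistic coefficients, and a run manifest sufficient to
reproduce the run bit-for-bit.

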