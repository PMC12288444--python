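# Methods

## The model

`urbanvar` fits a double-hierarchical Gaussian model (DHGLM) — a Bayesian
location–scale mixed model — to individual trait records (tarsus length in
mm, lay date in day-of-year) of great and blue tits breeding in nest boxes
along replicated urban gradients. Observations are Z-scored before fitting.
For observation *i* in year *t(i)*, study system *s(i)* and cluster
(subpopulation) *c(i)*:

```
y_i        ~ Normal(mu_i, sigma_i)
mu_i       = x_i' beta + a_year[t(i)] + a_sys[s(i)] + a_clust[c(i)]
log sigma_i = z_i' gamma + b_sys[s(i)] + b_clust[c(i)]
```

The mean part (`beta`, `a_*`) models trait means; the dispersion part
(`gamma`, `b_*`) models the log within-cluster residual standard deviation.
System and cluster intercepts appear in both parts as correlated
bivariate-normal pairs; year intercepts are mean-part only. In the
categorical urbanisation mode the cluster SDs and correlations are
habitat-specific (forest vs urban), which yields the three quantities of
interest:

1. **Among-cluster variance in trait means**, urban vs forest
   (`sd_cluster_urban²` vs `sd_cluster_forest²`): do urban subpopulations
   differentiate more in their means?
2. **Urban effect on within-cluster residual variance** (`gamma` on the
   habitat dummy): do urban subpopulations contain more variation? On the
   log-SD link, a coefficient *g* means a `100·(exp(g) − 1)` percent change
   in residual SD.
3. **Among-cluster variance in residual variance**, urban vs forest
   (`sd_disp_cluster_*²`): do urban subpopulations differ more in how
   variable they are?

In the continuous modes (`isa_100`, `isa_1000`, `isa_both`) the habitat
dummy is replaced by standardised impervious-surface proportions and a
single pooled cluster variance is fitted in each part (habitat-specific
variances are not identifiable along a continuous gradient axis).

Priors (responses and continuous covariates are Z-scored, so these are
weakly informative): Normal(0, 1) for fixed effects, half-Normal(0, 1) for
random-effect SDs, LKJ(2) for the mean–dispersion correlations.

### Trait-specific fixed effects

| trait | mean part | dispersion part |
|---|---|---|
| adult tarsus | habitat, latitude, sex | habitat, heterogeneity, latitude, cluster area, cluster years, sex |
| nestling tarsus | habitat, latitude, chick age | habitat, heterogeneity, latitude, cluster area, cluster years |
| lay date | habitat, latitude | habitat, heterogeneity, latitude, cluster area, cluster years, female age |

`heterogeneity` is the Shannon diversity of land-cover classes within 1 km
of the cluster centroid; `cluster area` and `cluster years` control for
sampling-design differences between clusters.

## Clusters, habitat and environmental covariates

Nest boxes are grouped per study system by single-linkage clustering:
clusters are connected components of the graph joining boxes within 300 m
(great-circle distance), kept when they have at least five members. Single
linkage is deliberate — chain-shaped nest-box transects are common and a
complete-linkage rule would shatter them. Cluster habitat is the majority
of the owner-assigned box labels; an exact tie must be resolved in
configuration. Cluster area is the convex hull of member boxes buffered by
150 m (half the linkage distance), computed in a local equirectangular
metric projection, so coincident or collinear boxes still give positive
area. Mean latitude is the arithmetic mean of member latitudes.

Impervious surface area (ISA) is the mean of raster cells whose centres
fall within 100 m and 1000 m of the cluster centroid (cell-centre
inclusion; unbiased for grids much finer than the buffer). Shannon
diversity uses natural logs; the base cannot affect model fits because the
covariate is standardised. Rasters are in-memory grids with a plain-text
serialisation (origin, cell size, values); they stand in for
continental imperviousness/land-cover products, which are external data.

## Preprocessing

Fixed filter order, each step audited (input rows = output rows + removals):

1. **Convert** tarsus measures to Svensson's Alternative method via linear
   per-method calibrations (identity for native measures; unknown methods
   are dropped and counted).
2. **Outlier windows** (closed): adult tarsus 12.70–25.49 mm (both
   species); nestling tarsus 10.2–25.9 mm (great tit), 12.11–21 mm (blue
   tit); lay date 75–152 day-of-year.
3. **First clutches** (lay date): within each species x year x cluster,
   keep clutches laid within 30 days of the group's earliest date, then
   each female's first clutch of the season.
4. **Deduplicate** to one row per analysis unit: adults = mean of repeated
   tarsus measures; nestlings = one uniformly random nestling per brood
   (dedicated seeded stream, independent of MCMC seeds); lay date = each
   female's first appearance (earliest year, then date).
5. **Standardise** response and continuous covariates with the n−1 sample
   SD, globally per species x trait dataset; the (mean, SD) pair is kept
   for back-transformation to mm/days.

Records missing a covariate the trait's model needs (sex for adult tarsus,
chick age for nestlings, female age for lay date) are dropped with a logged
count, never imputed.

## Sampling

The posterior is explored with an in-package No-U-Turn sampler (NUTS):
slice-variable tree doubling, dual-averaging step-size adaptation (target
acceptance 0.9), and a mass matrix estimated during warmup in expanding
windows — diagonal until a window is long enough to support a dense
(full-covariance, Cholesky) estimate, dense afterwards. The dense metric is
load-bearing: cluster-level fixed effects (habitat, heterogeneity, area,
years) are collinear with the 40 cluster random intercepts, and the
resulting ridge correlations are invisible to a diagonal metric.

Random effects are sampled on the centred parameterisation (effect values
directly). At desk scale every grouping level carries tens to hundreds of
observations, which pins the effect values and removes the classic funnel
for most scale parameters; the non-centred form (also implemented, as is a
mixed form with non-centred dispersion halves) re-introduces a strong
nonlinear coupling between pinned effects and their log-SDs and measured
substantially worse on every test problem. The one genuinely
weakly-identified scale — the system-level dispersion SD, with only four
systems in the desk scenario — mixes slowly under every parameterisation;
the remedy is the warmup-heavy, thinned run protocol below rather than a
reparameterisation.

Run protocol: the default settings are 4 chains x 10,000 iterations with
6,000 warmup and thinning 4 (4,000 retained draws). Desk-scale checks use
2 chains with the same per-chain protocol (2,000 retained). Convergence is
gated on split-Rhat ≤ 1.01 (a strict operationalisation of "Rhat = 1") and
bulk ESS > 400 for every non-latent parameter, computed with arviz.
Divergent transitions after warmup are counted and logged as warnings.
A leapfrog step whose dispersion linear predictor exceeds |40| (where
`exp` would overflow) is rejected as divergent.

Determinism: each chain draws from a `numpy` Generator seeded from the run
seed via `SeedSequence.spawn`, so identical seed + config + data reproduce
draws bit-for-bit.

## Inference rules

* **HPDI**: shortest contiguous window over the sorted draws containing
  ⌈prob·n⌉ draws; among equally short windows the lowest is taken. 95% and
  50% intervals are reported.
* **Probability of direction (pd)**: share of draws with the predicted
  sign; draws exactly at zero count half toward each side, so
  pd⁺ + pd⁻ = 1 identically.
* **Evidence labels**: "evidence" when the 95% HPDI excludes zero; else
  "weak" when pd > 0.90; else "none". Random-effect SDs use the
  HPDI-above-0.001 rule instead (an SD bounded away from zero).
* **Variance contrasts** (quantities 1 and 3): per-draw urban and forest
  variances (SD² draw by draw, preserving the nonlinearity), their
  difference and ratio, with pd of the difference under the prediction
  urban > forest.
* **Back-transformation**: percent change in residual SD =
  100·(exp(g) − 1); residual SDs in original units =
  exp(baseline log-SD)·trait SD. Percentages are rounded half-away-from-
  zero to one decimal.
* Point estimates are posterior means; medians are emitted alongside.
  Summaries report random effects on both the SD and the variance scale.

## The synthetic-data generator

The generator runs the same model forward. A scenario places study systems
across European latitudes (43–59°N), each with urban and forest clusters
2 km apart whose boxes sit on a jittered 60 m grid — so the clustering rule
recovers the intended memberships exactly — plus ISA rasters whose cells
average 0.46 imperviousness around urban clusters and 0.01 around forest
ones (the habitat means that motivated the categorical labels), and
land-cover rasters whose class richness varies cluster to cluster so the
heterogeneity covariate has variance. Trait values are drawn from the
DHGLM: latent effects from their (habitat-specific, correlated) normals,
then `y ~ Normal(mu_i, sigma_i)`, emitted in original units via
species-typical affine maps (e.g. great tit adult tarsus 19.8 ± 0.85 mm)
and kept on the generating Z scale in the truth record together with every
latent value.

Generating parameters default to the published posterior estimates for the
chosen species x trait (the printed among-group random-effect entries are
treated as variances — the printed urban/forest ratios match the reported
"four times"/"five times" statements on that scale — so generating SDs are
their square roots). A habitat-neutral variant with switchable effects
(inflated urban among-cluster variance in means; a positive urban
dispersion coefficient; inflated urban among-cluster variance in residual
variance) supports power and false-positive checks for the three
hypotheses.

The default desk scenario is 4 systems x (5 urban + 5 forest clusters) x
10 boxes x 5 years with 10 individuals per cluster-year (≈ 1,600–2,000
records after per-cluster year subsetting): large enough for recovery,
small enough for minutes-scale fitting. Each cluster is active in a random
subset of the last 1–5 years so the cluster-years covariate varies.

What the generator does **not** emulate: real geography and dispersal,
climate-driven phenology, measurement error structure, repeated captures
(it emits one row per analysis unit, so the deduplication rules pass
through unchanged on clean synthetic data), unbalanced sampling as extreme
as the real archives, and genetic structure. Passing tests therefore
demonstrate statistical correctness of the machinery under the stated
generative model, not field validity of the published estimates.

## Test-scale choices

Unit and acceptance tests size their simulations to run on one CPU in
minutes: parameter-recovery uses ten replicates of the desk scenario
(40 clusters, ~950 records each) refit with 2 chains x 1,400 iterations
(800 warmup), asking the 95% HPDIs to cover the generating habitat-mean
effect, urban dispersion coefficient (0.2) and urban among-cluster SD in
at least 8 of 10 — note these are frequentist coverages at a *fixed* truth,
so with weakly identified coefficients and shrinkage priors the expected
rate sits slightly below the nominal 95%. Detection of the dispersion
effect is asserted in aggregate (mean posterior z-score across replicates
above the one-sided 0.90 threshold) because per-replicate detection power
at this scale is only ~80%. The convergence gate runs the 2-chain
warmup-heavy protocol on the default scenario. The log-density oracle, HPDI window oracle, clustering
transitive-closure oracle and Shannon/ISA closed forms are exact and run in
seconds. The forward link check simulates ~10⁴ observations per habitat
with an urban dispersion coefficient of 0.223 and verifies the within-
habitat residual-SD ratio equals exp(0.223) within 3 Monte-Carlo SEs.

## Known limitations

* With only four systems, the system-level dispersion SD is prior-limited;
  its ESS dominates the convergence gate and needs the warmup-heavy
  protocol. Real multi-system archives (13–14 systems) identify it better.
* Cluster area uses the buffered convex hull; archives whose owners define
  plot areas administratively will disagree (hull areas cannot reach
  hundreds of km²).
* Great-circle (spherical) distances differ from ellipsoidal geodesics by
  well under 1% at the 300 m linkage scale.
* The ISA-mode model shares all machinery but its generating defaults are
  not published, so ISA-mode scenarios must supply parameters explicitly.
* No pedigree/animal-model extension, no within-individual dispersion
  modelling, no model comparison.
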