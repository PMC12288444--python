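# urbanvar

Variance partitioning of phenotypic traits along replicated urban gradients
with double-hierarchical Gaussian models (DHGLMs).

Urbanisation changes not just trait *means* in wild populations but the
*variation* they contain — and it can do so at different spatial scales.
`urbanvar` is for ecologists who combine long-term nest-box datasets of
great tits (*Parus major*) and blue tits (*Cyanistes caeruleus*) across
urban gradients and want to ask, for tarsus length or lay date:

1. Do urban subpopulations differentiate more in their **mean** traits than
   forest subpopulations? (among-subpopulation heterogeneity)
2. Do urban subpopulations contain more **within-subpopulation** variation?
   (within-subpopulation heterogeneity)
3. Do urban subpopulations differ more in **how variable** they are?
   (heterogeneity in heterogeneity)

The package covers the full workflow: clustering nest boxes into
subpopulations (≥ 5 boxes chained within 300 m), deriving urbanisation
covariates (impervious surface proportion at 100 m and 1000 m, Shannon
land-cover diversity), applying the field's filtering and deduplication
rules, fitting the DHGLM with its own NUTS sampler, and summarising the
posterior with HPDIs and probabilities of direction. A synthetic-data
module generates complete gradient studies from the same model, so every
stage is testable without access to the underlying archives.

## The model

With observation *i* in year *t(i)*, study system *s(i)* and cluster
*c(i)*, and Z-scored responses:

```
y_i         ~ Normal(mu_i, sigma_i)
mu_i        = x_i' beta + a_year[t(i)] + a_sys[s(i)] + a_clust[c(i)]
log sigma_i = z_i' gamma + b_sys[s(i)] + b_clust[c(i)]
```

The dispersion part makes the within-cluster residual SD itself a
regression: the urban coefficient in `gamma` tests hypothesis 2
(back-transformed, a coefficient *g* is a `100·(exp(g) − 1)` % change in
residual SD). Cluster random effects have habitat-specific SDs in both
parts — the urban-vs-forest variance contrasts test hypotheses 1 and 3.
System and cluster effects are correlated bivariate pairs across the two
parts. Priors: Normal(0,1) fixed effects, half-Normal(0,1) SDs, LKJ(2)
correlations. See `docs/methods.md` for the full account.

## Worked example

```python
from urbanvar import (SimScenario, simulate_observations, sample_posterior,
                      MCMCSettings, check_convergence, habitat_variance_contrast,
                      back_transform_dispersion, hpdi)

scenario = SimScenario(species="great_tit", trait="adult_tarsus", seed=7)
sim = simulate_observations(scenario)           # 40 clusters, 4 systems
print(f"simulated {sim.design.n} adult great tits in {len(sim.clusters)} clusters")
draws = sample_posterior(sim.design,
                         MCMCSettings(chains=2, iterations=10_000, warmup=6_000, thin=4),
                         seed=1)
report = check_convergence(draws)
print(f"convergence: worst Rhat {report['worst_rhat']:.3f}, min ESS {report['min_ess']:.0f}")

gamma_hab = draws.get("b_disp[habitat_urban]")
lo, hi = hpdi(gamma_hab, 0.95)
print(f"urban effect on log residual SD: {gamma_hab.mean():.3f} "
      f"[95% HPDI {lo:.3f}, {hi:.3f}] (generating value {sim.params.gamma[1]:.3f})")
pct, _, _ = back_transform_dispersion(gamma_hab)
print(f"=> {pct:.1f}% change in within-cluster residual SD in urban habitats")
contrast = habitat_variance_contrast(draws, "cluster_mean")
print(f"among-cluster variance (mean part): urban {contrast.var_urban.mean():.3f}, "
      f"forest {contrast.var_forest.mean():.3f}, pd(urban>forest) = {contrast.pd:.2f}")
```

which prints:

```
simulated 1580 adult great tits in 40 clusters
convergence: worst Rhat 1.004, min ESS 717
urban effect on log residual SD: -0.016 [95% HPDI -0.195, 0.162] (generating value 0.040)
=> -1.6% change in within-cluster residual SD in urban habitats
among-cluster variance (mean part): urban 0.268, forest 0.104, pd(urban>forest) = 0.95
```

Reading it: a single simulated study of this size cannot pin down a small
urban dispersion effect — the estimate is −0.016 but its 95% HPDI
(−0.195 to 0.162) comfortably spans the generating value 0.040, so the
evidence classification is "none" (hypothesis 2 undecided at this scale).
The among-cluster variance in mean tarsus, by contrast, is estimated ~2.6x
higher in urban habitat with pd = 0.95 (weak evidence for hypothesis 1,
matching the generating urban/forest variance ratio 0.234/0.056 ≈ 4 within
sampling error). The full run takes a few minutes on one CPU.

The same pipeline runs end-to-end from the shell:

```sh
urbanvar all --config config.yaml --out artifacts/
```

with stages `simulate | cluster | preprocess | fit | summarise` also
available individually; artifacts include the cluster tables, filter
reports, posterior draws (CSV), diagnostics and a model-summary table.

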