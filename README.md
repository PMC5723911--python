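# bymgamma

Bayesian hierarchical spatial gamma regression for small-area standardized
disease prevalence, with the full analysis chain around it: direct sex/age
standardization of survey records, Besag–York–Mollié (BYM) spatial random
intercepts, region-varying exposure slopes, Metropolis-within-Gibbs MCMC,
and relative-risk summaries with 95% credibility intervals.

The package is aimed at spatial epidemiologists studying how a community-level
exposure (here: smoking rate, passive smoking at home, passive smoking at
work, in percent) relates to the standardized prevalence of cardiovascular
outcomes (hypertension, stroke, myocardial infarction, angina) across many
small administrative areas observed over several annual survey waves.

## The model

For region *i* and year *t*, the sex/age-standardized prevalence (in percent)
is modelled as

```
y_it ~ Gamma(shape α, mean μ_it),    log μ_it = η_it
η_it = β₀ + β_x·x_it + β_b·bmi_it + β_d·drink_it + β_t·(year_t − ȳ)
       + u_i + v_i + b_i·(x_it − x̄)
```

* `x_it` — one smoking exposure (%); mean BMI and monthly drinking rate are
  confounders; the year enters linearly, centered at the mid-study year.
* `u` — spatially structured intercept with the intrinsic CAR (ICAR) prior:
  precision matrix `Q` has vertex degree on the diagonal and −1 for adjacent
  regions, so `u'Qu = Σ_{i~j}(u_i − u_j)²`; each connected component of the
  adjacency graph carries a sum-to-zero constraint.
* `v_i`, `b_i` — iid zero-mean normal unstructured intercepts and region
  random slopes (the BYM decomposition plus independent slopes).
* Priors: every random-effect precision has a Gamma(1, 5·10⁻⁵) prior, fixed
  effects are zero-mean normal with precision 0.001, and the gamma shape α
  has a Gamma(1, 0.01) prior.

The effect scale is the **relative risk per 5-percentage-point exposure
increase**: nationally `RR = exp(5 β_x)`, and `exp(5(β_x + b_i))` for region
*i*. A 95% equal-tailed posterior interval excluding 1 is reported as a
significant association.

The posterior is computed by Metropolis-within-Gibbs: conjugate Gamma draws
for the precisions, vectorised single-site Metropolis for the random effects
(colour classes of the adjacency graph for `u`), a preconditioned joint walk
for the fixed effects, and η-invariant translation/rescaling moves for the
weakly identified directions (intercept level vs `v̄`, slope level vs `b̄`,
structured/unstructured split of the intercept).

## Worked example

```python
import bymgamma as bg

cfg   = bg.GeneratorConfig(grid_shape=(5, 10), seed=3)   # 50 regions, 2008-2013
truth = bg.sample_truth(cfg)                             # RR 1.060 per 5 points
panel = bg.generate_panel(truth, cfg)

model = bg.SpatialGammaModel(panel, cfg.resolve_graph(), cfg.model_spec())
res = model.fit(bg.SamplerConfig(n_iter=4000, n_burnin=2000, thin=2,
                                 n_chains=2, seed=11))
print(res.summary())
```

prints (abridged):

```
Bayesian hierarchical gamma regression (BYM intercept + random slopes)
outcome: stroke   exposure: smoking_rate
regions: 50   observations: 300   chains: 2   draws/chain: 1000

                          mean         sd    ci_2.5%   ci_97.5%
parameter
beta[intercept]        -0.1199     0.8602    -1.9950     1.6214
beta[smoking_rate]      0.0383     0.0304    -0.0203     0.0995
beta[mean_bmi]         -0.0131     0.0159    -0.0437     0.0203
beta[drinking_rate]     0.0059     0.0018     0.0021     0.0094
beta[year_centered]     0.0037     0.0052    -0.0066     0.0141
...
tau_b                  22.7721     4.5462    15.0117    33.2594
alpha                  51.5534     5.1839    41.9536    62.2209

national RR per 5-point smoking_rate increase: 1.225 (95% CI 0.903, 1.645)
```

The national RR point estimate is the posterior mean of the `exp(5β_x)` draws;
the interval is the 2.5–97.5 percentile band. Here the interval covers the
generating truth (1.060); with only 50 regions the interval is wide because
the national slope is entangled with the mean of the region random slopes.
Per-region RRs, rankings and CSV export:

```python
res.rr_regional()[:3]          # RRSummary per region
res.rank_regions(k=5)          # top/bottom 5 regions by RR
res.export_region_table("region_rr.csv")
res.diagnostics()              # split R-hat / ESS via ArviZ
```

The same pipeline is scriptable from the shell:

```
bymgamma simulate --seed 7 --grid 5x10 --records --outdir data/
bymgamma standardize --records data/records.csv --outdir std/
bymgamma fit --prevalence std/panel_prevalence.csv \
             --covariates std/panel_covariates.csv \
             --adjacency data/adjacency.txt --outcome stroke \
             --exposure smoking_rate --outdir fit/
bymgamma report --samples fit/samples.csv --outdir report/
```

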