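# Methods

## Scope

`bymgamma` implements a small-area association analysis between
community-level smoking exposures and standardized cardiovascular disease
prevalence: survey records → direct sex/age standardization → a Bayesian
hierarchical gamma regression with spatial random intercepts and region
random slopes → national and per-region relative risks (RR) per
5-percentage-point exposure increase. A synthetic-data module generates data
from the model's own forward process with known truth, so every stage is
testable without access to restricted survey microdata.

## Direct standardization

The standardized rate of a binary indicator is `100 · Σ_s w_s r_s` over
sex × age-group strata, with `r_s` the stratum mean among non-missing values
(complete-case within stratum) and `w_s` normalized standard-population
weights. Disease outcomes are computed on age-restricted subsets
(hypertension ≥ 30, stroke ≥ 50, myocardial infarction and angina ≥ 40
years); a configured age band that straddles a cutoff is rejected rather
than split. Design choices where the convention is genuinely open:

* **Reference population** — by default each year's pooled sample demography
  is that year's standard (year-specific standardization); any standard can
  be supplied as a CSV of `sex, age_group, weight`.
* **Empty strata** — their weight is redistributed proportionally over the
  observed strata (keeps weights summing to 1); a switch drops that weight
  instead.
* **Age bands** — default 5-year bands 19–24 … 80+, configurable.

Two identities pin the implementation down exactly: standardizing with the
sample's own demography reproduces the crude rate, and the result is
invariant to replicating the record set.

## The hierarchical model

Observation model for region *i*, year *t* (prevalence `y` in percent,
strictly positive):

    y_it ~ Gamma(shape α, mean μ_it),  rate = α/μ_it
    log μ_it = β₀ + β_x x_it + β_b bmi_it + β_d drink_it
               + β_t (year_t − ȳ) + u_i + v_i + b_i (x_it − x̄)

The gamma family reflects that regional prevalence distributions are
positive and right-skewed (a Shapiro–Wilk screen of the panel is provided as
`normality_screen`, informational only). The log link makes `exp(5β_x)` the
national RR per 5 exposure points and `exp(5(β_x + b_i))` region *i*'s RR.

* **BYM intercept.** `u` has the intrinsic CAR prior with kernel
  `(rank(Q)/2)·log τ_u − (τ_u/2)·u'Qu`, `Q = D − A` from the adjacency
  graph; `v_i ~ N(0, 1/τ_v)` iid. The ICAR prior is improper per connected
  component, so each component's mean of `u` is constrained to zero. The
  pseudo-determinant of `Q` is a constant and is dropped; the τ-dependent
  `rank/2 · log τ_u` factor is kept so the conjugate τ_u update sees the
  correct power.
* **Random slopes.** `b_i ~ N(0, 1/τ_b)` iid, spatially unstructured, so
  intercepts and slopes are independent a priori. The slope multiplies the
  exposure's *deviation from its mean* (`x̄` = sample mean in the model,
  configured mean in the generator). This is a reparameterisation of the
  same region-slope structure — the slope on `x` is `β_x + b_i` either way
  and all RRs are unchanged — chosen because with raw `x ≈ 25 ± 3` the
  region intercept and slope are ~99% collinear, which both cripples
  single-site samplers and makes the implied intercept heterogeneity
  (`exp(b_i·x̄)`) explode at realistic slope variances.
* **Priors.** Every precision τ has a Gamma(1, 5·10⁻⁵) prior — nearly flat
  over (0, ~2·10⁴) — and each fixed effect an independent N(0, 1/0.001).
  The likelihood shape α (shared across cells of one outcome) has a
  Gamma(1, 0.01) prior: weakly informative and scale-free enough for shape
  values in the tens, where the per-cell coefficient of variation
  `1/√α ≈ 0.14` matches the observed spread of standardized prevalence.
* **Nonpositive cells.** A gamma response cannot be 0; cells with
  nonpositive standardized prevalence are dropped with a warning by default
  (`half_min` imputation behind a flag). Covariates enter in natural units
  (percent, kg/m²), uncentered, except the year.

## Posterior computation

Metropolis-within-Gibbs (`mcmc.py`), chosen over deterministic
approximations because every update is transparent and testable against
closed forms:

* conjugate Gibbs for τ: `Gamma(a + r/2, c + S/2)` with `r` = vector length
  and `S = Σe²` (iid) or `r = rank(Q)`, `S = u'Qu` (ICAR);
* joint random-walk Metropolis for β, preconditioned with
  `chol((X'X)⁻¹)`;
* single-site random-walk Metropolis for `u`, vectorised over the colour
  classes of a proper graph colouring (no two updated regions adjacent, so
  the batched update factorises exactly); `v` and `b` factorise across
  regions and are updated in one vectorised batch;
* `u` is re-centred per component after each sweep, the mean shift absorbed
  into β₀ (exact η-invariance on connected graphs; on disconnected graphs
  this is the usual on-the-fly centering of areal samplers);
* α is updated on the log scale with the Jacobian correction;
* three η-invariant moves target the weakly identified directions:
  translation of `v̄` against β₀, translation of `b̄` against β_x (with the
  compensating β₀ shift), and two rescaling moves that exchange magnitude
  between the structured and unstructured intercepts jointly with their
  precisions (the second only on connected graphs, where absorbing the mean
  shift into β₀ is exact). Without these, the posterior of β_x and the τ's
  mixes an order of magnitude slower because the likelihood constrains only
  sums such as `u_i + v_i` and `β_x + b̄`.

Proposal scales adapt by Robbins–Monro during burn-in only (targets 0.44
scalar / 0.23 block) and are frozen afterwards. Initialisation is
deterministic: log-linear least squares for β, zeros for random effects,
precisions 1, α from the log-residual variance. Identical (data, config,
seed) reproduce bit-identical draws; per-chain generators derive from
`(seed, chain)`.

Defaults: 4 chains × 10,000 iterations, 5,000 burn-in, thinning 5 — sized
for ~253 regions × 6 years on a single CPU (a fit of that size with 2
chains × 4,000 iterations takes a few seconds). Diagnostics (split-R̂, ESS,
acceptance rates) are computed via ArviZ; R̂ > 1.05 or ESS < 100 raise
warnings, and the CLI `fit` command exits nonzero at R̂ > 1.2 unless
`--force`. The structured/unstructured variance split (τ_u vs τ_v) remains
weakly identified with few within-region replicates — its posterior is
diffuse and prior-sensitive even when the chain mixes well; the exposure
slope and the RRs do not suffer from this.

## Effects

RR summaries are computed draw-wise (`exp(δ·β)`), δ = 5 points by default.
The point estimate is the posterior mean of the RR draws (median behind a
flag); intervals are equal-tailed 2.5/97.5 percentiles, so the RR interval
is the exponential of the slope interval and "95% CI excludes 1" is
equivalent to the slope interval excluding 0. Rankings sort descending by
point estimate with ties broken by region id; the per-region table exports
as CSV joinable to any boundary file for mapping.

## Synthetic data

The generator is the forward model itself plus a respondent level:

* `sample_truth` draws `u` from the ICAR distribution at τ_u (via the
  positive eigenspace of Q, hence exactly centred per component), `v`, `b`
  iid normal, and calibrates β₀ analytically so the marginal mean of the
  primary outcome matches its target (default 3.3% — a stroke-like outcome;
  treated-as-normal moments for the logit-normal exposure make this
  calibration approximate but accurate to well under the ±1-point check
  band). Default truth: RR 1.060 per 5 points (β_x = ln(1.060)/5),
  τ_u = τ_v = τ_b = 25, α = 50.
* `generate_panel` draws covariates per region-year — logit-normal rates
  and normal BMI moment-matched to the published descriptive statistics of
  the study population (smoking 25.2 (SD 2.9)%, passive home 11.8 (4.1)%,
  passive work 29.2 (9.3)%, drinking 56.5 (5.4)%, BMI 23.0 (0.7)) — and the
  response from the gamma law. Non-primary outcomes use a simpler
  lognormal-region-effect gamma model matched to their mean/SD so a full
  four-outcome panel exists. Defaults: 253 regions on an 11×23 rook lattice,
  years 2008–2013, 900 respondents per region-year.
* `generate_survey_records` re-draws the *same* gamma region-year
  prevalences (shared sub-seed) and samples respondents around them:
  sex/age strata from a configured demography, disease indicators Bernoulli
  with a mild age gradient normalized against the demography restricted to
  each outcome's assessment ages (so the standardized prevalence estimates
  the cell's gamma draw), exposure/drinking flags Bernoulli at the cell
  rates, BMI normal with individual SD 3 kg/m². Sharing the aggregate draw
  is what makes the two generation paths agree to binomial sampling error —
  the closure property the pipeline tests rely on.

What the generator does **not** emulate: survey design weights and
probability-proportional-to-size sampling, nonresponse, measurement error,
spatial structure in the covariates, temporal autocorrelation of exposures
within a region, and real contiguity geometry (a rook lattice stands in for
the administrative map). Passing tests therefore demonstrate correctness of
the estimator under its own assumptions, not robustness to these realities.

## Numerical details and limitations

* Region order is the lexicographic order of region ids everywhere.
* The sum-to-zero constraint is enforced to 10⁻⁸; `log_prior` rejects
  states violating it.
* Overflow in proposal evaluation is handled by rejecting (−∞ log-ratio).
* The quadrature oracle and the degenerate-limit comparison in the test
  suite are written against scipy/statsmodels, independent of the package's
  likelihood code.
* With 50 regions the national slope posterior is dominated by the prior
  identification of the mean random slope (sd ≈ `1/√(n τ_b)`); credible
  intervals are honest about this (they are wide), and simulation studies
  at that scale show between-dataset RR spread of ±0.15 — a property of the
  design, not the sampler.
* Disconnected adjacency graphs are supported (per-component constraints);
  the second intercept-rescaling move is skipped there, costing some mixing
  efficiency for the variance split only.
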