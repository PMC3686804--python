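# Methods

## The model

Let `C_it` be the count of birds on circle `i` (in region `r = r(i)`)
in winter `t`. Counts are modelled as over-dispersed Poisson:

```
C_it ~ Poisson(mu_it)
log mu_it = beta0_r + beta1_r (t - t_mid) + beta2 * boat_it
            + gamma_i + delta_t + f(zeta_it) + eps_it
```

* `beta0_r`, `beta1_r` — region intercept and log-linear trend. With
  two or more regions both are exchangeable draws from common normal
  distributions whose means get N(0, 10³) priors and whose variances
  get inverse-gamma(0.001, 0.001) priors; with a single region the
  hyperdistribution is unidentified and the coefficients take the flat
  N(0, 10³) prior directly.
* `beta2` — additive log-scale effect of boat use (the survey record
  carries only a binary flag, not boat hours).
* `gamma_i ~ N(0, s2_circle)` — circle effects; `delta_t ~ N(0,
  s2_year)` — year effects beyond trend, shared across regions (the
  more parsimonious of the two possible readings; a regional year
  effect would add R×T parameters that CBC-sized data cannot support).
* `eps_it ~ N(0, s2_noise)` — per-observation noise; this is what makes
  the counts over-dispersed (Poisson-lognormal).
* `f(zeta) = B ((zeta/zeta_m)^p - 1)/p` — nonlinear effort adjustment,
  `zeta` the total survey hours and `zeta_m` their mean over the
  dataset, so `f = 0` at typical effort. A single `(B, p)` pair is
  shared by all regions. `p` is constrained positive by sampling
  `log p` with a N(0, 1.5²) prior — wide enough for `p` anywhere in
  roughly [0.01, 90] while keeping `(zeta/zeta_m)^p` representable;
  below `p = 1e-4` the limit `B log(zeta/zeta_m)` is evaluated by
  series expansion. `B` takes the same N(0, 10³) prior as the other
  coefficients: a hierarchical variance on a single scalar identifies
  nothing.
* The time covariate is centred at the series midpoint, decorrelating
  intercept and trend.

Missing surveys (circle-years with no records) contribute nothing to
the likelihood; their expected counts are reconstructed afterwards from
the posterior as derived statistics, which is what lets circles with
patchy coverage stay in the analysis.

**Identifiability.** The likelihood cannot separate a region intercept
from the mean of its circle effects, nor the trends from a linear drift
in the shared year effects. Stored draws are therefore projected to the
identified contrasts: circle effects sum to zero within region, year
effects sum to zero and are orthogonal to the centred time covariate,
with the swept-out mean and slope moved into `beta0_r` and `beta1_r`.
The linear predictor is unchanged by this projection; reported trends
are the total (identified) log-linear change.

## Sampling

The posterior is explored by an adaptive Metropolis-within-Gibbs
sampler, all blocks vectorised with numpy:

* conjugate Gibbs for the three variance components and, with several
  regions, the hyper-means and hyper-variances of `beta0`/`beta1`;
* elementwise random-walk Metropolis for the noise field with per-site
  proposal scales matched to the local conditional curvature
  `1/s2_noise + mu` (the curvature proxy omits the site's own noise
  term so the proposal stays symmetric); two passes per sweep;
* blockwise random-walk Metropolis for circle, year and region
  coefficients, with per-group curvature-matched scales;
* a joint `(B, log p)` random-walk preconditioned by a running
  covariance estimate, plus a transport move that perturbs `log p`
  while rescaling `B` to hold the effort effect at one standard
  deviation of log effort fixed (the deterministic map contributes a
  Jacobian term) — the `(B, p)` posterior is a curved ridge;
* likelihood-invariant translation moves along every confounded ridge:
  intercept vs circle effects, intercepts/trends vs year-effect mean
  and drift, and — the decisive ones for mixing — moves that shift a
  coefficient while absorbing the change into the noise field, leaving
  the likelihood untouched so only Gaussian priors enter the ratio;
* interweaving moves that rescale each variance component jointly with
  its field (non-centred step), curing the variance/field funnels.

Proposal scales adapt by Robbins–Monro during burn-in only (targets
0.44 for one-dimensional blocks, 0.25 for the two-dimensional one), so
the retained draws come from a fixed kernel. Chains are initialised
from data-derived intercepts with seeded jitter; each chain and every
random draw derives deterministically from the fit seed, making fits
bit-for-bit reproducible.

Defaults follow the two-chain protocol: burn-in of 10,000 sweeps (one
sweep ≈ one model-equivalent iteration), 5,000 retained draws per
chain. Convergence is declared only if every monitored parameter —
region coefficients, boat effect, effort parameters, variance
components, hyper-parameters — has split R-hat ≤ 1.1 and Monte-Carlo
error/posterior sd ≤ 0.05 (computed as 1/sqrt(ESS), bulk ESS via
arviz). The pipeline halts on a non-converged fit unless overridden.

## Posterior predictive check

At every retained draw a replicate dataset is drawn from
`Poisson(mu_it)` at that draw's realised means (noise included), and
observed and replicated data are compared through a sums-of-squared-
error discrepancy — squared Pearson residuals `(C - mu)²/mu` by
default, plain squared error by option, since the variance scaling is a
convention the analyst must pick. The Bayesian p-value is the fraction
of draws whose replicated discrepancy is at least the observed one
(ties count toward the numerator; they matter only in degenerate
integer cases). Values near 0.5 indicate a model that reproduces its
own data-generating behaviour; the package's self-consistency tests
require p in (0.2, 0.8) for data simulated from the model itself.

## Derived quantities

* **Abundance index** — for each region-year, the posterior predicted
  mean count per circle at standardized conditions: mean effort
  (`f = 0`), boat off, noise at its zero mean, averaged over every
  circle of the region including unsurveyed circle-years. Summaries are
  the posterior mean and the central (equal-tailed) 2.5%/97.5%
  interval. Setting the noise term to zero reports the median-scale
  component of abundance; any lognormal mean correction would cancel
  out of ratios and thus of trends.
* **Trend** — the geometric mean of proportional index changes between
  the first and last modelled years, `100 ((I_T/I_1)^(1/(T-1)) - 1)`,
  computed per posterior draw so the credible interval propagates all
  uncertainty; a trend is significant when the 95% interval excludes
  zero. In the zero-year-effect limit this equals `100 (e^{beta1} - 1)`
  exactly. A regression through all years is a reasonable alternative
  estimator but the endpoint form is the default, matching the
  geometric-mean definition.
* **Cumulative change** — `100 ((1 + r/100)^n - 1)` over `n`
  year-to-year intervals.
* **Centre of occurrence** — the count-weighted mean latitude
  `sum(m_i y_i)/sum(m_i)` over all circles, using the standardized
  predicted counts per draw; the shift between two years is converted
  at 111.195 km per degree of latitude (meridian arc on the mean-radius
  sphere; the constant is deliberately explicit since published
  figures of this kind are often not exactly recoverable from rounded
  centre latitudes).

## The synthetic-data generator

`simulate_dataset` draws from exactly the model above, so parameter
recovery is a meaningful end-to-end test. It emulates: region
intercepts spanning two orders of magnitude in mean count (calibrated
to the spread seen across real winter-count regions, from strongholds
near 10³ birds per circle to sparse interiors near 10), steep declines
and strong increases, large between-circle heterogeneity (the default
scenario uses sigma_circle = 1.87, the value reported for winter count
circles within regions), lognormal survey hours acting through the
nonlinear effort effect, a Bernoulli boat covariate, independent
Bernoulli missingness, and genus-level relabelling by binomial thinning
at a configurable fraction (13.9% is the reported post-split rate).
Randomness uses one root seed with deterministic per-circle substreams,
so enlarging a scenario appends circles without reshuffling existing
ones.

It does **not** emulate observer-skill differences, spatial
autocorrelation between circles, weather, or non-random missingness.
Passing recovery tests therefore demonstrate correctness of the
machinery under the model's own assumptions, not robustness of the
model to real-data violations of them.

## Problem sizes and test design

The package's tests run everything at desk scale by choice: recovery
experiments use a single region of 13–30 circles over 36 years
(roughly 400–1,000 observed surveys) with burn-in 10,000 and 5,000
draws per chain; the interval-calibration suite uses twenty replicates
of 8 circles × 24 years with shorter chains; the pipeline tests use
two regions of 5 circles over 15 years. At these sizes a full fit
takes tens of seconds on one core and all monitored diagnostics pass
the convergence thresholds.

## Known limitations

* The sampler is random-walk based; datasets orders of magnitude larger
  than the test scales would warrant a gradient-based sampler. The
  sampler contract is distributional (pinned by the likelihood/prior
  oracles and recovery tests), so the engine can be swapped.
* The inverse-gamma(0.001, 0.001) prior on variance components is the
  conventional "vague" choice but is known to be influential when a
  variance is near zero (the year-effect variance in several test
  scenarios); it is kept for fidelity and is config-overridable.
* Genus-level allocation assumes the identified ratio on a count is
  unbiased for the unidentified birds on that count.
* Coast distance is an input column; no coastline geometry is computed.
* The boat flag enters additively on the log scale; any interaction
  with effort hours is not modelled (boat hours are not recorded).
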