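# cbctrend

Hierarchical Bayesian trend, effort-adjustment and range-shift analysis
for circle-based winter count surveys, in the mould of the Audubon
Christmas Bird Count (CBC): volunteers count every bird inside a fixed
24.1-km circle on one day each winter, recording total survey hours and
whether a boat was used. Counts from such programmes are invaluable for
detecting long-term change in wintering waterbird populations — the
motivating case is the collapse of western grebe (*Aechmophorus
occidentalis*) numbers in the Salish Sea alongside increases in
California — but they are noisy: effort varies between circles and
years, circles differ enormously in how many birds they hold, surveys
go missing, and a slice of grebes is reported only to genus.

`cbctrend` packages the full analysis chain:

* **Data handling** — validated CSV ingest, genus-level (`UNID`) counts
  apportioned by the identified western:Clark's ratio on the same count
  (with a regional fallback chain), circle filtering (≥ 10 birds lifetime
  and surveyed in ≥ 50% of years), and a configurable rule table that
  groups circles into analysis regions by coast distance (< 50 km =
  coastal) and latitude.
* **The model** — counts are over-dispersed Poisson,

  ```
  C_it ~ Poisson(mu_it)
  log mu_it = beta0_r + beta1_r (t - t_mid) + beta2 * boat_it
              + gamma_i + delta_t + f(zeta_it) + eps_it
  f(zeta)   = B ((zeta/zeta_m)^p - 1) / p          (p -> 0: B log(zeta/zeta_m))
  ```

  with region intercepts/trends `beta0_r, beta1_r` drawn from common
  normal distributions, circle effects `gamma`, year effects beyond
  trend `delta`, observation noise `eps` (the over-dispersion), and a
  nonlinear effort adjustment `f` shared by all regions. Priors are
  vague: N(0, 10³) on coefficients, inverse-gamma(0.001, 0.001) on
  variances. Missing surveys simply drop out of the likelihood and are
  recovered later as derived statistics.
* **Fitting** — a vectorised adaptive Metropolis-within-Gibbs sampler
  (conjugate Gibbs for variances and hyper-means; curvature-matched
  random-walk blocks plus likelihood-invariant ridge moves for
  everything else), run as two independent chains with split Gelman–
  Rubin R-hat and Monte-Carlo-error/sd checks per parameter.
* **Checking** — posterior predictive replication with a
  sums-of-squared-error (Pearson) discrepancy and the Bayesian p-value
  (≈ 0.5 means a well-fitting model).
* **Derived quantities** — effort-standardized regional abundance
  indices (missing surveys imputed), geometric-mean annual percent
  trends with 95% credible intervals and significance calls, cumulative
  change, and the abundance-weighted latitudinal centre of occurrence
  with its shift in km.
* **Synthetic data** — a generator that draws datasets from exactly the
  model above with known ground truth, so every stage is testable
  without access to the proprietary survey database.

## Worked example

```python
import cbctrend as ct

cfg = ct.default_config(seed=42)           # 4 regions, 36 winters
dataset, truth = ct.simulate_dataset(cfg)
dataset = ct.allocate_unidentified(dataset)
dataset, excluded = ct.filter_circles(dataset, min_total=10, min_coverage=0.5)

model = ct.CircleCountModel(dataset)
results = model.fit(ct.MCMCConfig(n_chains=2, burn_in=8000,
                                  n_samples=4000, seed=1))
print(results.trend_table().round(2).to_string(index=False))
print("bayesian_p =", round(results.ppc(seed=1, thin=10).bayesian_p, 2))
print(results.range_shift(1980, 2010))
```

prints (about half a minute on one core):

```
                   region  annual_percent  lower95  upper95  significant
Northern California Coast           -0.92    -1.44    -0.38         True
        Northern Interior            0.02    -0.74     0.82        False
               Salish Sea           -9.22    -9.72    -8.71         True
    Southwestern Interior            6.65     5.83     7.45         True
              continental           -5.13    -5.61    -4.64         True
bayesian_p = 0.53
centre 1980: 47.09 deg N -> 2010: 41.25 deg N, shift 649 km south
```

The generating truths for the four regions were −9.29, −0.73, +6.70 and
+0.60 %/yr: the fit recovers the steep stronghold decline and the
interior increase, flags the near-flat region non-significant, and the
count-weighted centre of the simulated winter range moves south as the
northern stronghold empties. `results.summary()` gives the full
parameter table with R-hat and MC-error diagnostics, and
`results.abundance_index()` the tidy per-region index series.

The same stages are available from the shell:

```
cbctrend simulate scenario.yaml -o data.csv --truth truth.csv
cbctrend filter data.csv -o filtered.csv --report excluded.csv
cbctrend fit filtered.csv -o draws.csv --manifest fit.yaml
cbctrend run-all config.yaml
```

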