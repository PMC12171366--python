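# espccd

Tools for studying the **balance between health and income in rural
households** and the causal effect of **high-intensity work** on that
balance, from village-clustered survey microdata.

The package implements, as a reusable and tested pipeline:

* **Entropy-weighted composite indices.** Raw health indicators
  (self-rated health, mental distress, smoking, drinking, exercise,
  medical visits) and livelihood indicators (human, natural, physical,
  financial and social capital) are min-max normalized with declared
  orientations and weighted by the entropy method, giving per-household
  scores `Health_i` and `Income_i` in [0, 1].

* **Coupling coordination degree (CCD).** For each household,

  ```
  C = 2 * sqrt(H * I) / (H + I)        # coupling: similarity of subsystems
  T = alpha * H + beta * I             # coordination: average level (alpha = beta = 1/2)
  D = C * T                            # coupling coordination degree
  ```

  with `D = sqrt(C * T)` available behind a flag. Households with
  `D >= 0.5` are classed *health-income balanced* (1), the rest
  imbalanced (0).

* **Endogenous switching probit (ESP) by FIML.** Work intensity is a
  self-selected binary treatment (weekly hours strictly above the
  sample mean). The system

  ```
  I*  = gamma'Z + u          I = 1{I* > 0}       (selection)
  Y1* = beta1'X + eps1       Y1 = 1{Y1* > 0}     (treated regime)
  Y0* = beta0'X + eps0       Y0 = 1{Y0* > 0}     (untreated regime)
  ```

  has correlated errors `corr(u, eps1) = rho1`, `corr(u, eps0) = rho0`,
  so selection on unobservables is handled jointly. `Z` contains the
  controls plus a leave-one-out instrument: the share of *other*
  same-village members doing high-intensity work (peer effect).
  Estimation is full-information maximum likelihood built on the
  bivariate normal CDF, with analytic scores, village-cluster-robust
  covariance, and a Wald test of `rho1 = rho0 = 0`.

* **ATT with counterfactual probabilities.** For each treated household
  the treated-regime and counterfactual untreated-regime balance
  probabilities are compared conditional on selection; the relative
  change is `|ATT| / p_treated * 100`.

* **Robustness battery.** Age-exclusion refit (drop ages above 70),
  1:1 nearest-neighbour propensity score matching, and subgroup ATTs
  by workplace (native / non-native community) and region.

* **Synthetic populations with known ground truth.** The survey data
  such studies use is typically restricted, so a generator emulates
  village clustering, realistic covariate marginals, trivariate-normal
  latent errors and both potential outcomes per farmer — every stage is
  testable against exact ground truth.

## Worked example

```python
from espccd import SyntheticConfig, generate_population, true_att, ESPData, \
    fit_esp, att_esp, wald_independence_test

cfg = SyntheticConfig(n_villages=250, village_size_range=(15, 25),
                      mode="model", rho1=0.25, rho0=0.10, seed=3)
table, truth = generate_population(cfg)
data = ESPData.from_frame(table, outcome="balanced", treatment="work",
                          covariates=["gender", "insurance", "internet", "lnpop_total"],
                          instrument="iv", cluster="village_id")
est = fit_esp(data)
print(f"rho1 = {est.rho1:.3f}, rho0 = {est.rho0:.3f}")
print(f"Wald indep. = {wald_independence_test(est).statistic:.3f}")
rep = att_esp(est, data, bootstrap_reps=20, seed=1)
print(f"ATT = {rep.att:.3f} (se {rep.se:.3f}), change = {rep.change_pct:.1f}%")
print(f"ground truth ATT = {true_att(truth, table):.3f}")
```

Output:

```
rho1 = 0.242, rho0 = 0.085
Wald indep. = 6.652
ATT = -0.159 (se 0.020), change = 176.6%
ground truth ATT = -0.170
```

The fitted correlations land on the generating values (0.25 / 0.10), the
Wald test rejects independence of the equations, and the estimated ATT
matches the potential-outcome ground truth within sampling error: the
treated-regime balance probability is about 16 percentage points below
the counterfactual, i.e. high-intensity work sharply lowers the chance
of balanced health-income development under this generating process.

For the full survey-style flow (indicators → entropy indices → CCD →
ESP → robustness) use the CLI:

```bash
espccd run-all --config config.yaml
```

with a YAML config naming either an input CSV or a `synthetic` block;
subcommands `simulate`, `indices`, `ccd`, `fit`, `att` and `robustness`
expose the individual stages. Every run writes a manifest recording the
seed, configuration and SHA-256 of each output, and identical
config + seed reproduces every output byte for byte.

## Layout

```
src/espccd/
  preprocess.py           winsorization, logs, work flag, leave-one-out IV, t-tests
  entropy_index.py        indicator schema, normalization, entropy weights, scores
  ccd.py                  C, T, D and the balance class
  esp_probit.py           bivariate normal CDF, FIML system, Wald test, ATT
  effects_robustness.py   exclusion refit, PSM, subgroup ATTs
  synthetic_data.py       village-clustered generator with ground truth
  cli_pipeline.py         config-driven runner, CSV IO, click CLI
docs/methods.md           model, assumptions, numerical choices, limitations
```
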