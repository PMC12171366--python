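# Methods

This note documents the models implemented in `espccd`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Composite indices

Health and income (livelihood) levels are composite indices over raw
indicator panels. Each indicator has a declared orientation; indicators
are min-max normalized to [0, 1], with negative-orientation ones
reversed as `(max - x) / (max - min)`. A constant column carries no
information: it is normalized to zeros and warned about rather than
erroring, since degenerate indicators occur in small subsamples.
Missing indicator values are an error — the pipeline is complete-case
by design, mirroring how such surveys are typically cleaned before
index construction.

Entropy weighting uses the plain column-share convention: shares
`p_ij = x'_ij / sum_i x'_ij`, Shannon entropy `e_j = -(1/ln n) sum p ln p`
with `0 ln 0 := 0`, divergence `d_j = 1 - e_j`, weights `w_j`
proportional to `d_j`. No epsilon shift is applied by default; a
`zero_offset` argument reproduces the epsilon-shifted variant used by
some implementations, because the two conventions can differ noticeably
on sparse indicators and published analyses rarely say which was used.
All-zero columns get weight zero (warned); a panel with no informative
column at all is an error.

Entropy weights are scale-dependent in an important way: long-tailed
count indicators (livestock, property income) concentrate their shares
on a few households, which drives entropy down and weight up. This is
faithful to the method — published weight tables from this kind of
survey show exactly this concentration — but it means composite scores
are sensitive to indicator coding.

## Coupling coordination degree

For bounded subsystem scores H and I the coupling degree is
`C = 2 sqrt(HI) / (H + I)` (1 iff H = I > 0, by AM-GM), the coordination
index is `T = alpha H + beta I` with `alpha = beta = 1/2` (the two
subsystems are given equal status), and the coupling coordination
degree is `D = C * T` by default. The CCD literature more commonly uses
`D = sqrt(C * T)`; both are implemented (`d_formula`), the default
follows the formula as printed in the applied work this package
mirrors, and the choice is recorded in every pipeline manifest. Since
`C * T` is in [0, 1], the product form is always the smaller of the
two, so the choice shifts the share of households above any threshold
and must be held fixed across compared runs.

Degenerate input: at H = I = 0 the diagonal limit of C is 1, but a
household with zero health and zero income capital is treated as
uncoupled, C := 0. Households are classed *balanced* when
`D >= 0.5` — the boundary counts as balanced.

## Variable construction

* Winsorization clips at the 1st/99th percentile order statistics
  (numpy `method="lower"`/`"higher"`), not interpolated quantiles; this
  makes clipping exactly idempotent. A `trim` mode drops instead of
  clipping.
* The high-intensity work flag is `hours > mean(hours)` with a strict
  inequality: a farmer exactly at the mean is low-intensity. The flag
  is invariant to adding a constant to everyone's hours.
* The instrument for work intensity is the leave-one-out village share:
  for farmer i in a village of size T, the fraction of the other T - 1
  members flagged high-intensity. The numerator excludes the respondent
  and the denominator is T - 1, which keeps the share in [0, 1];
  singleton villages have no peers and yield a missing value (or are
  dropped, or raise, per option). Exclusion rests on the peer-effect
  argument: co-villagers' work intensity shifts one's own work choice
  but has no direct channel to one's own health-income balance.
* The descriptive screen is a two-sample t-test per variable, pooled
  variance by default with a Welch option, differences oriented as
  low-intensity minus high-intensity, stars at the 10/5/1% levels.

## Endogenous switching probit

The system (selection equation + two regime-specific binary outcome
equations) is estimated by full-information maximum likelihood. Each
observation contributes one of four cells, with the standard
switching-probit sign convention:

| arm | outcome | cell probability |
|---|---|---|
| treated | y = 1 | Phi2( g'Z,  b1'X;  rho1) |
| treated | y = 0 | Phi2( g'Z, -b1'X; -rho1) |
| control | y = 1 | Phi2(-g'Z,  b0'X; -rho0) |
| control | y = 0 | Phi2(-g'Z, -b0'X;  rho0) |

The four cells sum to one identically (tested), and at
`rho1 = rho0 = 0` the log-likelihood factorizes exactly into three
independent probits (tested against statsmodels).

**Bivariate normal CDF.** `bvn_cdf` uses the Owen's-T decomposition
(`scipy.special.owens_t`), accurate to ~1e-15 and fully vectorized,
which is what makes likelihood evaluation cheap enough for bootstrap
refits. Exact zeros in the arguments are replaced by +1e-15 to resolve
the 0/0 in the T-function arguments (error below 1e-12), and
`|rho| >= 1 - 1e-12` falls back to the comonotone/antimonotone limits.
Accuracy is verified in the tests against the arcsine closed form at
the origin and against iterated numerical double integration on an
(a, b, rho) grid.

**Optimization.** Correlations are estimated on the atanh scale so the
search is unconstrained; starting values are the three separate probits
with atanh-rho at 0. The mean log-likelihood is maximized by BFGS with
the analytic score (gradient tolerance 1e-7); convergence is reported
honestly via a flag (optimizer status plus a gradient check), and a
constrained fit with both correlations pinned at zero is available as
the null model for likelihood-ratio comparisons. Collinear covariates
and a missing or constant instrument are rejected at construction, not
silently absorbed.

**Covariance.** Cluster-robust (sandwich) by village: the bread is a
central-difference Hessian of the analytic score, the meat is the outer
product of within-village score sums with a G/(G-1) correction. The
Wald test of independent equations is the chi-square(2) statistic for
the two atanh-scale correlations. Coverage of the resulting 95%
intervals is verified by simulation (200 replications at n ~ 5,000) in
the acceptance tests.

**ATT.** For treated household i,

```
p1_i = Phi2(g'Z_i, b1'X_i; rho1) / Phi(g'Z_i)
p0_i = Phi2(g'Z_i, b0'X_i; rho0) / Phi(g'Z_i)
ATT  = mean(p1_i - p0_i),   change% = |ATT| / mean(p1_i) * 100
```

with the selection probability floored at 1e-12 against underflow.
These are *predicted* conditional probabilities (the observed-mean
alternative can be assembled through `ATTReport.from_probabilities`);
the change denominator is the treated-regime column, the only
definition consistent with the standard triplet arithmetic
(e.g. 0.011/0.129 -> 8.527%). The ATT standard error is a
nonparametric village-cluster bootstrap (default 500 replicates,
seeded, warm-started at the full-sample estimate); replicates that fail
to fit are skipped, and fewer than 10 successes yields a missing SE
with a warning rather than a fabricated one.

## Robustness procedures

* **Exclusion refit** re-runs the full fit and ATT on a rule-filtered
  sample (canonically age <= 70) and records the rule and counts.
* **PSM** estimates the propensity by probit (or logit) on the outcome
  covariates — never the instrument, which belongs to the selection
  equation only — and matches 1:1 nearest-neighbour, greedy in
  descending treated-score order. The module default is matching
  without replacement (raising when treated outnumber controls); the
  pipeline defaults to replacement because a work share near one half
  makes the no-replacement design infeasible about half the time. An
  optional caliper discards treated units with no close control. The SE
  is a paired bootstrap over villages. A standardized-mean-difference
  balance table is provided as a diagnostic.
* **Subgroup ATTs** refit the whole system inside each level of a
  declared partition (workplace, region). Labels must cover every row;
  subgroups that cannot be fitted (too small, one-armed, separated, or
  non-converged) are reported as skipped with the reason. Controls that
  are constant within a subgroup (e.g. the region dummy inside a region
  subgroup) are dropped with a warning before the rank check.

## Synthetic data generator

The generator is the package's stand-in for restricted survey
microdata; its defaults are the study conditions.

* **Layout.** 497 villages of 4-13 farmers (about 4,100 households, the
  scale of the motivating survey). Binary covariate marginals are
  calibrated to the survey's descriptive statistics (male 0.544,
  married 0.919, party member 0.037, insured 0.119, internet 0.443;
  village facilities 0.174/0.831/0.468/0.577); household sizes are
  negative-binomial with matched mean/SD (3.429/2.052 and 1.140/1.446);
  weekly hours are 48 +- a village effect (SD 6) and individual noise
  (SD 12), giving a high-intensity share near 0.504 under the
  mean threshold.
* **Model mode** draws treatment and both potential outcomes directly
  from the probit system. (u, eps1, eps0) are trivariate normal with
  `corr(eps1, eps0) = 0` — the two outcome errors are never jointly
  observed, so this completion is the simplest valid covariance; it
  requires `rho1^2 + rho0^2 <= 1`, which is enforced. The instrument is
  the village-level quantity `Phi(a_v)` where `a_v` is the same village
  effect that drives hours, making it village-clustered and relevant by
  construction. Default correlations are rho1 = 0.25, rho0 = 0.10,
  selection and regime coefficients of the magnitudes such surveys
  report (instrument coefficient 2.59, regime intercepts around -1).
* **Structural mode** flags work from hours, shifts latent health by
  -0.10 and latent income by +0.03 under high-intensity work (net
  coordination shift -0.035), and emits 16 raw indicator columns as
  noisy monotone transforms of the latent levels. The intensities were
  calibrated once so the *observed* pipeline output matches the
  descriptive statistics of the motivating survey: a balance rate near
  0.15 and a high/low-intensity gap near 0.03. Potential outcomes are
  the balance classes computed from the latent levels under each
  regime; the observed entropy-weighted CCD is a noisy version of this
  latent truth, so structural-mode "true ATT" and the pipeline estimate
  agree in sign and order of magnitude, not to sampling precision.
* **Not emulated:** survey weights and multi-stage PPS sampling, the
  joint covariate distribution (only marginals are matched), item
  nonresponse, and any real geography behind the region labels.
  Passing tests on synthetic data therefore demonstrate internal
  consistency of the estimators under a correctly specified DGP, not
  robustness to the misspecifications real survey data carry.

## Problem sizes used in the checks

The test suite uses 200 model-based replications at n ~ 5,000 for
parameter recovery and coverage, one n ~ 10,000 draw for ATT recovery
against the potential-outcome ground truth, and a 60-village fixture
for byte-level reproducibility of the full pipeline. The acceptance
script runs one survey-scale (497-village) model-based study with
60-replicate bootstraps and a 300-village structural pipeline run.

## Known limitations

* The FIML Hessian is obtained by differencing the analytic score;
  for very flat likelihoods (weak instrument, tiny subgroups) the
  sandwich can be ill-conditioned — the Wald test raises on a singular
  block rather than reporting a misleading statistic.
* The bootstrap refits are warm-started at the full-sample estimate;
  with very few villages the resampled likelihood can be multimodal and
  occasional replicate failures are expected (they are skipped and
  counted).
* Entropy weights are recomputed within any refit sample; weights from
  the full sample are not frozen and carried into subsamples.
* ATU and ATE are deliberately not reported, though the counterfactual
  machinery would permit them.
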