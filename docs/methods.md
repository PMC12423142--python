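# Methods

This note documents the statistical model, the sampler, the synthetic-data
generator and the evaluation protocol implemented in `poppred`, including
the numerical choices made where the design was genuinely open.

## Model

The joint density factorizes as

```
p(y, z, Lambda, mu, sigma, beta) =
    prod_i [ prod_t N(y_it | a_i + g_i e^{-r_i m_it}, eps_i^2) ]        # process
  x prod_i Bernoulli(z_i | logistic(b0 + B_lam Lambda_i + B_x x_i))^{obs_i}
  x prod_i N(a_i | mu_a, sigma_a^2) N(g_i | ...) N(r_i | ...)
           TN_{>0}(eps_i | mu_eps, sigma_eps^2)                          # hierarchy
  x prod N(mu | 0,1) N+(sigma | 0,1) N(beta | 0,1)                      # hyperpriors
```

where `obs_i` is 1 when person *i*'s outcome is observed and 0 otherwise.
Choices worth calling out:

* **Latent predictors enter the logistic on their raw scale** (seconds,
  per-day). This is required for the counterfactual risk chain computed
  from group-level means and SDs to reproduce; it also means coefficient
  magnitudes are per-unit-of-marker, not per-SD.
* **`a_i`, `g_i`, `r_i` are unconstrained.** A negative learning rate
  encodes worsening performance across the burst and is a legitimate
  state; only `eps_i` must be positive for the likelihood to exist.
* **The eps truncation is properly normalized.** Each person contributes
  `-log Phi(mu_eps / sigma_eps)` to the hierarchical prior. This term is a
  function of the hyperparameters, not a constant: dropping it makes the
  model fit an untruncated normal to positive-only values and biases
  `sigma_eps` downward by ~10% at the default generating values, which is
  detectable in recovery tests. With the term included, interval coverage
  of the group-level parameters is calibrated.
* **Missing outcomes** are represented explicitly (`OutcomeRecord(None)`),
  never imputed; a missing outcome removes exactly one Bernoulli factor.

## Sampler

No gradient-based probabilistic-programming backend is used; the sampler
(`poppred.inference`) is a vectorized Metropolis-within-Gibbs scheme whose
only contract is to draw from the joint posterior above:

1. **Person-level markers.** Component-wise Gaussian random-walk
   Metropolis, proposed for all persons simultaneously (one vectorized
   accept/reject per marker), with per-person, per-marker log proposal
   scales adapted during warmup toward 0.44 acceptance. A second,
   joint-per-person move proposes all four markers at once using a
   per-person proposal covariance accumulated online (Welford) during
   warmup and refreshed every 25 iterations; this handles the strong
   within-person correlation of (a, g, r). Proposals violating a
   positivity constraint are rejected outright, which together with the
   renormalized prior implements the truncated target.
2. **Recentering moves.** For each marker dimension, a translation move
   (shift all `lam_ij` and `mu_j` together) and a scale move (rescale the
   deviations and `sigma_j` together, with log-Jacobian `(n+1) zeta`).
   The hierarchical kernel is invariant under both, so acceptance depends
   only on the likelihood, hyperpriors and truncation term. These moves
   decouple the group-level parameters from the person-level markers,
   which is otherwise the slowest direction of the posterior.
3. **Group means.** Exact conjugate Gibbs draws; for the truncated
   dimension the `-n log Phi(mu/sigma)` term breaks conjugacy and the
   conditional is slice-sampled around the conjugate kernel.
4. **Group SDs.** Univariate slice sampling on (0, inf).
5. **Structural coefficients.** Component-wise slice sampling in a
   centered parameterization: predictor columns are centered at their
   sample means over outcome-observed rows and the intercept re-absorbed,
   removing the dominant intercept/slope correlation; the N(0,1) priors
   are evaluated on the original coefficient scale through the (linear,
   unit-Jacobian) back-transform.

Slice sampling (stepping-out + shrinkage) needs no tuning; the only
adapted quantities are random-walk scales, adapted only during warmup so
the post-warmup chain is a fixed Markov kernel. Chains are seeded from a
`SeedSequence` spawn of the configured seed; identical configuration gives
bit-identical draws.

**Thinning.** `McmcConfig.thin` keeps every thin-th post-warmup iteration.
Random-walk updates carry more autocorrelation per iteration than the
gradient-based samplers this protocol was designed around; thinning lets a
"500 retained draws" budget deliver a comparable effective sample size at
proportional (still small) runtime. Recovery tests run 2 chains x 500
warmup x 500 retained draws with `thin=4` (~20 s per fit at 150
participants x 16 days on one CPU).

**Diagnostics.** Split R-hat (rank-normalized) and bulk ESS are computed
with arviz; the default pass threshold is R-hat < 1.03 with an ESS warning
below 300. A single chain yields an undefined R-hat, reported as NaN and
flagged as failing rather than skipped.

**Process-model fit.** `variance_explained` reports
`1 - SS_resid / SS_total`, with fitted values the posterior-mean model
curve per person-day and `SS_total` taken about the grand mean pooled over
all person-days. "Akin to an R^2" admits several definitions; this one is
fixed and documented so the statistic is well-defined on any dataset.

## Synthetic cohorts

`generate_dataset` composes four seeded stages (covariates, markers,
outcomes, time series) from a single `SeedSequence`, so the cohort is a
deterministic function of the configuration. Defaults emulate the cohort
the model was developed on:

| quantity | default | note |
|---|---|---|
| participants / days | 316 / 16 | measurement-burst design |
| age | 77.54 (SD 4.98), standardized within-sample | |
| sex | 33% male (dummy 1 = male) | |
| education | 15.09 (SD 3.55) years, standardized | |
| race / ethnicity | P(Black) = 0.43, P(Hispanic) = 0.13 | collapsed dummies matching the cohort margins |
| marker hierarchy | group means/SDs at the reported estimates | `EAS_HYPERS` |
| structural coefficients | reported posterior means | `EAS_COEFFS` |

`r_i` and `eps_i` are rejection-sampled to be positive (improving,
well-defined curves); generated response times are redrawn at values <= 0;
redraw counts are logged. Standardization of age and education is
within-sample, like the analysis of a fixed cohort. The implied outcome
prevalence at the defaults is ~29%.

What the generator does **not** emulate: session-level structure (the ~6
daily sessions and trial counts are collapsed into the daily-mean residual
SD `eps_i`), missed sessions or other missingness in the behavioral data,
outcome misclassification noise, and any non-exponential shape of real
learning curves. Passing recovery tests therefore demonstrate that the
estimation machinery is correct and calibrated *under the model*, not that
the exponential model is adequate for any particular empirical dataset.

Two generator/model mismatches are deliberate and visible in recovery
tests: the generator truncates `r_i > 0` while the model leaves `r_i`
unconstrained (the realized population of a truncated normal has a
slightly higher mean and smaller SD than its parameters), and the
structural intercept's generating value (-2.80) sits far in the tail of
its N(0,1) prior, so at small n its posterior shrinks noticeably toward
zero. Both effects are properties of the stated study conditions, and the
pooled 95% interval coverage across seeds stays above the 85% criterion
with them included.

## Evaluation protocol

* **Counterfactual risk chain.** Baseline profile: markers at group means,
  standardized covariates at 0, dummies at reference. Shifts are applied
  cumulatively and written in SD units for markers ("asymptote +1sd") or
  as covariate assignments ("race_black = 1"). From the reported
  estimates the chain is 0.2497 -> 0.3719 -> 0.4903 -> 0.5957. The first
  three round to the published .25/.37/.49; the fourth rounds to .60
  against a published .59 — plugging rounded point estimates into the
  logistic cannot reproduce a value that was computed from unrounded
  posterior draws (averaging the logistic over the posterior pulls values
  toward 0.5). The package reports the plug-in value.
* **Cross-validation.** Outcome-stratified folds (permute within class,
  deal round-robin, negatives continuing where positives end), so fold
  sizes and per-fold positive counts each differ by at most one. Each fold
  is refitted from scratch with the fold's outcomes missing; the held-out
  prediction is the posterior mean of `logistic(eta_i)` over draws — not
  the logistic of the posterior-mean linear predictor — so marker and
  coefficient uncertainty propagate. Per-fold seeds derive from the run
  seed and fold index.
* **Comparators.** "Manifest only": Bayesian logistic regression on the
  five covariates with the same N(0,1) priors and folds. "Manifest +
  latent descriptors": the same joint architecture with the learning curve
  replaced by `y_it ~ N(m_i, s_i^2)` and structural weights on (m_i, s_i).
* **ROC/AUC.** Mann-Whitney AUC with half-credit ties and the full
  threshold sweep (scikit-learn, `drop_intermediate=False`); the
  trapezoidal area under the returned curve equals the AUC identically.
  The bootstrap CI resamples participants within outcome class (2000
  percentile replicates at the 95% level by default), so both classes are
  always present in a replicate.

## Problem sizes used by the test suite

Recovery: 5 cohorts of 150 x 16 at the default generating values, 2 chains
x 500/500 thinned by 4. Cross-validation: one cohort of 316 x 16, 10
folds, 3 variants, 2 chains x 300/300 thinned by 2 per refit. The full
suite runs in about 6 minutes on a single CPU; full-scale analyses (4
chains x 2500/2500) take minutes per fit and are exposed through the CLI
defaults.

## Known limitations

* The sampler is tuned for cohorts of hundreds of participants and tens of
  occasions; very long series or very weak per-person information would
  favor a gradient-based sampler.
* R-hat/ESS are necessary, not sufficient, convergence evidence; the
  recovery suite provides the stronger end-to-end check.
* The descriptor comparator shares the joint-estimation machinery, so its
  "no process model" label refers to the generative model for the time
  series, not to a two-stage estimation shortcut.
* Directional probabilities use strict inequalities; draws exactly zero
  (measure-zero in practice) count toward neither side.
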