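# Methods

## Model and estimation

The pooling model is the bivariate binomial-normal ("exact binomial")
random-effects model: per study, counts are binomial given a latent
(logit sensitivity, logit specificity) pair drawn from a bivariate normal
with means (mu_A, mu_B), SDs (sigma_A, sigma_B) and correlation rho. The
within-study likelihood is the exact binomial -- no continuity correction
or normal approximation enters the likelihood, so studies with zero cells
or extreme rates contribute correctly.

Each study's marginal likelihood is a 2-D integral evaluated by **adaptive
Gauss-Hermite quadrature** (default 21 nodes per dimension): the grid is
re-centred at the study's posterior mode (found by a damped Newton
iteration on the strictly concave integrand) and re-scaled by the local
curvature's inverse Cholesky factor. Adaptive centring is essential: a
large study's integrand is a sharp peak that can sit many prior SDs from
the population mean, where a fixed prior-centred grid of practical size
has no nodes. Binomial terms are accumulated in log space and the node sum
uses log-sum-exp, so likelihood evaluation is overflow-safe up to arm sizes
of 10^6 and beyond.

Maximisation is quasi-Newton (L-BFGS-B) on the unconstrained transformed
scale (mu_A, mu_B, log sigma_A, log sigma_B, atanh rho), started from
moment estimates of the continuity-corrected observed logits, with up to
three deterministically jittered restarts; a successful optimizer status is
preferred over a marginally lower objective from a failed run. Wide bounds
(|atanh rho| <= 7, sigma in [1e-6, 50]) keep degenerate panels finite;
fits stopping there are flagged `boundary` rather than silently clipped.
In practice sigma estimates below ~1e-4 are indistinguishable from zero
heterogeneity (the profile is flat in log sigma), and that is the flag's
threshold. Estimation is ML, not REML: the AUC/SROC mapping and the
likelihood-ratio meta-regression test are then self-consistent.

The estimator covariance is the inverse of a central-difference Hessian of
the negative log-likelihood at the optimum (step 1e-4 relative).
Confidence intervals are 95% Wald: logit scale for proportions, log scale
for PLR/NLR/DOR, with closed-form delta-method gradients in the
(mu_A, mu_B) block.

## Derived quantities

- **Summary measures**: sens = invlogit(mu_A), spec = invlogit(mu_B),
  PLR = sens/(1-spec), NLR = (1-sens)/spec, DOR = exp(mu_A+mu_B). The
  identity DOR = PLR/NLR holds to machine precision by construction.
- **SROC**: the Rutter-Gatsonis parameterisation,
  Lambda = s mu_A + mu_B/s, beta = ln(sigma_B/sigma_A),
  Theta = (s mu_A - mu_B/s)/2 with s = sqrt(sigma_B/sigma_A). The curve
  `logit(TPR) = mu_A + (sigma_A/sigma_B)(logit(FPR) + mu_B)` passes
  through the summary point exactly. The ratio-of-SDs slope (rather than a
  covariance-based regression slope) was chosen because it matches the
  convention of the established DTA software family and guarantees
  summary-point pass-through. AUC is the trapezoidal integral over the
  **full** FPR range [0, 1] on a 2001-point grid (restricted ranges via
  `fpr_range`); the slope is capped at 1e3 when sigma_B sits at its floor.
- **Confidence/prediction regions**: Wald ellipses on the (mu_A, mu_B)
  plane (chi-square(2) quantile), the prediction ellipse adding Sigma,
  both mapped through the inverse logit.

## Classical statistics

- **Cochran Q / I-squared** per margin on observed logits with inverse
  binomial-variance weights (1/tp + 1/fn, resp. 1/tn + 1/fp); a 0.5
  continuity correction is added to all four cells only when a cell is
  zero, and only for these descriptive statistics -- never the likelihood.
  I2 = max(0, (Q - df)/Q) x 100.
- **Threshold effect**: Spearman rank correlation between sensitivity and
  the false-positive rate (positive r suggests a threshold effect, the
  Meta-DiSc convention; `pair="sens_spec"` flips the sign convention).
  Two-sided p from the t approximation on n-2 df.
- **Deeks' test**: WLS of lnDOR on 1/sqrt(ESS), ESS = 4 n1 n2/(n1+n2),
  weights ESS; t for the slope on n-2 df. On the bundled panel this gives
  |t| = 1.21, p = 0.239; the statistic's sign is determined by the data
  under this standard orientation.
- **Fagan**: post-test odds = pre-test odds x LR, reported as
  probabilities; default pre-test probability 0.20.
- **Scattergram**: confirmation line PLR > 10 and exclusion line
  NLR < 0.1 (the conventional clinical thresholds); boundary values fall
  to the weaker category.

## Subgroups and meta-regression

Dichotomies follow the bundled study panel's design: prospective vs
retrospective; <=50 vs >50 patients; <=65 vs >65 years; 1.5 vs 3.0 T;
b = 2000 ("high") vs > 2000 ("ultra-high"); ADC vs visual assessment.
Subgroup levels are refitted with the full model; levels with fewer than 4
rows return point estimates only (variance components are then unreliable)
and levels under 2 rows are skipped with a log entry.

Meta-regression adds the covariate additively to both latent means (two
extra parameters) and tests with the likelihood ratio on chi-square(2);
variance explained per margin is 100 max(0, (s2_base - s2_cov)/s2_base).
At small K (tens of studies) the ML LR test is mildly anticonservative
(observed type-I ~ 0.10 at K <= 40 in our simulations, near-nominal at
K = 100); interpret borderline p-values accordingly.

## Influence and outlier diagnostics

Cook's distance per study is d' I(theta_hat) d on the transformed
5-parameter scale, d the leave-one-out parameter shift and I the full-fit
observed information; the top decile within a panel is flagged
influential. Outlier residuals are **randomized quantile residuals against
the marginal (prior-predictive) count distribution** -- the binomial CDF
integrated over the logit-normal random effect by 41-node Gauss-Hermite
quadrature -- with |r| > 2 on either margin flagged. Residuals at the
empirical-Bayes point predictions were deliberately rejected: EB modes
track each study's own counts at realistic arm sizes, so such residuals
are near zero even for gross outliers. The randomized stream is seeded
(default 0) for reproducibility. Bivariate normality is assessed by
pairing sorted squared Mahalanobis distances of the EB effects with
chi-square(2) quantiles at plotting positions (i - 0.5)/K.

Both flag thresholds (|r| > 2, top-decile Cook's d) are conventional,
documented defaults, not calibrated decision rules.

## Synthetic-data generator

`SyntheticConfig` defaults encode the reference simulation conditions:
K = 30 studies, mu_A = 1.4, mu_B = 1.8 (sens/spec approx. 0.80/0.86,
near the bundled panel's fit), sigma_A = sigma_B = 0.5, rho = -0.4, and
arm sizes log-uniform on [30, 600], mimicking the bundled panel's spread.
Optional mechanisms: an additive covariate shift on the means for a random
subset of studies; a publication-selection rule with inclusion probability
expit(strength (lnDOR - center)); and a threshold mechanism adding a
per-study cutoff t ~ N(0, strength^2) to logit sensitivity and
subtracting it from logit specificity. The cutoff stream is a separate
child of the seed, so strength 0 is byte-identical to the plain generator.
Latent draws are exposed on the returned panel for testing.

What the generator does **not** emulate: within-study correlation of the
two margins (patients contributing to both arms), covariate-dependent arm
sizes, non-normal random effects, and multi-arm studies sharing a latent
effect (the bundled panel's multiple-b-value rows are treated as
independent, as in the source analysis). Passing simulation tests
therefore validate the estimation machinery under the model's own
assumptions, not robustness to their violation.

## Problem sizes and numerical choices

The bundled-panel pipeline (fit, subgroups, meta-regression, 29
leave-one-out refits) runs in well under a minute on one CPU. Simulation
suites use 200 replicates at K = 30 for recovery/coverage, 50 replicates
at K = 100 for type-I behaviour, and 30 replicates at K = 100 for
threshold-test power, with 7-10 quadrature nodes (estimates at these node
counts agree with 21-node fits to ~1e-6 on these panel sizes).

## Known limitations

- Wald intervals on transformed scales can undercover when a variance
  component sits near zero or |rho| near 1 (flagged `boundary`).
- The five-row "printed percentage vs printed counts" inconsistencies in
  the bundled panel are inherited from the source tables; counts are
  authoritative and the discrepancies are documented in the test suite.
- Meta-regression supports one dichotomous covariate at a time; no
  continuous moderators.
- The influence analysis refits K times per call; for K in the hundreds
  prefer a subsample or accept the linear cost.
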