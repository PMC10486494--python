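# Methods

`seroprog` models the joint distribution of five longitudinal serological
markers and survival in a two-arm mHSPC trial cohort, and scores the
resulting dynamic predictions. This note records the model, the synthetic
data-generating process, the numerical machinery, and the design decisions
taken where more than one defensible choice existed.

## 1. Joint model

**Longitudinal sub-model.** Each marker k (Hb, NLR, PLR, LMR on their
native scales; PSA on log(PSA+1)) follows a linear mixed model in time t
(months from randomisation):

    y_ikj = m_ik(t_j) + e_ikj,    e_ikj ~ N(0, sigma_k^2)
    m_ik(t) = beta0_k + b0_ik + (beta_t_k + b1_ik) t
              + beta_arm_k arm_i + beta_armt_k arm_i t + beta_base_k x_ik

with `(b0, b1) ~ N(0, D_k)`, `D_k` unstructured 2x2, and `x_ik` the
recorded baseline value (modelling scale). The *response* consists of the
post-baseline measurements only: the t = 0 measurement is, by definition,
the baseline covariate, and entering the same number on both sides of the
model makes its residual degenerate. The t = 0 rows remain part of the
data tables (they drive the eligibility screen).

**Survival sub-model.** Proportional hazards on nine baseline covariates
(ECOG >= 1, skeletal lesions >= 10, liver metastasis, N1 nodal stage,
Gleason 9–10, baseline Hb, log baseline PSA, worst pain 0–10 as a
continuous per-point covariate, treatment arm), with a piecewise-constant
baseline hazard on six segments whose knots sit at equal quantiles of the
observed event times. Endpoints: OS (any death) and PCSS (prostate-cancer
death; other deaths censored). Ties, which can only arise from rounded
inputs, are handled by lifelines' Efron correction in the Cox sub-model.

**Link.** Current-value association: the log hazard at t adds
`sum_k alpha_k m_ik(t) / s_k`, where `m_ik(t)` is the full linear
predictor (fixed and random parts, including the baseline-value term) and
`s_k` the reporting scale — 1 g/dL Hb, 1 NLR point, 100 PLR points, 5 LMR
points, 1 log-PSA unit — so `exp(alpha_k)` is directly the reported hazard
ratio. The multivariate model deliberately retains baseline Hb and log
baseline PSA in the survival sub-model while also modelling their
trajectories; the collinearity between a marker's baseline covariate and
the baseline-anchored part of its current value is resolved by the
within-subject dynamics and is part of the replicated design.

**Likelihood.** Because the longitudinal sub-model is Gaussian, each
subject's likelihood factorises exactly into (i) the closed-form marginal
Gaussian likelihood of the marker series and (ii) the expectation of the
survival factor under the closed-form Gaussian posterior of the random
effects given that series. Only (ii) needs numerical integration:

- one marker: pseudo-adaptive Gauss–Hermite quadrature centred at the
  per-subject longitudinal posterior (5 nodes per dimension, 25 total;
  raising the order to 15 changes a converged log-likelihood by < 1e-4 on
  the test problems);
- several markers: scrambled-Sobol quasi-Monte-Carlo normal draws (32 by
  default) from the block-diagonal cross-marker posterior, held fixed
  across likelihood evaluations (common random numbers), with cross-marker
  random-effect independence assumed in the integrator.

With `m(t)` linear in t and the baseline hazard piecewise constant, every
cumulative-hazard integral has the closed form
`h0_l exp(lp) (exp(C t2) - exp(C t1)) / C` per segment, computed with an
`expm1`-stable kernel and exponent clipping at +-700.

## 2. Estimation backends

- **two_stage** — per-marker longitudinal ML (own closed-form marginal,
  L-BFGS on 9 parameters), empirical-Bayes (BLUP) current-value lines,
  plugged as time-varying covariates (1-month episodes, midpoint values)
  into a lifelines `CoxTimeVaryingFitter`; the piecewise baseline is then
  profiled in closed form. Fast and approximate — it ignores the
  informative-dropout tilt on the random effects — and is used as the warm
  start, for cross-validation loops, and as a directional cross-check of
  the full likelihood.
- **full_likelihood** — maximises the marginalised likelihood above by
  L-BFGS from the two-stage start. For a single marker all 25 parameters
  (longitudinal, gamma, alpha, log baseline) move jointly; with several
  markers the survival block (gamma, alpha, log baseline) is maximised
  with longitudinal parameters held at their stage-1 ML estimates, whose
  own sampling error at the default cohort sizes is small. Wald intervals
  from a central-difference numerical Hessian.
- **bayesian_mcmc** — required for horseshoe shrinkage. An emcee ensemble
  sampler (>= 2 x dim + 4 walkers, 900 steps, 400 burn-in by default)
  targets the survival block conditional on stage-1 longitudinal ML fits,
  with random effects marginalised by the QMC rule at every evaluation.
  Priors: gamma_j ~ N(0, 2.5^2); log h0_l ~ N(-4, 3^2); alpha_k ~
  N(0, tau^2 lambda_k^2) with lambda_k ~ C+(0,1), tau ~ C+(0, tau0),
  tau0 = 1 (horseshoe on the associations only — the standard shrinkage
  target in this setting; baseline covariates stay weakly informative).
  Posterior medians are reported as HRs with equal-tailed 95% intervals;
  the `p_value` column is the two-sided posterior sign probability, and
  the table records which interval type is in use. A fully joint MCMC over
  longitudinal and survival parameters with nested 10-dimensional
  random-effect integration was rejected on computational grounds; the
  modularised posterior is the package's design choice and is labelled in
  the fit diagnostics.

The optimizer trace of accepted L-BFGS iterates is stored and must be
nonincreasing (tested). Significance in reporting tables uses the study's
strict two-sided p < 0.004 threshold.

## 3. Synthetic cohort generator

The generator emulates the data structure of a 1138-subject two-arm trial
(563 experimental / 575 control, exact allocation by permutation):

- **Baseline covariates** are drawn independently from marginals matched
  to the published cohort (normal Hb 13.2 +- 1.7 g/dL; log-normal PSA,
  NLR, PLR, LMR with medians 16.5 / 2.2 / 138 / 4.75; binary prevalences
  0.45 / 0.65 / 0.05 / 0.47 / 0.52; pain 0–10 with median 1, Q3 = 4).
  Correlations between baseline covariates are not modelled — only
  marginals are published.
- **Trajectories** follow the longitudinal sub-model exactly, with
  per-month slopes and variance components chosen to give clinically
  plausible five-year drifts (e.g. PSA declining on the log scale under
  ADT, faster in the experimental arm; blood-count ratios drifting
  slowly). The t = 0 series value equals the recorded baseline exactly.
- **Event times** come from the cause-specific prostate-cancer hazard
  `h0(t) exp(gamma'w + sum_k alpha_k (m_k(t) - ref_k)/s_k)` with a Weibull
  baseline (shape 1.3, scale 80 months), a constant other-cause hazard
  (0.0015/month), exponential random censoring (0.003/month) and
  administrative censoring at 60 months. The association is centred at
  reference marker values (`marker_ref`) so that the Weibull baseline is
  the hazard of a typical trajectory and event rates stay realistic across
  alpha scenarios; the centring constant is absorbed by any fitted
  baseline hazard and leaves all estimands unchanged. The cumulative
  hazard is integrated on a 0.05-month grid and inverted against
  -log(U) by monotone interpolation; subjects whose -log(U) exceeds
  H(60) are administratively censored. Default gamma/alpha are the
  published multivariate OS effect sizes.
- **Visits** follow the trial schedule (monthly to month 12, bimonthly
  after), truncated at the event/censoring time, with each post-baseline
  visit skipped independently with probability 0.15
  (missing-completely-at-random; informative missingness is a known
  limitation of the source analysis, not a feature of it). Simulated
  native-scale values below 0.01 are floored there with a logged warning.
- **Eligibility screen**: a baseline and at least two post-baseline values
  of every one of the five markers; exclusions are logged.

Calibration was done once at design time and frozen: Weibull scale 80 and
missingness 0.15 jointly reproduce a ~46% five-year OS event fraction and
the published median of 25 marker assessments; baseline medians land
within 10% of the published values (tested).

What the generator does **not** emulate: treatment crossover or dose
modification, radiographic progression, correlated baseline covariates,
informative visit missingness, and cross-marker random-effect correlation.
Passing recovery tests therefore show estimator correctness under the
stated model, not robustness to those real-data features.

**Recovery scenarios** (`seroprog.scenarios`) additionally set the
other-cause hazard to a negligible 1e-8/month: with a material constant
competing hazard mixed into OS, the generated OS hazard is no longer of
the proportional-hazards form whose alpha the estimator is asked to
recover (empirically a ~14% attenuation of the association at the default
setting), so the recovery estimand would be ill-defined. At n = 600 the
full-likelihood estimate retains a small finite-sample bias away from the
null (order -0.02 on the log scale for the Hb scenario, vanishing by
n = 3000); the recovery tests average ten seeds and test against twice the
Monte-Carlo standard error of that mean.

## 4. Dynamic prediction

For a subject alive at landmark t (12 or 24 months by default) with marker
history restricted to [0, t], the conditional survival is

    pi(u | t) = E_b[S(u | b, w)] / E_b[S(t | b, w)],

the expectation over the closed-form longitudinal posterior of b given the
history (500 seeded Monte-Carlo draws by default; the ratio form supplies
the survival-to-t conditioning). The trajectory beyond t extrapolates the
subject's fitted linear predictor — no post-landmark data are used,
matching the landmark design. `posterior_random_effects` exposes the
survival-tilted posterior itself via importance weights proportional to
S(t | b). Horizons beyond the largest observed event time extend the last
baseline segment and are flagged. pi(t | t) = 1 exactly; monotonicity in u
holds draw-wise; at alpha = 0 the predictor reduces to the
proportional-hazards ratio exactly (tested to 1e-6).

## 5. Evaluation

- **IPCW**: censoring distribution G by Kaplan–Meier on the scored set
  (not covariate-adjusted). Weights: events before u get 1/G(T-),
  subjects at risk at u get 1/G(u-), censored before u get 0. The left
  limit at u makes the weights robust to the administrative-censoring atom
  at the end of follow-up, where G(u) itself is 0; a subject censored
  exactly at u counts as alive at u. A horizon with no censoring support
  raises an explicit error.
- **Brier(u)**: IPCW-weighted mean squared distance between survival
  status at u and predicted survival, divided by the number of scored
  subjects; the effective (summed) weight is reported alongside.
- **Calibration (ICI/E50/E90)**: IPCW-weighted local-linear regression of
  the event-by-u indicator on cloglog(predicted risk), evaluated at each
  subject's prediction; ICI is the weighted mean absolute difference
  between smoothed observed and predicted risk, E50/E90 the weighted
  median/90th percentile. Bandwidth: 1.8 sd(x) n^(-1/5) with a Gaussian
  kernel. Sensitivity on the oracle-consistency example (n = 2000,
  predictions equal to true risks): fixed bandwidths 0.1/0.2/0.4 give ICI
  0.025/0.020/0.014, and plug-in constants 0.9/1.8 give 0.0215/0.0158;
  the density-estimation constant 0.9 is too narrow for regression
  smoothing, so 1.8 was fixed as the default. Identical predictions
  degenerate the smoother; the pooled |observed - predicted| is returned
  for all three metrics with a warning.
- **Cross-validation**: k = 5 folds stratified by the endpoint's event
  indicator with a recorded seed; each fold's model is fitted on the
  remainder, and held-out subjects still at risk at the landmark are
  scored on a horizon grid (every 3 months to 60 by default). A
  `predictor` hook lets tests inject oracle predictions to verify the
  harness adds no distortion.
- **Decision curves**: net benefit `TP/n - p/(1-p) FP/n` on a 0.01–0.60
  threshold grid, with TP/FP estimated by the same IPCW weights (the
  censoring adjustment is this package's choice; the source analysis does
  not state one) and `NB_all = prev - p/(1-p)(1 - prev)`. Thresholds at or
  above 1 are capped at 0.99 with a warning.

## 6. Known limitations

- The two-stage backend ignores informative dropout when estimating the
  random effects; it is documented as approximate and used accordingly.
- The Bayesian backend conditions on stage-1 longitudinal estimates
  (modular, "cut"-style posterior): longitudinal-parameter uncertainty is
  not propagated into the association intervals.
- Association structures other than current-value (slope, cumulative) and
  interval-censored outcomes are out of scope, as are spline trajectories;
  time is months from randomisation throughout.
- PCSS analyses censor other-cause deaths (cause-specific hazards); no
  subdistribution (Fine–Gray) modelling.
- Wald intervals at small n inherit the usual likelihood asymptotics;
  coverage at the null is verified at n = 200 to within +-5 percentage
  points of nominal, not beyond.
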