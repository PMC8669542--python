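# Methods

`camagree` analyzes agreement between two binary delirium instruments — the
long-form Confusion Assessment Method (CAM) and its 3-minute screening
derivative (3D-CAM) — scored concurrently and repeatedly on the same
patients by pairs of raters drawn from a shared rater pool.

## Model

Every analysis rests on one Bernoulli-logit mixed model per outcome column
(overall delirium or one of the four cardinal features).  For record *j* on
patient *i*, rater *r*, instrument *m*:

    y_j | u ~ Bernoulli(p_j),
    logit(p_j) = beta_0 + beta_method * 1[m = 3DCAM] + b_i + c_r + d_im,

with independent normal random effects

| term | symbol | meaning | default in the generator |
|---|---|---|---|
| patient intercept | b_i ~ N(0, s2_patient) | a patient's delirium propensity | sigma = 2.2 |
| rater intercept | c_r ~ N(0, s2_rater) | a rater's scoring leniency | sigma = 0.45 |
| patient-by-method | d_im ~ N(0, s2_interaction) | patient-specific instrument discordance | sigma = 0.3 |

`beta_method` is the conditional (subject-specific) log-odds shift of the
3D-CAM relative to the CAM; a positive value means the screening
instrument is more often positive.  Occasions within a patient are treated
as exchangeable replications — there is no occasion-level random effect,
because every downstream summary is per patient per method.

## Estimation

The marginal likelihood is maximized over (beta, log sigma) with L-BFGS-B
plus a damped-Newton polish on numeric derivatives, using:

* **adaptive Gauss-Hermite quadrature** (default order 15 for the
  one-dimensional patient block; tensor product of order 5 per dimension
  when the patient-by-method block makes it three-dimensional) whenever the
  random structure is patient-factored, so the likelihood factors over
  patients; and
* the **Laplace approximation** when crossed rater effects make the
  integral non-factorable.  On a shared fixture the two agree with
  `lme4::glmer` (nAGQ=15 and nAGQ=1 respectively) to a few times 1e-3.

Numerical choices, all exposed in `GlmmOptions`:

* variance components are optimized as log(sigma) with a floor at
  sigma = 1e-6; an estimate below sigma = 1e-2 (negligible on the logit
  scale) is reported as 0 with a `boundary` flag rather than as a
  convergence failure;
* convergence requires optimizer success and a (projected) numeric
  gradient norm below `gradient_tol` (default 1e-3 — the realistic
  precision of central-difference gradients on a log-likelihood of
  magnitude 1e2–1e3; the flag and the tolerance are both recorded in the
  fit);
* the optimization is restarted from sigma in {1.0, 0.5, 2.0} if the first
  start stalls short of the tolerance;
* the covariance of the fixed effects is the inverse numeric Hessian in
  beta at the optimum, conditional on the estimated variance components
  (the `lme4` convention), and Wald tests/CIs are normal-based on the
  natural scale;
* complete separation (a response constant within an instrument) is
  detected before fitting and raised as an error naming the instrument.

`marginal_loglik_bruteforce` re-evaluates the marginal likelihood by dense
Simpson integration over a +/-10-sigma tensor grid per patient, refusing
rater effects (non-factorable) and more than five patients.  It shares no
code with the quadrature paths and anchors the likelihood tests; with the
default grids its own refinement error is below 1e-6 for up to two active
dimensions per patient (the three-dimensional grid is coarser, ~1e-5).

## Latent summaries

Empirical-Bayes predictions are posterior **modes** (the quadrature/Laplace
centering locations), the natural by-product of the fit.  Each patient's
latent pair is

    eta_i(m) = beta_0 + beta_method * 1[m = 3DCAM] + b_i + d_im,

with rater effects at their population mean 0, carried on three scales:
linear predictor, probability p = logistic(eta), and log p.

* **Bland-Altman**: per-patient points (average, CAM - 3DCAM difference) on
  the probability or log-probability scale; mean difference with CI
  mean +/- 1.96 SD/sqrt(n) over patients (one point per patient, so
  independence is reasonable — this empirical CI is a package convention)
  and limits of agreement mean +/- 1.96 SD.  Collapsing to one latent pair
  per patient is what adjusts the analysis for repeated assessments.
* **Probability ratio**: on the log scale, exp(mean difference) estimates
  P(CAM+)/P(3DCAM+).  Reported values are rounded to two decimals and the
  inverse ratio is the reciprocal of the *rounded* forward value — the
  convention that makes a printed ratio of 0.36 invert to 2.78 rather than
  exp(1.03) = 2.80.  Unrounded values are kept alongside.
* **Scale policy**: overall delirium and altered level of consciousness
  are analyzed on the log scale, the other three features on the
  probability scale.  A skewness check (|g1| > 1 on probability-scale
  differences suggests the log scale) is advisory and logged, never
  auto-applied.
* **Cohen kappa**: latent probabilities dichotomized at 0.5 (tie maps to
  positive; threshold configurable), a standard 2x2 kappa over one pair
  per patient, and Landis-Koch-style labels using the bands
  "> 0.75 substantial, 0.40–0.75 moderate, < 0.40 poor" (configurable).
* **ICC**: from single-instrument fits with patient and rater intercepts,
  ICC = s2_patient / (s2_patient + s2_rater).  The logistic residual
  variance pi^2/3 is *excluded* by default — the non-patient share is
  attributed to raters — with `include_residual=True` giving the other
  common convention.  Which convention the original analyses used cannot
  be determined, so both are exposed.

### Kappa intervals

`pair_bootstrap` (default, B=2000) resamples patients' latent pairs;
`refit_bootstrap` resamples patients' raw records and refits the model per
replicate.  The pair bootstrap conditions on the fitted parameters: when
parameter uncertainty dominates (small cohorts, few occasions) it is
anti-conservative, and the refit bootstrap should be preferred — the test
suite demonstrates exactly this contrast.  Replicates with undefined kappa
(a constant instrument) are redrawn, capped at 10B attempts.

## Synthetic cohorts

`simulate_cohort` is the generative mirror of the model above.  Patient
and rater effects are shared across the overall outcome and the four
features (inducing realistic cross-outcome correlation within a patient);
each outcome has its own fixed effects and its own patient-by-method
draws.  Raters are cross-trained, so a rater has a single c_r regardless
of instrument; each occasion draws an ordered pair of distinct raters
uniformly.  Interview durations are lognormal with median/IQR targets of
8 (6–10) minutes for the CAM and 3 (2–4) for the 3D-CAM.

`study_emulating_config` fixes the realized structure at 299 patients, 471
concurrent pairs and 16 raters (occasion counts are drawn from a
distribution with mean ~1.58 on support {1..6} and deterministically
nudged to sum to 471).  No true parameter values are known for the real
cohort; the defaults (beta_0 = -2.2 for a ~25% positive rate,
beta_method = +0.7, sigma_patient = 2.2 >> sigma_rater = 0.45,
sigma_interaction = 0.3) are illustrative, chosen once to land in the
reported regime: per-instrument ICC above 0.8, the 3D-CAM more often
positive, overall latent kappa near 0.7 and above the acute-change kappa.

What the generator does **not** emulate: the CAM scoring algorithm's
logical coupling between the four features and the overall outcome (all
five columns are generated from their own marginal models), fluctuating
delirium time courses, dropout, and rater-by-instrument training effects.
Passing tests therefore demonstrate that the estimation and summarization
machinery is correct under the assumed model, not that the model captures
every feature of real assessment data.

## Experiment sizes

The simulation experiments (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use: 50 cohorts of 300 patients x 2 occasions
with 16 raters for method-effect recovery and Wald coverage; 10 null
cohorts of 150 patients for the shared-latent null (the Monte-Carlo SE
across replicates is the right yardstick there, because within one run the
latent differences are a near-deterministic function of the estimated
method effect); three fixtures of 3–5 patients for the likelihood-oracle
comparison; and one full 299/471/16 study-emulating run.

## Known limitations

* Laplace accuracy: with two binary observations per patient per
  instrument, crossed-design fits inherit the usual small-cluster Laplace
  bias; the recovery experiment bounds its practical size (mean absolute
  error ~0.14 on a true effect of 0.7).
* Wald inference near a variance boundary is approximate.
* The per-feature analyses refit the same random structure per feature;
  no multivariate model links features.
* Only two instruments are supported, and only the logit link.
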