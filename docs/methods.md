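# Methods

## Scope

`rppdecay` models the decay of residual pneumoperitoneum (RPP) volume after
robotic-assisted laparoscopic prostatectomy, as measured by CT volumetry on
post-operative days (PODs) 3, 5 and 7. The original patient-level data are
not public, so the package pairs the model with a synthetic cohort
generator whose defaults are calibrated to the published cohort summaries;
every downstream stage (descriptives, fit, prediction, recovery) is
testable without any download.

## Response transform and censoring

Volumes are analysed as `y = log(V_mL + 1)`. The one-unit shift keeps the
transform defined at 0 mL and maps the minimum back to zero. The day
covariate is centred at the first scan (`x = POD − 3`), so a patient's
intercept is their expected log-volume at the first CT.

A recorded 0 mL is treated as a left-censored reading: the latent y lies
at or below `c = log(detection_limit + 1)`. The volumetric detection
threshold of the segmentation software is not published; the package
default is 0.05 mL and it is configurable everywhere. Because the
back-transform floors at zero, the model intrinsically assigns the
sub-threshold mass `P(y < c)` to exact zeros.

## Hierarchical model

For observation *i* of patient *j*,

    y_i ~ Normal(alpha_j + beta_j * x_i + g(group_i), sigma_y^2)
    (alpha_j, beta_j) ~ BVN((mu_alpha, mu_beta), Sigma_re)

with `Sigma_re` parameterized by `sigma_alpha`, `sigma_beta` and the
correlation `rho`, and `g` the BMI-stratum fixed effect (WHO cutoffs:
normal < 25, overweight [25, 30), obese >= 30 kg/m²; the source cohort
uses these three strata without stating cutoffs).

**Identifiability.** A population intercept alongside all three stratum
dummies is over-parameterized, so the default *reference coding* fixes the
normal-weight effect at zero; `mu_alpha` is then the normal-weight POD-3
mean. A `full_dummy` mode retains all three dummies and relies on the
shrinkage priors for soft identification; only contrasts (e.g.
`gamma − eta`) are well determined there.

**Priors** (none are published; these are the package's choices, weakly
informative and scale-appropriate for log-mL data, where the plausible
range of y is roughly [0, 8]): fixed effects ~ Normal(0, 5²); the three
SDs ~ half-Normal(2.5); `rho` ~ LKJ(2), i.e. density ∝ (1 − rho²).

## Likelihood and sampler

The patient effects are integrated out analytically. Each patient's scan
vector is multivariate normal with covariance `Z Sigma_re Z' + sigma_y² I`
(Z the per-patient [1, x] design). Censored components contribute the
normal CDF of their conditional law given the exact components —
univariate in the common case (under the conditional follow-up design a
patient can have at most one censored scan, the last), multivariate CDF in
the general case. This marginal likelihood is verified in the tests
against direct 2-D quadrature of the random-effects integral to 1e-8 and
against the closed-form multivariate normal density when nothing is
censored.

The resulting 8- (or 9-) parameter posterior is sampled with the
affine-invariant ensemble sampler (emcee), using a 0.8/0.2 mixture of
differential-evolution and snooker moves, which mix far better than the
stretch move on this correlated posterior. Scale parameters are sampled
on the log scale and `rho` through atanh, with the Jacobians folded into
the prior. Walkers start in a small ball around the posterior mode
(L-BFGS on the log posterior from a pooled least-squares start). Defaults:
32 walkers, 2 000 warm-up and 5 000 retained iterations (~13 s for 200
patients on one CPU, effective sample sizes in the thousands). Convergence
is gated on split-chain R-hat < 1.01 across walkers; a failed gate flags
the result and warns — downstream prediction refuses non-converged draws
unless forced. A caveat inherent to ensemble samplers: walkers are
interacting, so the across-walker R-hat can understate non-convergence if
the whole ensemble is stuck in one region; the mode-based initialization
makes this unlikely for this unimodal posterior.

## Posterior prediction

For a new patient of a given stratum at day x, y is normal with

    mean = mu_alpha + mu_beta*x + g,
    var  = sigma_alpha^2 + 2 rho sigma_alpha sigma_beta x
           + sigma_beta^2 x^2 + sigma_y^2.

`predictive_interval` simulates, per posterior draw, a new `(alpha, beta)`
pair plus residual noise, back-transforms with the zero floor, and takes
empirical quantiles (default 400 000 samples); the closed-form law above
is its oracle at fixed parameters. `make_credible_table` tabulates the
3 strata × PODs 3–7 grid. Days before POD 3 extrapolate outside the
fitted design and are refused by default.

A structural note: with a negative mean slope the *median* predictive
volume always decays, but the *upper* 97.5% limit decays only while the
mean decay dominates the growth of the between-patient slope spread
(roughly `|mu_beta| > 1.96 sigma_beta` over the tabulated range). The
fitted reference calibration is in that regime over PODs 3–7; a fit with a
very uncertain slope spread need not be.

## ROPE equivalence testing

Parameter "significance" uses the region of practical equivalence: the
95% highest-density interval is compared with ±0.1 reference SDs around
zero — reject (disjoint), accept equivalence (contained), undecided
(overlap). The reference SD defaults to the SD of all non-censored
transformed volumes pooled across PODs (the package's reading of the
"general population" spread on the model scale); it is an explicit
argument, so any other reference can be supplied. The decision is
invariant to jointly rescaling draws and reference SD.

## Synthetic cohort generator

The generator draws exactly from the hierarchical model above, plus:

* **Demographics** as independent truncated normals matched to the
  published means/SDs (age 66.2 ± 6.7 y; height 177.2 ± 6.1 cm; BMI
  26.59 ± 4.1 kg/m²; operative duration 302.4 ± 43.4 min; insufflation
  278.9 ± 42.3 min; total gas 971.45 ± 426.2 L). Locations are shifted so
  the *truncated* means match exactly. Weight is derived as
  `BMI × height²`, so the BMI law is exact by construction; no claim is
  made of matching the real covariate covariance. Two of 31 patients are
  flagged not manually decompressed, mirroring the source cohort; the
  flag is carried but never modelled (n = 2 supports no inference).
* **Zeros** from two mechanisms: detection-limit censoring of the latent
  volume, plus an explicit per-POD zero-inflation probability
  (non-decreasing across PODs in the default calibration) representing
  genuinely resolved pneumoperitoneum. The published data cannot
  distinguish the two.
* **Follow-up rules**: `conditional` (the study design — later scans only
  while gas was still visible; this missingness depends only on recorded
  censoring events, so the fitted likelihood remains valid), `complete`,
  and `independent_missing` (each row dropped independently), the latter
  because the published per-day patient counts (28 at POD 5 but 29 at
  POD 7) cannot arise from a strictly conditional rule.

Degenerate (zero) spreads are deliberately allowed in the generator
config: they turn noise sources off, which the noise-free construction
check and the ANOVA null simulations rely on. The fitted model's
parameters remain strictly positive.

### Default calibration

The frozen defaults (`defaults.yaml`) were obtained by moment-matching
large common-random-number simulations (Nelder-Mead, 400 000 patients) to
the published summaries: POD-3 mean 37.6 mL and median 9.58 mL, POD-5
mean 19.85 mL, zero-RPP fractions 3.2% (POD 3) and 32.3% (by POD 7,
counting earlier resolution as zero), and the BMI distribution. The
calibration was constrained to `rho >= 0` (the source describes higher
starting volumes going with *slower* resolution) and to a clear
obese-below-overweight-below-normal intercept ordering. The result:
normal-weight POD-3 log-mean 4.109 with stratum effects −2.221
(overweight) and −2.883 (obese) — a ~9× / ~18× volume reduction, matching
the pattern of the published reference table — slope −0.375/day,
`sigma_alpha` 0.831, `sigma_beta` 0.248, `rho` 0.021, `sigma_y` 0.420,
and small zero-inflation probabilities (0.03%, 0.19%, 0.37%).

### What the generator does not reproduce

The published **POD-7 median of 0.09 mL is jointly incompatible with the
POD-5 mean of 19.85 mL** under this generative family — under *any*
parameter values, not merely the defaults. A median of 0.09 mL with only
32.3% exact zeros requires ~18% of patients in the sliver between the
detection limit and ~0.13 mL, i.e. a day-7 log-scale spread of ~0.2;
but the day-5 spread needed to produce a 19.85 mL mean alongside a
~1.4 mL median is ~2, and the per-day variance
`s²(x) = sigma_alpha² + 2 rho sigma_alpha sigma_beta x + sigma_beta² x² + sigma_y²`
is convex in x, so the day-7 spread can never fall below the day-5 spread
by that much (the extreme `rho → −1` funnel that minimizes day-7 spread
also caps day-5 spread at `sigma_alpha/2` and contradicts the positive
intercept-slope relation seen in the data). The published values are
empirical statistics of 28–29 patients with single extreme outliers
(maxima above 200 mL) and need not be jointly attainable by any smooth
population law. The default calibration therefore matches the POD-3
mean/median, POD-5 mean, both zero fractions and the BMI mean tightly,
and its POD-7 median falls near 1.5 mL; the corresponding acceptance
check is expected to fail and is left failing rather than distorting the
generator into a degenerate regime. More generally, real volumetry data
would bring quantized small readings, covariate-correlated decay rates,
and measurement artefacts none of which the generator emulates — passing
tests validate the *machinery*, not clinical transferability.

## Descriptive layer

* Summaries use linear-interpolation ("type 7") quantiles; `n` counts
  available values per variable. Patients whose scans stopped after an
  earlier zero are imputed as 0 mL at later days for summaries and zero
  fractions (that is how a resolved patient logically enters a
  gas-free-patient count); rows missing for other reasons stay missing.
* The ANOVA is one-way across PODs on log-shifted volumes, available-case
  (the published analysis states an F-test without specifying scale or
  repeated-measures structure). Its type-I error is validated on null
  simulations with patient heterogeneity off, because with random effects
  a one-way F-test on repeated measures is anticonservative by
  construction — the validation shows the implementation is a correct
  F-test, not that the design's correlation structure is handled.
  The degenerate all-equal input returns F = 0, p = 1.
* Correlations default to Pearson (Spearman available given the heavy
  skew), pairwise-complete over demographics, operative data and per-POD
  volumes; constant variables yield flagged NaNs, never silent zeros.

## Parameter recovery

`recovery_experiment` simulates cohorts at known parameters (zero
inflation off, so the generating law is exactly the fitted model),
refits, and reports per-parameter bias and 95% central-interval coverage;
non-converged replicates are flagged and retained. The default uses 200
patients — at the published cohort size of 31 the variance parameters are
weakly identified, and a `--paper-scale` mode demonstrates exactly that
wider uncertainty. Twenty replicates at n = 200 (the shipped experiment,
~4 minutes on one CPU) give ≥ 90% coverage for the population intercept,
slope and residual SD and slope bias well under 0.05/day.

## Numerical choices and edge cases

* All randomness flows from explicit integer seeds (NumPy `SeedSequence`
  spawning per stage/replicate); identical configs reproduce cohort CSVs
  byte-for-byte and identical posterior summaries.
* Multivariate normal CDFs beyond one censored dimension (possible only
  outside the conditional design) fall back to SciPy's `multivariate_normal`
  with a 1e-300 floor before the log.
* The batched (across-walker) likelihood evaluation is bit-checked against
  the scalar path in the tests; both paths reject non-PSD covariances with
  `-inf` rather than raising inside the sampler.
* `pytest` runs the full suite in ~5 minutes on one CPU; the heavy pieces
  are the 20-replicate recovery and one 200-patient reference fit.
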