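# rppdecay

Statistical modelling of **residual pneumoperitoneum (RPP)** — the CO₂ gas
that remains in the abdomen after laparoscopic surgery — for cohorts of
robotic-assisted laparoscopic prostatectomy (RALP) patients scanned by CT on
post-operative days (PODs) 3, 5 and 7.

Free intra-abdominal air on a post-operative CT is the hallmark sign of a
bowel injury, but after laparoscopy it is usually just leftover insufflation
gas. Knowing how much residual gas is *expected* on a given day, for a given
body habitus, helps radiologists and surgeons decide whether a finding is
alarming. This package provides, for analysts working with such cohorts:

* a **synthetic cohort generator** calibrated to published cohort summaries
  (volumes decaying near-exponentially, a rising fraction of gas-free
  patients, BMI-dependent volumes, and the conditional follow-up design in
  which later scans happen only while gas is still visible);
* a **Bayesian hierarchical censored log-linear decay model** with
  correlated patient-level intercepts and slopes and BMI-stratum fixed
  effects;
* **posterior-predictive credible tables** (the clinician-facing
  BMI-group × POD reference grid), **ROPE equivalence tests**, a
  descriptive layer (summary table, one-way POD ANOVA, correlation matrix,
  zero-RPP fractions), and a seeded, reproducible pipeline CLI.

## The model

Volumes are shifted and log-transformed, `y = log(V_mL + 1)`, so that 0 mL
maps to y = 0, and the day covariate is centred at the first scan,
`x = POD − 3`. For observation *i* of patient *j*:

```
y_i ~ Normal( α_j + β_j·x_i + γ·normal_i + δ·overweight_i + η·obese_i ,  σ_y² )

(α_j, β_j) ~ BVN( (μ_α, μ_β),  [[σ_α², ρσ_ασ_β], [ρσ_ασ_β, σ_β²]] )
```

A recorded 0 mL is **left-censored**: the latent y is only known to lie at
or below `c = log(detection limit + 1)`. Under the default reference coding
the normal-weight effect γ ≡ 0, so μ_α is the normal-weight mean log-volume
at POD 3 (a soft-identified full-dummy coding is available as an option).

The fit integrates the patient effects out analytically — each patient's
scan vector is multivariate normal, censored components entering through
conditional normal CDFs — leaving an 8-parameter posterior that is sampled
with an affine-invariant ensemble MCMC (differential-evolution moves),
with split-chain R-hat < 1.01 as the convergence gate. Priors are weakly
informative: Normal(0, 5²) on fixed effects, half-Normal(2.5) on SDs, an
LKJ(2) prior on ρ.

For a *new* patient of a given BMI group at day `x`, y is normal with

```
mean = μ_α + μ_β·x + group effect
var  = σ_α² + 2ρσ_ασ_β·x + σ_β²x² + σ_y²
```

which is both the analytic oracle for the Monte-Carlo predictive machinery
and the basis of the credible prediction tables (back-transformed with the
`max(exp(y) − 1, 0)` floor).

## Worked example

Simulate a 31-patient cohort at the default calibration, summarize it, fit
the model, and tabulate predictive intervals:

```bash
rpp simulate --n 31 --seed 7 --out cohort/
rpp report --data cohort/ --out report/
rpp fit --data cohort/ --seed 7 --out fit/
rpp predict-table --fit fit/ --pods 3,5,7 --out pred/
```

The report prints per-variable summaries, e.g. (seed 7):

```
    variable  n     mean      sd   median  iqr_low  iqr_high
 rpp_pod3_mL 31   21.789  30.218    9.805    2.620    26.097
 rpp_pod5_mL 31    9.444  16.066    3.637    0.469     9.582
 rpp_pod7_mL 31    4.360   9.332    0.464    0.000     3.737
```

— a heavily right-skewed volume distribution decaying across scan days,
with the mean far above the median. The fit reports the posterior:

```
  parameter      mean       sd   hdi_2.5  hdi_97.5     rhat      ess
   mu_alpha  3.499570 0.258330  2.999483  4.023906 1.005147 5512.298
    mu_beta -0.430263 0.044350 -0.519318 -0.344184 1.005923 5319.206
      delta -1.694915 0.351192 -2.381134 -0.993041 1.007433 5631.396
        eta -1.727854 0.396598 -2.496951 -0.923491 1.005876 5861.354
    ...
```

`mu_beta ≈ −0.43` per day means a typical patient's (shifted) volume decays
by a factor `exp(−0.43) ≈ 0.65` per day; `delta`/`eta` say overweight and
obese patients start around `exp(−1.7) ≈ 0.18×` the normal-weight volume.
At 31 patients the overweight and obese effects are barely distinguishable
— the predictive table makes the same point on the mL scale:

```
 bmi_group  pod  lower_mL   upper_mL
    normal    3  3.149423 259.736555
    normal    5  0.847579 104.502437
    normal    7  0.000000  60.365064
overweight    3  0.000000  46.891396
     obese    3  0.000000  47.464924
    ...
```

Reading: 95% of new normal-weight patients are expected to show between
about 3 and 260 mL of residual gas on POD 3; an obese patient above
~47 mL on POD 3 is outside the expected range. Lower limits hit the 0 mL
floor as gas resolves.

`rpp all --out run/` chains every stage and writes a manifest with the
config hash and seeds; re-running a config reproduces identical outputs.
`rpp recover --out rec/` runs the parameter-recovery experiment
(simulate at known truth → refit → bias and credible-interval coverage).

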