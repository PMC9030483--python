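# Reference calibration of the synthetic cohort generator.
#
# The decay-model parameters (intercept/slope law, BMI-stratum effects,
# residual SD, zero-inflation probabilities) were frozen by moment-matching
# large simulated cohorts to the published cohort summaries: POD-3 mean and
# median volume, POD-5 mean, the POD-3 and POD-7 zero fractions, and the BMI
# distribution.  Demographics are truncated normals at the published
# means/SDs.  All log-scale quantities refer to y = log(volume_mL + 1).
generator:
  n_patients: 31            # published cohort size; raise freely for experiments
  seed: 0
  pop_intercept_mean: 4.10903   # normal-weight mean log-volume at POD 3
  pop_slope_mean: -0.37513      # mean decay per day on the log scale
  sd_intercept: 0.83057
  sd_slope: 0.24813
  intercept_slope_corr: 0.02088
  group_effects:                # additive shifts of the intercept, log scale
    normal: 0.0
    overweight: -2.22131
    obese: -2.8829
  residual_sd: 0.42034          # per-scan measurement/within-patient noise
  detection_limit_mL: 0.05      # volumetry detection threshold (unreported; configurable)
  zero_inflation:               # extra per-day probability of a resolved (zero) scan
    3: 0.00028
    5: 0.00187
    7: 0.0037
  followup_rule: conditional    # later scans only if gas was still visible
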