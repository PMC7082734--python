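# Default configuration of the synthetic maternal-cohort generator.
#
# target_spearman holds the published rank correlations between the six
# value-domain scores and the ten original belief/concern scores (rows keyed
# by concern topic, columns by value domain).  The three later-added concerns
# have no published targets and default to zero.  alpha_targets are the
# published internal-consistency coefficients of the six value domains.
# Marginals and the intention mixture were never published; the defaults are
# mildly right-skewed pro-vaccine distributions chosen as realistic for an
# insured US maternal population, and are fully configurable.
target_spearman:
  vaccine_safety_research:
    universalism: -0.249
    conformity: -0.202
    security_disease_prevention: -0.126
    security_vaccine_risk: 0.339
    tradition: 0.247
    self_direction: 0.261
  vaccine_preventable_diseases:
    universalism: -0.423
    conformity: -0.257
    security_disease_prevention: -0.311
    security_vaccine_risk: 0.202
    tradition: 0.199
    self_direction: 0.080
  number_timing_of_vaccines:
    universalism: -0.139
    conformity: -0.364
    security_disease_prevention: -0.199
    security_vaccine_risk: 0.411
    tradition: 0.257
    self_direction: 0.365
  immune_system_and_vaccines:
    universalism: -0.315
    conformity: -0.226
    security_disease_prevention: -0.204
    security_vaccine_risk: 0.259
    tradition: 0.324
    self_direction: 0.106
  vaccine_side_effects:
    universalism: -0.123
    conformity: -0.173
    security_disease_prevention: -0.078
    security_vaccine_risk: 0.352
    tradition: 0.360
    self_direction: 0.180
  do_own_research:
    universalism: -0.173
    conformity: -0.180
    security_disease_prevention: -0.221
    security_vaccine_risk: 0.249
    tradition: 0.178
    self_direction: 0.505
  vaccine_ingredients:
    universalism: -0.251
    conformity: -0.347
    security_disease_prevention: -0.117
    security_vaccine_risk: 0.239
    tradition: 0.240
    self_direction: 0.156
  vaccines_and_autism:
    universalism: -0.205
    conformity: -0.231
    security_disease_prevention: -0.092
    security_vaccine_risk: 0.338
    tradition: 0.358
    self_direction: 0.164
  vaccination_risks_benefits:
    universalism: -0.186
    conformity: -0.115
    security_disease_prevention: -0.343
    security_vaccine_risk: 0.474
    tradition: 0.344
    self_direction: 0.333
  alternative_delayed_schedules:
    universalism: -0.319
    conformity: -0.176
    security_disease_prevention: -0.351
    security_vaccine_risk: 0.412
    tradition: 0.301
    self_direction: 0.257
  vaccines_during_pregnancy: {}
  role_of_pharma: {}
  tips_for_vaccinating_at_kaiser: {}

alpha_targets:
  security_disease_prevention: 0.74
  security_vaccine_risk: 0.73
  universalism: 0.86
  self_direction: 0.66
  conformity: 0.62
  tradition: 0.79

# Per-item category probabilities (strongly_disagree ... strongly_agree).
value_item_marginals: [0.08, 0.17, 0.40, 0.35]
belief_item_marginals: [0.05, 0.10, 0.20, 0.35, 0.30]

# Latent correlation between the two items of a composite concern, beyond
# what their shared concern factor induces.
composite_item_loading: 0.85

intention_mixture:
  refuses_all: 0.05
  alternative_schedule: 0.15
  full_acceptor: 0.80

demographics:
  pregnant_fraction: 0.30
  gender_probs: {female: 0.48, male: 0.48, unknown: 0.04}
  maternal_age_mean: 31.0
  maternal_age_sd: 4.5
  child_age_days_max: 60
  nicknames: [Sam, Alex, Bea, Charlie, Dani, Eli, Frankie, Gio, Harper, Izzy,
              Jo, Kai, Lou, Mia, Nico, Ollie, Pip, Quinn, Remy, Sky]

calibration:
  n: 60000
  seed: 20200305
  tol: 0.0015
  max_iter: 40
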