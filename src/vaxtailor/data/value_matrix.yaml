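# Which of the six value domains may frame each Just-for-You tile topic.
# Tradition is unavailable for every topic; the tips_for_vaccinating_at_kaiser
# tile receives no values tailoring at all.  The alternative_delayed_schedules
# row ships conformity and universalism as unavailable (the published grid
# leaves those two cells blank; this file records them as unavailable without
# inferring intent).
availability:
  vaccine_safety_research: [security_disease_prevention, security_vaccine_risk, self_direction, conformity]
  vaccine_preventable_diseases: [security_disease_prevention, security_vaccine_risk, self_direction, conformity, universalism]
  number_timing_of_vaccines: [security_disease_prevention, security_vaccine_risk, self_direction, conformity]
  vaccine_ingredients: [security_disease_prevention, security_vaccine_risk, self_direction, conformity]
  vaccine_side_effects: [security_disease_prevention, security_vaccine_risk, self_direction]
  do_own_research: [security_disease_prevention, security_vaccine_risk, self_direction, conformity, universalism]
  immune_system_and_vaccines: [security_disease_prevention, security_vaccine_risk, conformity, universalism]
  vaccines_and_autism: [security_disease_prevention, security_vaccine_risk, self_direction]
  vaccination_risks_benefits: [security_disease_prevention, security_vaccine_risk, self_direction, universalism]
  vaccines_during_pregnancy: [security_disease_prevention, security_vaccine_risk, self_direction, conformity]
  role_of_pharma: [security_vaccine_risk, self_direction]
  alternative_delayed_schedules: [security_disease_prevention, security_vaccine_risk, self_direction]
  tips_for_vaccinating_at_kaiser: []
no_values_tailoring:
  - tips_for_vaccinating_at_kaiser
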