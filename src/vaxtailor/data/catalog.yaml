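# Informational architecture of the intervention: 17 general topic areas
# divided into 41 specific content areas, grouped under the 6 standard
# home-page tiles.  Four specific topics were newly developed for the
# intervention; the rest were adapted from an earlier one.
general_topics:
  - name: vaccine_schedule
    tile: vaccine_schedule_timing
    specific_topics:
      - {name: recommended_vaccine_schedule}
      - {name: vaccines}
      - {name: safety_of_the_schedule}
      - {name: how_the_schedule_is_made}
      - {name: importance_of_vaccine_timing}
  - name: alternative_schedules
    tile: vaccine_schedule_timing
    specific_topics:
      - {name: reasons_we_cannot_recommend_an_alternative_schedule}
  - name: immunity_and_timing
    tile: vaccine_schedule_timing
    specific_topics:
      - {name: babys_developing_immune_system}
      - {name: parents_main_concerns_about_baby_vaccines}
  - name: vaccine_safety_research
    tile: vaccine_safety_side_effects
    specific_topics:
      - {name: how_vaccine_studies_are_done}
      - {name: how_vaccine_side_effects_are_reported}
      - {name: doing_your_own_research, newly_developed: true}
  - name: vaccine_side_effects
    tile: vaccine_safety_side_effects
    specific_topics:
      - {name: mild_common_side_effects}
      - {name: serious_rare_side_effects}
      - {name: conditions_not_linked_to_vaccines}
      - {name: who_should_be_vaccinated}
  - name: how_vaccines_are_made
    tile: how_vaccines_work
    specific_topics:
      - {name: vaccine_production}
      - {name: how_pharma_works}
      - {name: kaiser_and_pharma}
  - name: vaccine_ingredients
    tile: how_vaccines_work
    specific_topics:
      - {name: why_some_ingredients_are_needed}
      - {name: vaccine_ingredient_types}
      - {name: individual_ingredients}
  - name: vaccines_and_immunity
    tile: how_vaccines_work
    specific_topics:
      - {name: natural_versus_vaccine_immunity}
  - name: why_vaccinate
    tile: reasons_to_vaccinate
    specific_topics:
      - {name: community_benefits_of_vaccination}
      - {name: risk_of_diseases, newly_developed: true}
      - {name: worldwide_risk_of_diseases, newly_developed: true}
      - {name: current_outbreaks, newly_developed: true}
  - name: diseases_prevented
    tile: reasons_to_vaccinate
    specific_topics:
      - {name: vaccine_preventable_diseases_and_vaccines_given}
  - name: the_baby_vaccine_visit
    tile: getting_vaccines_at_kaiser
    specific_topics:
      - {name: before_the_vaccine_visit}
      - {name: during_the_vaccine_visit}
      - {name: after_the_vaccine_visit}
  - name: maternal_vaccination
    tile: getting_vaccines_at_kaiser
    specific_topics:
      - {name: vaccines_in_pregnancy}
      - {name: safety_of_vaccines_in_pregnancy}
  - name: kaiser_permanente_clinics
    tile: getting_vaccines_at_kaiser
    specific_topics:
      - {name: transportation_to_kaiser_clinics}
      - {name: bus_routes}
      - {name: kaiser_clinic_hours}
  - name: colorado_vaccine_laws
    tile: learn_more
    specific_topics:
      - {name: colorado_vaccine_laws}
      - {name: colorado_vaccine_exemptions}
  - name: travel_vaccination
    tile: learn_more
    specific_topics:
      - {name: kaiser_travel_clinic}
      - {name: vaccines_and_traveling_abroad}
  - name: adolescent_vaccination
    tile: learn_more
    specific_topics:
      - {name: adolescent_vaccination}
  - name: other_faqs
    tile: learn_more
    specific_topics:
      - {name: other_faqs}

# Which standard tile "owns" each Just-for-You concern topic.  Qualifying
# concerns beyond a participant's top three are highlighted on these tiles.
concern_tile_map:
  vaccine_safety_research: vaccine_safety_side_effects
  vaccine_preventable_diseases: reasons_to_vaccinate
  number_timing_of_vaccines: vaccine_schedule_timing
  immune_system_and_vaccines: how_vaccines_work
  vaccine_side_effects: vaccine_safety_side_effects
  do_own_research: vaccine_safety_side_effects
  vaccine_ingredients: how_vaccines_work
  vaccines_and_autism: vaccine_safety_side_effects
  vaccination_risks_benefits: reasons_to_vaccinate
  alternative_delayed_schedules: vaccine_schedule_timing
  vaccines_during_pregnancy: getting_vaccines_at_kaiser
  role_of_pharma: how_vaccines_work
  tips_for_vaccinating_at_kaiser: getting_vaccines_at_kaiser
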