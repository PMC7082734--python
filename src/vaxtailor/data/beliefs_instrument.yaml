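# Vaccine beliefs/concerns instrument: 13 concern topics on a 5-point
# agreement scale, three of them two-item composites (16 items total).
# Item wording and composite membership were never published; texts here are
# SYNTHETIC placeholders, and the choice of which three concerns are
# composites is a shipped default (configurable).  All items are worded
# pro-vaccine (reverse_keyed: false), so that after coding
# strongly_disagree=1 ... strongly_agree=5 a LOWER concern score means a MORE
# anti-vaccine view.  The `label` field records the survey-analysis name of
# the ten concerns that carry printed value-belief correlations.
instrument_id: beliefs
coding:
  n_levels: 5
  labels: [strongly_disagree, disagree, neutral, agree, strongly_agree]
items:
  - {item_id: bel_01, group: vaccine_safety_research, text: "Enough research has been done on the safety of vaccines.", polarity: pro_vaccine, reverse_keyed: false}
  - {item_id: bel_02, group: vaccine_preventable_diseases, text: "The diseases vaccines prevent are serious enough to vaccinate against.", polarity: pro_vaccine, reverse_keyed: false}
  - {item_id: bel_03, group: vaccine_preventable_diseases, text: "My baby could be exposed to vaccine-preventable diseases.", polarity: pro_vaccine, reverse_keyed: false}
  - {item_id: bel_04, group: number_timing_of_vaccines, text: "The number of vaccines given at one visit is safe for my baby.", polarity: pro_vaccine, reverse_keyed: false}
  - {item_id: bel_05, group: immune_system_and_vaccines, text: "Vaccine immunity protects my baby as well as immunity from getting sick.", polarity: pro_vaccine, reverse_keyed: false}
  - {item_id: bel_06, group: vaccine_side_effects, text: "Serious side effects from vaccines are rare.", polarity: pro_vaccine, reverse_keyed: false}
  - {item_id: bel_07, group: do_own_research, text: "I do not need to do my own research before following the vaccine schedule.", polarity: pro_vaccine, reverse_keyed: false}
  - {item_id: bel_08, group: vaccine_ingredients, text: "The ingredients in vaccines are safe for babies.", polarity: pro_vaccine, reverse_keyed: false}
  - {item_id: bel_09, group: vaccines_and_autism, text: "Vaccines do not cause autism.", polarity: pro_vaccine, reverse_keyed: false}
  - {item_id: bel_10, group: vaccination_risks_benefits, text: "The benefits of vaccinating my baby outweigh the risks.", polarity: pro_vaccine, reverse_keyed: false}
  - {item_id: bel_11, group: vaccination_risks_benefits, text: "Vaccinating on time is less risky than leaving my baby unprotected.", polarity: pro_vaccine, reverse_keyed: false}
  - {item_id: bel_12, group: alternative_delayed_schedules, text: "Following the recommended schedule is better than spreading vaccines out.", polarity: pro_vaccine, reverse_keyed: false}
  - {item_id: bel_13, group: alternative_delayed_schedules, text: "Delaying vaccines would put my baby at risk.", polarity: pro_vaccine, reverse_keyed: false}
  - {item_id: bel_14, group: vaccines_during_pregnancy, text: "Vaccines recommended during pregnancy are safe for my baby.", polarity: pro_vaccine, reverse_keyed: false}
  - {item_id: bel_15, group: role_of_pharma, text: "Vaccine recommendations are based on science, not drug-company profit.", polarity: pro_vaccine, reverse_keyed: false}
  - {item_id: bel_16, group: tips_for_vaccinating_at_kaiser, text: "I know how to get my baby's vaccine visits done at my clinic.", polarity: pro_vaccine, reverse_keyed: false}
concern_labels:
  vaccine_safety_research: "Enough research"
  vaccine_preventable_diseases: "Disease risk and benefit"
  number_timing_of_vaccines: "Too many, too soon"
  immune_system_and_vaccines: "Natural immunity"
  vaccine_side_effects: "Vaccine safety"
  do_own_research: "Do own research"
  vaccine_ingredients: "Vaccine ingredients"
  vaccines_and_autism: "Autism"
  vaccination_risks_benefits: "Vaccine risk versus benefit"
  alternative_delayed_schedules: "Combined risk/benefit"
  vaccines_during_pregnancy: "Vaccines during pregnancy (later addition)"
  role_of_pharma: "Role of pharmaceutical companies (later addition)"
  tips_for_vaccinating_at_kaiser: "Vaccinating at Kaiser (later addition)"
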