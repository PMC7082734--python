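# Parental vaccine-values instrument: 20 items over 6 value domains on a
# 4-point agreement scale.  Item wording was never published, so the `text`
# fields here are SYNTHETIC placeholders written for this package; the
# structural layout (20 items, 6 domains, 4-point coding) is the instrument's
# real architecture.  The 4/3/4/3/3/3 split of items across domains is a
# shipped default and can be overridden with a user YAML.
instrument_id: pvvs
coding:
  n_levels: 4
  labels: [strongly_disagree, disagree, agree, strongly_agree]
items:
  - {item_id: pvvs_01, group: security_disease_prevention, text: "Protecting my child from serious infections matters more to me than almost anything.", polarity: value_endorsement, reverse_keyed: false}
  - {item_id: pvvs_02, group: security_disease_prevention, text: "I would feel responsible if my child caught a disease I could have prevented.", polarity: value_endorsement, reverse_keyed: false}
  - {item_id: pvvs_03, group: security_disease_prevention, text: "Keeping my child safe from illness guides my health decisions.", polarity: value_endorsement, reverse_keyed: false}
  - {item_id: pvvs_04, group: security_disease_prevention, text: "Preventing disease before it happens is important to me.", polarity: value_endorsement, reverse_keyed: false}
  - {item_id: pvvs_05, group: security_vaccine_risk, text: "I worry about medicines exposing my child to unnecessary risks.", polarity: value_endorsement, reverse_keyed: false}
  - {item_id: pvvs_06, group: security_vaccine_risk, text: "Protecting my child from side effects of medical products is important to me.", polarity: value_endorsement, reverse_keyed: false}
  - {item_id: pvvs_07, group: security_vaccine_risk, text: "I am careful about what goes into my child's body.", polarity: value_endorsement, reverse_keyed: false}
  - {item_id: pvvs_08, group: universalism, text: "I value doing my part to keep my community healthy.", polarity: value_endorsement, reverse_keyed: false}
  - {item_id: pvvs_09, group: universalism, text: "Protecting vulnerable people around us matters to me.", polarity: value_endorsement, reverse_keyed: false}
  - {item_id: pvvs_10, group: universalism, text: "My family's choices should help protect everyone's children.", polarity: value_endorsement, reverse_keyed: false}
  - {item_id: pvvs_11, group: universalism, text: "I care about the health of children beyond my own family.", polarity: value_endorsement, reverse_keyed: false}
  - {item_id: pvvs_12, group: self_direction, text: "I like to gather information myself before making health decisions.", polarity: value_endorsement, reverse_keyed: false}
  - {item_id: pvvs_13, group: self_direction, text: "I prefer to come to my own conclusions rather than rely on others.", polarity: value_endorsement, reverse_keyed: false}
  - {item_id: pvvs_14, group: self_direction, text: "Being the one who decides about my baby's health is important to me.", polarity: value_endorsement, reverse_keyed: false}
  - {item_id: pvvs_15, group: conformity, text: "I value following the advice of medical experts.", polarity: value_endorsement, reverse_keyed: false}
  - {item_id: pvvs_16, group: conformity, text: "Doing what doctors and authorities recommend is important to me.", polarity: value_endorsement, reverse_keyed: false}
  - {item_id: pvvs_17, group: conformity, text: "I trust official guidance when making decisions for my child.", polarity: value_endorsement, reverse_keyed: false}
  - {item_id: pvvs_18, group: tradition, text: "I value doing things the way my family has always done them.", polarity: value_endorsement, reverse_keyed: false}
  - {item_id: pvvs_19, group: tradition, text: "The customs of my religion or community guide my decisions.", polarity: value_endorsement, reverse_keyed: false}
  - {item_id: pvvs_20, group: tradition, text: "Keeping with established norms matters to me.", polarity: value_endorsement, reverse_keyed: false}
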