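# Representative quality-indicator library.
#
# These definitions mirror well-known chronic-care indicator families
# (pressure ulcers, pain presence and worsening, ADL decline, ADL
# improvement, physical restraints) over the item vocabulary emitted by
# nhqi.simulate.  They are illustrative: real deployments supply their own
# definition documents conforming to the same schema.
#
# Items:
#   pressure_ulcer    0/1, reassessed each quarter
#   pain_level        0 none / 1 moderate / 2 severe
#   adl_self          0 (independent) .. 4 (total dependence)
#   physical_restraint 0/1, highly persistent resident trait
#   cognition_scale, comorbidity_index   continuous covariates
#   adl_long_form     continuous stratifier
qis:
  - qi_id: PRU01
    description: Prevalence of pressure ulcers
    scope: cross_sectional
    numerator_rule: {item: pressure_ulcer, op: "==", value: 1}
    denominator_rule: true
    exclusion_rules: []
    covariate_names: [cognition_scale, comorbidity_index]
    stratifier_name: adl_long_form
    polarity: adverse

  - qi_id: PAI0X
    description: Prevalence of pain (moderate or severe)
    scope: cross_sectional
    numerator_rule: {item: pain_level, op: ">=", value: 1}
    denominator_rule: true
    exclusion_rules: []
    covariate_names: [cognition_scale, comorbidity_index]
    stratifier_name: adl_long_form
    polarity: adverse

  - qi_id: PAN01
    description: Worsening pain since prior quarter
    scope: change
    numerator_rule: {item: pain_level, op: ">", value: {item: "pain_level@baseline"}}
    denominator_rule: {item: "pain_level@baseline", op: "<=", value: 1}
    exclusion_rules: []
    covariate_names: [cognition_scale, comorbidity_index]
    stratifier_name: adl_long_form
    polarity: adverse

  - qi_id: ADL01
    description: Decline in ADL self-performance since prior quarter
    scope: change
    numerator_rule: {item: adl_self, op: ">", value: {item: "adl_self@baseline"}}
    denominator_rule: {item: "adl_self@baseline", op: "<=", value: 3}
    exclusion_rules: []
    covariate_names: [cognition_scale, comorbidity_index]
    stratifier_name: adl_long_form
    polarity: adverse

  - qi_id: ADL06
    description: >
      Improvement in early-loss ADL function, or remaining completely
      independent (double-barrelled numerator)
    scope: change
    numerator_rule:
      any:
        - {item: adl_self, op: "<", value: {item: "adl_self@baseline"}}
        - all:
            - {item: adl_self, op: "==", value: 0}
            - {item: "adl_self@baseline", op: "==", value: 0}
    denominator_rule: true
    exclusion_rules: []
    covariate_names: [cognition_scale, comorbidity_index]
    stratifier_name: adl_long_form
    polarity: desirable

  - qi_id: RES01
    description: Prevalence of daily physical restraints
    scope: cross_sectional
    numerator_rule: {item: physical_restraint, op: "==", value: 1}
    denominator_rule: true
    exclusion_rules: []
    covariate_names: [cognition_scale, comorbidity_index]
    stratifier_name: adl_long_form
    polarity: adverse
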