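# Minimal oestrogen-receptor event network backing the ontology fixture:
# the mapped terms resolve to these events.
events:
- id: er_alpha_binding
  name: Oestrogen receptor alpha binding
  level: molecular
  role: MIE
- id: er_beta_binding
  name: Oestrogen receptor beta binding
  level: molecular
  role: MIE
- id: er_activation
  name: Oestrogen receptor activation
  level: molecular
  role: KE
- id: endocrine_disruption
  name: Endocrine disruption
  level: individual
  role: AO
kers:
- {upstream: er_alpha_binding, downstream: er_activation, strength: Medium}
- {upstream: er_beta_binding, downstream: er_activation, strength: Medium}
- {upstream: er_activation, downstream: endocrine_disruption, strength: Medium}
groups: []
assays:
- {id: ACEA_T47D_80hr_Positive, name: ACEA T47D proliferation, reliability: Medium, tier: in_vitro, measurements: [overall_call]}
- {id: ATG_ERE_CIS_up, name: ATG ERE cis activation, reliability: Medium, tier: in_vitro, measurements: [overall_call]}
- {id: Tox21_ERa_LUC_BG1_Agonist, name: Tox21 ERa luciferase agonist, reliability: Medium, tier: in_vitro, measurements: [overall_call]}
- {id: Tox21_ERa_BLA_Agonist_ratio, name: Tox21 ERa beta-lactamase agonist, reliability: Medium, tier: in_vitro, measurements: [overall_call]}
- {id: OT_ERa_EREGFP_0480, name: OT ERa ERE-GFP 480 min, reliability: Medium, tier: in_vitro, measurements: [overall_call]}
- {id: OT_ERa_EREGFP_0120, name: OT ERa ERE-GFP 120 min, reliability: Medium, tier: in_vitro, measurements: [overall_call]}
- {id: ATG_ERa_TRANS_up, name: ATG ERa trans activation, reliability: Medium, tier: in_vitro, measurements: [overall_call]}
- {id: NVS_NR_bER, name: NVS bovine ER binding, reliability: Medium, tier: in_vitro, measurements: [overall_call]}
- {id: NVS_NR_hER, name: NVS human ER binding, reliability: Medium, tier: in_vitro, measurements: [overall_call]}
- {id: NVS_NR_mERa, name: NVS mouse ERa binding, reliability: Medium, tier: in_vitro, measurements: [overall_call]}
- {id: Tox21_ERa_BLA_Antagonist_ratio, name: Tox21 ERa beta-lactamase antagonist, reliability: Medium, tier: in_vitro, measurements: [overall_call]}
- {id: Tox21_ERa_LUC_BG1_Antagonist, name: Tox21 ERa luciferase antagonist, reliability: Medium, tier: in_vitro, measurements: [overall_call]}
- {id: OT_ER_ERbERb_1440, name: OT ERb-ERb dimerization 1440 min, reliability: Medium, tier: in_vitro, measurements: [overall_call]}
- {id: OT_ER_ERbERb_0480, name: OT ERb-ERb dimerization 480 min, reliability: Medium, tier: in_vitro, measurements: [overall_call]}
- {id: OT_ER_ERaERb_1440, name: OT ERa-ERb dimerization 1440 min, reliability: Medium, tier: in_vitro, measurements: [overall_call]}
- {id: OT_ER_ERaERb_0480, name: OT ERa-ERb dimerization 480 min, reliability: Medium, tier: in_vitro, measurements: [overall_call]}
- {id: OT_ER_ERaERa_1440, name: OT ERa-ERa dimerization 1440 min, reliability: Medium, tier: in_vitro, measurements: [overall_call]}
- {id: OT_ER_ERaERa_0480, name: OT ERa-ERa dimerization 480 min, reliability: Medium, tier: in_vitro, measurements: [overall_call]}
assay_event_links: []
prediction_bases: []
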