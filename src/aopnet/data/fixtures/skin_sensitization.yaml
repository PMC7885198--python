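# Covalent protein binding leading to skin sensitization: one MIE, three
# intermediate KEs, one AO.  KER weights of evidence are High throughout
# except keratinocyte -> dendritic cell activation, where the evidence is
# weaker (Medium).
events:
- id: covalent_protein_binding
  name: Covalent protein binding
  level: molecular
  role: MIE
- id: keratinocyte_activation
  name: Keratinocyte activation
  level: cellular
  role: KE
- id: dendritic_cell_activation
  name: Dendritic cell activation
  level: cellular
  role: KE
- id: t_cell_activation
  name: T-cell proliferation and activation
  level: organ
  role: KE
- id: skin_sensitization
  name: Skin sensitization
  level: organ
  role: AO
kers:
- {upstream: covalent_protein_binding, downstream: keratinocyte_activation, strength: High}
- {upstream: keratinocyte_activation, downstream: dendritic_cell_activation, strength: Medium}
- {upstream: dendritic_cell_activation, downstream: t_cell_activation, strength: High}
- {upstream: t_cell_activation, downstream: skin_sensitization, strength: High}
groups: []
assays:
- id: dpra
  name: Direct peptide reactivity assay (DPRA)
  reliability: Large
  tier: in_chemico
  measurements: [cysteine_depletion, lysine_depletion, overall_call]
- id: keratinosens
  name: KeratinoSens
  reliability: Large
  tier: in_vitro
  measurements: [luciferase_induction, overall_call]
- id: lusens
  name: LuSens
  reliability: Large
  tier: in_vitro
  measurements: [luciferase_induction, overall_call]
- id: hclat
  name: h-CLAT
  reliability: Large
  tier: in_vitro
  measurements: [cd86_expression, cd54_expression, overall_call]
- id: usens
  name: U-SENS
  reliability: Large
  tier: in_vitro
  measurements: [cd86_expression, overall_call]
- id: llna
  name: Local lymph node assay (LLNA)
  reliability: Large
  tier: in_vivo
  measurements: [ec3_percent, overall_call]
- id: human_observation
  name: Observation in human
  reliability: Small
  tier: human_observation
  measurements: [overall_call]
assay_event_links:
- {assay_id: dpra, measurement_id: cysteine_depletion, event_id: covalent_protein_binding, convincingness: Large}
- {assay_id: dpra, measurement_id: lysine_depletion, event_id: covalent_protein_binding, convincingness: Large}
- {assay_id: dpra, measurement_id: overall_call, event_id: covalent_protein_binding, convincingness: Large}
- {assay_id: keratinosens, measurement_id: luciferase_induction, event_id: keratinocyte_activation, convincingness: Medium}
- {assay_id: keratinosens, measurement_id: overall_call, event_id: keratinocyte_activation, convincingness: Medium}
- {assay_id: lusens, measurement_id: luciferase_induction, event_id: keratinocyte_activation, convincingness: Medium}
- {assay_id: lusens, measurement_id: overall_call, event_id: keratinocyte_activation, convincingness: Medium}
- {assay_id: hclat, measurement_id: cd86_expression, event_id: dendritic_cell_activation, convincingness: Medium}
- {assay_id: hclat, measurement_id: cd54_expression, event_id: dendritic_cell_activation, convincingness: Medium}
- {assay_id: hclat, measurement_id: overall_call, event_id: dendritic_cell_activation, convincingness: Medium}
- {assay_id: usens, measurement_id: cd86_expression, event_id: dendritic_cell_activation, convincingness: Medium}
- {assay_id: usens, measurement_id: overall_call, event_id: dendritic_cell_activation, convincingness: Medium}
- {assay_id: llna, measurement_id: ec3_percent, event_id: t_cell_activation, convincingness: Large}
- {assay_id: llna, measurement_id: overall_call, event_id: t_cell_activation, convincingness: Large}
- {assay_id: human_observation, measurement_id: overall_call, event_id: skin_sensitization, convincingness: Large}
prediction_bases:
# An in-silico alert: the prediction argument itself is Small convincingness
# with Large (deterministic model) reliability -> Medium strength; the
# prediction-event relationship is Small x Medium -> Low, so the transmitted
# in-silico argument is Low.
- model_id: sar_model
  basis_id: skin_sensitization_alert
  convincingness: Small
  reliability: Large
  links:
  - {target_kind: ao, target_id: skin_sensitization, convincingness: Small, reliability: Medium}
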