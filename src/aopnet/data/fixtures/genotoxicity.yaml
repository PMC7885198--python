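# Genotoxic carcinogenicity: the Ames test reports for inherited DNA
# mutation, which leads to the adverse outcomes of genetic instability
# and cancer.  Other mutation assays are present without results.
events:
- id: dna_damage
  name: DNA damage
  level: molecular
  role: MIE
- id: inherited_dna_mutation
  name: Inherited DNA mutation
  level: molecular
  role: KE
- id: genetic_instability
  name: Genetic instability
  level: cellular
  role: AO
- id: cancer
  name: Cancer
  level: individual
  role: AO
kers:
- {upstream: dna_damage, downstream: inherited_dna_mutation, strength: High}
- {upstream: inherited_dna_mutation, downstream: genetic_instability, strength: High}
- {upstream: inherited_dna_mutation, downstream: cancer, strength: High}
groups: []
assays:
- id: ames
  name: Bacterial reverse mutation test (Ames)
  reliability: Large
  tier: in_vitro
  measurements: [overall_call]
- id: mouse_lymphoma_tk
  name: Mouse lymphoma thymidine kinase assay
  reliability: Medium
  tier: in_vitro
  measurements: [overall_call]
- id: transgenic_rodent_mutation
  name: Transgenic rodent somatic mutation assay
  reliability: Large
  tier: in_vivo
  measurements: [overall_call]
assay_event_links:
- {assay_id: ames, measurement_id: overall_call, event_id: inherited_dna_mutation, convincingness: Large}
- {assay_id: mouse_lymphoma_tk, measurement_id: overall_call, event_id: inherited_dna_mutation, convincingness: Medium}
- {assay_id: transgenic_rodent_mutation, measurement_id: overall_call, event_id: inherited_dna_mutation, convincingness: Large}
prediction_bases: []
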