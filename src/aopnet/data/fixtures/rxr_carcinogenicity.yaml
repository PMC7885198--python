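# Retinoid X receptor binding leading to carcinogenicity, with two key
# event groups: the p38 MAPK signalling pathway dysregulation group
# (three sub-KEs) and the cell proliferation increase group (itself an
# event group with two sub-KEs).  Sub-KE identities beyond the named
# groups are synthetic stand-ins for unpublished detail.
events:
- id: rxr_binding
  name: Retinoid X receptor binding
  level: molecular
  role: MIE
- id: p38_phosphorylation_change
  name: p38 phosphorylation change (synthetic sub-KE)
  level: molecular
  role: KE
  group_id: p38_mapk_dysregulation
- id: p38_signalling_imbalance
  name: p38 signalling imbalance (synthetic sub-KE)
  level: cellular
  role: KE
  group_id: p38_mapk_dysregulation
- id: p38_target_gene_dysregulation
  name: p38 target gene dysregulation (synthetic sub-KE)
  level: cellular
  role: KE
  group_id: p38_mapk_dysregulation
- id: hepatocyte_proliferation
  name: Hepatocyte proliferation (synthetic sub-KE)
  level: cellular
  role: KE
  group_id: cell_proliferation_increase
- id: clonal_expansion
  name: Clonal expansion of altered cells (synthetic sub-KE)
  level: tissue
  role: KE
  group_id: cell_proliferation_increase
- id: apoptosis_suppression
  name: Apoptosis suppression
  level: cellular
  role: KE
- id: carcinogenicity
  name: Carcinogenicity
  level: individual
  role: AO
kers:
- {upstream: rxr_binding, downstream: p38_phosphorylation_change, strength: Medium}
- {upstream: p38_phosphorylation_change, downstream: p38_signalling_imbalance, strength: Medium}
- {upstream: p38_signalling_imbalance, downstream: p38_target_gene_dysregulation, strength: Medium}
- {upstream: p38_target_gene_dysregulation, downstream: hepatocyte_proliferation, strength: Medium}
- {upstream: hepatocyte_proliferation, downstream: clonal_expansion, strength: Low}
- {upstream: clonal_expansion, downstream: carcinogenicity, strength: Medium}
- {upstream: rxr_binding, downstream: apoptosis_suppression, strength: Low}
- {upstream: apoptosis_suppression, downstream: carcinogenicity, strength: Low}
groups:
- id: p38_mapk_dysregulation
  name: p38 MAPK signalling pathway dysregulation
  members: [p38_phosphorylation_change, p38_signalling_imbalance, p38_target_gene_dysregulation]
- id: cell_proliferation_increase
  name: Cell proliferation increase
  members: [hepatocyte_proliferation, clonal_expansion]
assays: []
assay_event_links: []
prediction_bases: []
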