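# Two AOPs converging on reproductive toxicity: aromatase inhibition and
# androgen receptor agonism both reduce 17-beta oestradiol synthesis by
# ovarian granulosa cells.  Two MIE-role nodes share downstream events.
events:
- id: aromatase_inhibition
  name: Aromatase inhibition
  level: molecular
  role: MIE
- id: androgen_receptor_agonism
  name: Androgen receptor agonism
  level: molecular
  role: MIE
- id: estradiol_reduction
  name: Reduction in 17-beta oestradiol synthesis by ovarian granulosa cells
  level: cellular
  role: KE
- id: impaired_ovarian_cyclicity
  name: Impaired ovarian cyclicity
  level: organ
  role: KE
- id: reproductive_toxicity
  name: Reproductive toxicity
  level: individual
  role: AO
kers:
- {upstream: aromatase_inhibition, downstream: estradiol_reduction, strength: High}
- {upstream: androgen_receptor_agonism, downstream: estradiol_reduction, strength: Medium}
- {upstream: estradiol_reduction, downstream: impaired_ovarian_cyclicity, strength: Medium}
- {upstream: impaired_ovarian_cyclicity, downstream: reproductive_toxicity, strength: Medium}
groups: []
assays: []
assay_event_links: []
prediction_bases: []
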