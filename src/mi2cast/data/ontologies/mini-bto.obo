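format-version: 1.2
ontology: mini-bto
remark: Synthetic test-scaffolding subset of the BRENDA tissue ontology; not an ontology release.

[Term]
id: BTO:0000000
name: tissues, cell types and enzyme sources

[Term]
id: BTO:0000089
name: blood
is_a: BTO:0000000 ! tissues, cell types and enzyme sources

[Term]
id: BTO:0000142
name: brain
is_a: BTO:0000000 ! tissues, cell types and enzyme sources

[Term]
id: BTO:0000759
name: liver
is_a: BTO:0000000 ! tissues, cell types and enzyme sources
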