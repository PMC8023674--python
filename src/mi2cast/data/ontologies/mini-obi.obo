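format-version: 1.2
ontology: mini-obi
remark: Synthetic test-scaffolding subset of the Ontology for Biomedical Investigations; filler terms use stand-in ids; not an ontology release.

[Term]
id: OBI:0000011
name: planned process

[Term]
id: OBI:0000070
name: assay
is_a: OBI:0000011 ! planned process

[Term]
id: OBI:0600036
name: genetic transformation
is_a: OBI:0000011 ! planned process
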