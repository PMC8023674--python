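format-version: 1.2
ontology: mini-uberon
remark: Synthetic test-scaffolding subset of Uberon; not an ontology release.

[Term]
id: UBERON:0000479
name: tissue

[Term]
id: UBERON:0002107
name: liver
is_a: UBERON:0000479 ! tissue

[Term]
id: UBERON:0000955
name: brain
is_a: UBERON:0000479 ! tissue
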