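format-version: 1.2
ontology: mini-ro
remark: Synthetic test-scaffolding subset of the Relation Ontology causal branch; not an ontology release.

[Term]
id: RO:0002410
name: causally related to

[Term]
id: RO:0002411
name: causally upstream of
is_a: RO:0002410 ! causally related to

[Term]
id: RO:0002418
name: causally upstream of or within
is_a: RO:0002410 ! causally related to

[Term]
id: RO:0002211
name: regulates
is_a: RO:0002411 ! causally upstream of

[Term]
id: RO:0002213
name: positively regulates
is_a: RO:0002211 ! regulates

[Term]
id: RO:0002212
name: negatively regulates
is_a: RO:0002211 ! regulates

[Term]
id: RO:0002629
name: directly positively regulates
is_a: RO:0002213 ! positively regulates

[Term]
id: RO:0002630
name: directly negatively regulates
is_a: RO:0002212 ! negatively regulates
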