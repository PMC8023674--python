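format-version: 1.2
ontology: mini-eco
remark: Synthetic test-scaffolding subset of the Evidence & Conclusion Ontology; filler terms use stand-in ids; not an ontology release.

[Term]
id: ECO:0000000
name: evidence

[Term]
id: ECO:0000006
name: experimental evidence
is_a: ECO:0000000 ! evidence

[Term]
id: ECO:0000270
name: expression pattern evidence
is_a: ECO:0000006 ! experimental evidence

[Term]
id: ECO:0000068
name: yeast 2-hybrid evidence
is_a: ECO:0000006 ! experimental evidence

[Term]
id: ECO:0005805
name: yeast 2-hybrid evidence used in manual assertion
is_a: ECO:0000068 ! yeast 2-hybrid evidence

[Term]
id: ECO:0000204
name: author statement
is_a: ECO:0000000 ! evidence

[Term]
id: ECO:0000501
name: evidence used in automatic assertion
is_a: ECO:0000000 ! evidence
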