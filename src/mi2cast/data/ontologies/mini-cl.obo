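format-version: 1.2
ontology: mini-cl
remark: Synthetic test-scaffolding subset of the Cell Ontology; not an ontology release.

[Term]
id: CL:0000000
name: cell

[Term]
id: CL:0000057
name: fibroblast
is_a: CL:0000000 ! cell

[Term]
id: CL:0000084
name: T cell
is_a: CL:0000000 ! cell

[Term]
id: CL:0000236
name: B cell
is_a: CL:0000000 ! cell
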