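format-version: 1.2
ontology: mini-so
remark: Synthetic test-scaffolding subset of the Sequence Ontology; not an ontology release.

[Term]
id: SO:0000110
name: sequence_feature

[Term]
id: SO:0000704
name: gene
is_a: SO:0000110 ! sequence_feature

[Term]
id: SO:0000409
name: binding_site
is_a: SO:0000110 ! sequence_feature

[Term]
id: SO:0000234
name: mRNA
is_a: SO:0000110 ! sequence_feature

[Term]
id: SO:0000306
name: methylated DNA base feature
is_a: SO:0000110 ! sequence_feature
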