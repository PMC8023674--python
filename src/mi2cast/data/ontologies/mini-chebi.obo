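format-version: 1.2
ontology: mini-chebi
remark: Synthetic test-scaffolding subset of ChEBI (role branch plus amino-acid residue group); residue terms use stand-in ids; not an ontology release.

[Term]
id: CHEBI:50906
name: role

[Term]
id: CHEBI:23888
name: drug
is_a: CHEBI:50906 ! role

[Term]
id: CHEBI:35223
name: catalyst
is_a: CHEBI:50906 ! role

[Term]
id: CHEBI:35222
name: inhibitor
is_a: CHEBI:50906 ! role

[Term]
id: CHEBI:48705
name: agonist
is_a: CHEBI:50906 ! role

[Term]
id: CHEBI:33708
name: amino-acid residue

[Term]
id: CHEBI:46858
name: L-tyrosine residue
is_a: CHEBI:33708 ! amino-acid residue

[Term]
id: CHEBI:29999
name: L-serine residue
is_a: CHEBI:33708 ! amino-acid residue
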