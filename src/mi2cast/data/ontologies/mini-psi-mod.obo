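format-version: 1.2
ontology: mini-psi-mod
remark: Synthetic test-scaffolding subset of the PSI-MOD protein modification ontology; filler terms use stand-in ids; not an ontology release.

[Term]
id: MOD:00000
name: protein modification

[Term]
id: MOD:00696
name: phosphorylated residue
is_a: MOD:00000 ! protein modification

[Term]
id: MOD:00046
name: O-phospho-L-serine
is_a: MOD:00696 ! phosphorylated residue

[Term]
id: MOD:00047
name: O-phospho-L-threonine
is_a: MOD:00696 ! phosphorylated residue

[Term]
id: MOD:00048
name: O4'-phospho-L-tyrosine
is_a: MOD:00696 ! phosphorylated residue

[Term]
id: MOD:00427
name: methylated residue
is_a: MOD:00000 ! protein modification

[Term]
id: MOD:01875
name: dephosphorylated residue
is_a: MOD:00000 ! protein modification
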