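format-version: 1.2
ontology: mini-psi-mi
remark: Synthetic test-scaffolding subset of the PSI-MI controlled vocabulary; filler terms use stand-in ids; not an ontology release.

[Term]
id: MI:0000
name: molecular interaction

[Term]
id: MI:2233
name: causal statement
is_a: MI:0000 ! molecular interaction

[Term]
id: MI:2235
name: up-regulates
is_a: MI:2233 ! causal statement

[Term]
id: MI:2236
name: up-regulates activity
is_a: MI:2235 ! up-regulates

[Term]
id: MI:2237
name: up-regulates quantity
is_a: MI:2235 ! up-regulates

[Term]
id: MI:2240
name: down-regulates
is_a: MI:2233 ! causal statement

[Term]
id: MI:2241
name: down-regulates activity
is_a: MI:2240 ! down-regulates

[Term]
id: MI:0313
name: interactor type
is_a: MI:0000 ! molecular interaction

[Term]
id: MI:0326
name: protein
is_a: MI:0313 ! interactor type

[Term]
id: MI:0320
name: ribonucleic acid
is_a: MI:0313 ! interactor type

[Term]
id: MI:2190
name: messenger rna
is_a: MI:0320 ! ribonucleic acid

[Term]
id: MI:0250
name: gene
is_a: MI:0313 ! interactor type

[Term]
id: MI:0328
name: small molecule
is_a: MI:0313 ! interactor type

[Term]
id: MI:0314
name: complex
is_a: MI:0313 ! interactor type

[Term]
id: MI:1304
name: molecule set
is_a: MI:0313 ! interactor type

[Term]
id: MI:0346
name: experimental preparation
is_a: MI:0000 ! molecular interaction

[Term]
id: MI:0506
name: over expressed level
is_a: MI:0346 ! experimental preparation

[Term]
id: MI:0331
name: engineered
is_a: MI:0346 ! experimental preparation

[Term]
id: MI:2245
name: causal regulatory mechanism
is_a: MI:0000 ! molecular interaction

[Term]
id: MI:2246
name: transcriptional regulation
is_a: MI:2245 ! causal regulatory mechanism

[Term]
id: MI:2248
name: post transcriptional regulation
is_a: MI:2245 ! causal regulatory mechanism

[Term]
id: MI:0190
name: interaction type
is_a: MI:0000 ! molecular interaction

[Term]
id: MI:0407
name: direct interaction
is_a: MI:0190 ! interaction type

[Term]
id: MI:0414
name: enzymatic reaction
is_a: MI:0407 ! direct interaction

[Term]
id: MI:0217
name: phosphorylation reaction
is_a: MI:0414 ! enzymatic reaction

[Term]
id: MI:0203
name: dephosphorylation reaction
is_a: MI:0414 ! enzymatic reaction

[Term]
id: MI:0220
name: ubiquitination reaction
is_a: MI:0414 ! enzymatic reaction

[Term]
id: MI:0802
name: enhanced interaction
is_a: MI:0190 ! interaction type
is_obsolete: true
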