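format-version: 1.2
ontology: mini-go
remark: Synthetic test-scaffolding subset of the Gene Ontology (MF, BP and CC branches); not an ontology release.

[Term]
id: GO:0003674
name: molecular_function

[Term]
id: GO:0003824
name: catalytic activity
is_a: GO:0003674 ! molecular_function

[Term]
id: GO:0016301
name: kinase activity
is_a: GO:0003824 ! catalytic activity

[Term]
id: GO:0004713
name: protein tyrosine kinase activity
is_a: GO:0016301 ! kinase activity

[Term]
id: GO:0016791
name: phosphatase activity
is_a: GO:0003824 ! catalytic activity

[Term]
id: GO:0004725
name: protein tyrosine phosphatase activity
is_a: GO:0016791 ! phosphatase activity

[Term]
id: GO:0005488
name: binding
is_a: GO:0003674 ! molecular_function

[Term]
id: GO:0003700
name: DNA-binding transcription factor activity
is_a: GO:0003674 ! molecular_function

[Term]
id: GO:0008150
name: biological_process

[Term]
id: GO:0050789
name: regulation of biological process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0006915
name: apoptotic process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0006913
name: nucleocytoplasmic transport
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0051169
name: nuclear transport
is_a: GO:0006913 ! nucleocytoplasmic transport

[Term]
id: GO:0051170
name: import into nucleus
is_a: GO:0051169 ! nuclear transport

[Term]
id: GO:0006351
name: DNA-templated transcription
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0005575
name: cellular_component

[Term]
id: GO:0005634
name: nucleus
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0005737
name: cytoplasm
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0005829
name: cytosol
is_a: GO:0005737 ! cytoplasm

[Term]
id: GO:0005886
name: plasma membrane
is_a: GO:0005575 ! cellular_component
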