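# mi2cast

Checklist tooling for **molecular-interaction causal statements** — the
directed, signed records ("the kinase LYN phosphorylates PTPN6 at Tyr-564,
stimulating its phosphatase activity") that curators extract from the
literature and that regulatory-network resources such as SIGNOR, IntAct or
SignaLink exchange.

A causal statement is only reusable if it carries a minimum of metadata.
This package implements that minimum-information checklist as code, for
curators and database maintainers who need to lint, exchange and generate
such records:

* a **typed, immutable data model** — source/target entities with CURIE
  identifiers, the causal relation (with optional mechanism and resulting
  target modification), evidence (references, ECO evidence types) and
  biological context (activity, modification state, taxon, tissue, cell,
  compartment, experimental setup) attachable at the entity or interaction
  level;
* a **rule engine** covering the four annotation rules:
  1. source and target must be identified (complexes/families must list
     components),
  2. the causal relation must come from the Relation Ontology
     "causally related to" branch (RO:0002410) or the PSI-MI
     "causal statement" branch (MI:2233),
  3. provenance (PubMed/DOI references) and ECO evidence types are
     mandatory; experimental evidence should carry setup qualifiers,
  4. contextual detail is recommended — activity or mechanism (with the
     GO:0016301 ⇔ MI:0217 kinase/phosphorylation equivalence), biological
     type (MI:0313 branch; *mandatory* when the namespace implies none,
     e.g. an Entrez gene id standing in for a protein), resulting
     modification, NCBI taxon, and tissue/cell/compartment terms.

  "must" violations are ERROR, "should" are WARNING, unverifiable or
  advisory checks are INFO; every finding carries a rule id and the exact
  field path.
* an **identifier registry** (per-namespace accession regular expressions,
  implied interactor types, primary/alternative database preferences per
  entity class) and an **OBO loader** answering branch-membership queries
  over `is_a` subsumption;
* **interoperable I/O**: a lossless canonical JSON dialect, PSI-MITAB 2.8
  with the four causal columns (lossless via reserved `mi2cast-*`
  annotation topics), and signed SIF export (`->`, `-|`, `--`);
* a **synthetic-statement generator** that emits fully annotated statements
  or statements with precisely seeded rule violations plus machine-readable
  ground truth — the basis of the test suite and of validator benchmarking.

Everything runs offline: tiny synthetic OBO subsets of RO, PSI-MI, ECO, GO,
PSI-MOD, SO, ChEBI, BRENDA, Uberon, CL and OBI are bundled (they contain
every term the checklist's rules reference, and are test scaffolding, not
ontology releases). Accession syntax is checked; accession *existence* is
deliberately never queried remotely.

## Worked example

The statement from the package docstrings — LYN (uniprotkb:P07948, kinase
activity GO:0016301) directly positively regulates (RO:0002629) PTPN6
(uniprotkb:P29350) through a phosphorylation reaction (MI:0217), producing
O4′-phospho-L-tyrosine (MOD:00048) at position 564 and affecting PTPN6's
protein tyrosine phosphatase activity (GO:0004725), supported by one PubMed
reference with experimental evidence (ECO:0000006):

```python
from mi2cast import io, validate
from mi2cast.fixtures import worked_example

open("lyn.json", "w").write(io.write_json([worked_example()]))
```

```console
$ mi2cast validate --in lyn.json
statement_key	rule_id	severity	path	message
bf4422a62cb78d2bc95d8343c912449b	R3.3.setup	WARNING	evidence.interaction_context.experimental_setup	experimental evidence without experimental-setup qualifiers
$ echo $?
0
```

Zero ERROR findings, so the statement meets the mandatory core (exit
status 0); the single WARNING notes that experimental evidence would
ideally name its setup qualifiers (e.g. MI:0506, "over expressed level").
Deleting the reference list would instead produce one `R3.1.reference`
ERROR and exit status 1. The first column is the *statement key* — a
digest over entities, relation and biological context (but not provenance),
so the same interaction observed in a different cell type gets a new key,
while a second paper reporting the same interaction does not.

Export the same statement as a signed SIF edge:

```console
$ mi2cast convert --in lyn.json --out-format sif
uniprotkb:P07948 -> uniprotkb:P29350
```

Generate a benchmark corpus with seeded violations and lint it:

```console
$ mi2cast generate --out demo.json --n 5 --seed 42 --rate R3.1.reference=0.5
wrote 5 statements to demo.json; 4 injected violations in demo.json.truth.tsv
$ mi2cast validate --in demo.json
statement_key	rule_id	severity	path	message
529b6679f27caf387b4d2981593bccbf	R3.1.reference	ERROR	evidence.references	the minimal sufficient set of supporting references is empty
...
```

The findings reproduce the sidecar ground truth exactly — the property the
test suite checks at corpus scale.

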