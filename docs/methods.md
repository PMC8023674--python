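# Methods

This note documents the model behind the package, the checkable semantics it
assigns to each checklist rule, the numerical/design choices that were
genuinely open, and what the bundled synthetic fixtures do and do not show.

## The data model

A causal statement is a record `(source, target, relation, evidence)`:

* **BioEntity** — a CURIE identifier, an optional biological (interactor)
  type, an optional component list (families and transient complexes), and
  an entity-level context.
* **CausalRelation** — the regulatory-effect term (restricted to the `ro`
  and `mi` namespaces), an optional mechanism term, and the optional
  modification the mechanism produces on the target (type, residue,
  1-based sequence position — protein residue numbering convention, so
  "Tyr-564" is position 564).
* **Evidence** — a *minimal sufficient* set of references (`pubmed`/`doi`,
  pairwise distinct, order-irrelevant), ECO evidence-type terms, and the
  interaction-level context. One statement corresponds to one minimal
  evidence set; an independent observation of the same interaction is a
  separate statement.
* **EntityContext** — activity, prior modification states, taxon, tissue,
  cell type/line, compartment, experimental-setup terms. Context lives
  both on each entity and at the interaction level; the package never
  copies between the two levels, because they mean different things (an
  entity's tissue vs the tissue the interaction was observed in).

Construction enforces only *structural* invariants (a position needs a
residue; components need a declared type and must be distinct; reference
namespaces are pubmed/doi). Checklist compliance is left to the validator,
and `source`/`target`/`relation` may be `None`, so that incomplete records
can be parsed and linted rather than rejected.

Isoforms are plain identifiers whose accession carries the isoform suffix
(`uniprotkb:P08631-2`); there is no separate isoform field.

### The statement key

`statement_key` is a SHA-256 digest (truncated to 128 bits) of a canonical
JSON rendering covering source, target, relation and the interaction-level
biological context, with all list-valued fields sorted. Provenance — the
references *and* the ECO evidence types — is excluded: context-distinct
observations get distinct keys, whereas the same interaction reported by
different papers or assessed by different evidence shares one key. This is
the identity notion used to group independent observations of one
context-specific causal interaction.

## Rule semantics and severities

Severity mapping: a "must" clause (including the conditional musts: the
component list of a complex/family-typed entity, and the biological type of
an entity on a namespace that implies none) yields **ERROR**;
"should/recommended" yields **WARNING**; advisory and unverifiable checks
yield **INFO**. Reports are sorted by `(path, rule_id)` — validation is a
pure function of (statement, configuration, loaded ontologies), and ties
are broken reproducibly.

The full catalogue (`mi2cast.findings.RULE_IDS`):

| rule id | max severity | checks |
|---|---|---|
| `R1.entity` | ERROR | source and target each carry an identifier |
| `R1.components` | ERROR | complex/family-typed entities list their components |
| `R2.relation` | ERROR | relation term inside RO:0002410 or MI:2233; WARNING for bare-root (unsigned) usage |
| `R3.1.reference` | ERROR | the reference list is non-empty (pubmed/doi enforced structurally) |
| `R3.2.evidence` | ERROR | evidence types present and inside the ECO branch |
| `R3.3.setup` | WARNING | experimental evidence carries setup terms; setup terms inside ECO ∪ MI:0346 ∪ OBI |
| `R4.1.activity` | WARNING | some activity or mechanism annotated; activity terms in the branch fitting the entity class (GO MF / ChEBI role / SO) |
| `R4.1.mechanism` | WARNING | mechanism inside MI:2245 ∪ MI:0190 ∪ GO BP; INFO suggestion of the equivalent direct mechanism |
| `R4.2.biotype` | ERROR | explicit type required on type-ambiguous namespaces; WARNING for non-MI:0313 or implied-type contradictions |
| `R4.3.modification` | WARNING | modifying mechanisms annotate the resulting target modification |
| `R4.4.taxon` | WARNING | taxa are numeric NCBI Taxonomy identifiers |
| `R4.5.location` | WARNING | tissue/cell/compartment terms inside their branches; INFO for kingdom mismatches |
| `X.syntax` | WARNING | accession matches its namespace pattern; known prefix |
| `X.unverifiable` | INFO | a term could not be resolved against the loaded ontologies |
| `X.obsolete` | WARNING | an obsolete term is used |

Decisions worth recording:

* **Branch membership** is reflexive-transitive `is_a` subsumption only.
  All branch constraints in the checklist are subsumption branches, so
  `part_of` and other relations are ignored by design.
* **Unknown terms** (absent from the loaded ontologies) give membership
  `UNKNOWN`, reported as an `X.unverifiable` INFO rather than an error:
  the checklist must remain usable without full ontology downloads.
  Obsolete terms keep their membership but add an `X.obsolete` WARNING.
* **"Lowest possible level term"** is not decidable from an ontology alone
  (it depends on what the evidence justifies). The implemented proxy flags
  only the degenerate case — using a bare branch *root* as the causal
  relation (unsigned, undirected) — as a WARNING. Any non-root term
  passes.
* **Accession syntax** findings (`X.syntax`: unknown prefix, or accession
  not matching the namespace's pattern) are WARNING, not ERROR: the
  identifier *was* provided, which is what the mandatory clause demands;
  the recommended-database patterns are best practice. The Swiss-Prot vs
  TrEMBL preference is not syntax-decidable at all and is therefore a
  CLI-verbose curation note, not a finding.
* **Taxon** checks (`R4.4`) are WARNING: NCBI Taxonomy is the recommended,
  not the only permissible, namespace.
* **Direct-vs-indirect consistency** (e.g. a transcriptional mechanism
  combined with a "directly regulates" relation) is *not* cross-checked —
  there is no decision procedure for it; only branch membership is
  enforced.
* **Activity⇔mechanism equivalence** (kinase activity GO:0016301 ⇔
  phosphorylation reaction MI:0217, phosphatase activity GO:0016791 ⇔
  dephosphorylation MI:0203) ships as an extensible two-column table whose
  bijectivity is enforced at load. When a statement annotates a mapped
  activity but no mechanism, the validator emits an INFO suggesting the
  equivalent mechanism term.
* **Kingdom mismatches** in tissue annotation (a Plant/Fungal Anatomy
  Ontology term next to a metazoan taxon) are INFO, based on a small
  built-in taxon→kingdom table; anything beyond that would require the
  taxonomy itself.
* **Translocation** statements keep the origin compartment on the entity;
  the destination is conveyed by the mechanism term (e.g. GO:0051170,
  import into nucleus) and is checked only as branch membership.
* `compliance_level` summarizes a report: `non_compliant` (any ERROR),
  `minimum` (core rules met, but some recommended context flagged absent),
  `context_enriched` (neither).

## Serialization

* **JSON** is the canonical lossless dialect: sorted keys, a versioned
  `mi2cast_schema` header, explicit `null` for an absent source, target or
  relation (a *missing* key is a malformed document and yields a parse
  error naming the path). `read(write(S)) == S` field-for-field.
* **MITAB 2.8** uses the standard's 46 columns. Native homes: interactor
  ids (1–2), publications (9), taxids (10, 11, 29 for the interaction),
  interactor types (21–22), prior modification states as features (37–38,
  rendered `type:pos-pos(residue)`), biological effects (43–44), causal
  regulatory mechanism (45), causal statement (46, the relation CURIE with
  its quoted term name, e.g. `psi-mi:"MI:2235"(up-regulates)`). Fields
  with no MITAB home — components, per-entity locations and setup,
  interaction-level locations, ECO evidence types, the resulting target
  modification — go into the annotation columns (26–28) under reserved
  `mi2cast-*` topics, which keeps the round trip lossless without
  violating the column semantics. ECO terms are *never* placed in the
  interaction-detection-method column, because no ECO→MI cross-reference
  table is bundled to justify it. Reading inverts the mapping exactly.
* **SIF** is lossy by design (no reader): one
  `source <token> target` line per statement, with the token chosen by the
  relation term's position under the positive (RO:0002213, MI:2235) or
  negative (RO:0002212, MI:2240) sub-branches — `->`, `-|`, or `--` when
  the sign is not derivable. The token map is configurable.

All writers are deterministic: identical input produces byte-identical
output.

## The synthetic generator and fixtures

`fixtures.generate(ViolationSpec(n, seed, rates))` draws statements from
seven templates that emulate common curated patterns — kinase/phosphatase
modification, chemical inhibition, transcription-factor regulation of a
gene, nuclear import, complex- and family-sourced regulation, and a
gene-database fallback identifier with an explicit protein type. Clean
statements are fully context-enriched on purpose (activity *and* mechanism,
taxon, compartment, setup, cell/tissue at the interaction level), so a
clean statement validates with **zero** findings of any severity; that
makes exact finding-multiset comparison possible.

Violations are injected per rule as independent Bernoulli draws at the
configured rates, one corruption site per rule (drop the target; replace
the source with a component-less complex; swap the relation into the
interactor-type branch; empty the references or evidence types; strip the
declared type off a fallback-namespace entity; force a modifying mechanism
and delete the resulting modification; malform the source accession). The
sites are disjoint, so corruptions never cascade into extra findings; the
single designed overlap — dropping the target erases a co-drawn
biological-type corruption on that target — is resolved in the ground
truth, which always records the *effective* finding multiset. Per-rule
injected counts are deterministic functions of the seed. A single explicit
`random.Random(seed)` stream drives template choice, vocabulary sampling
and injection; there is no global random state.

The bundled mini-ontologies (≤ 30 terms each) contain every term id the
rules reference, connected by plausible `is_a` paths; filler terms whose
real ids were not verifiable use stand-in ids and each file is labeled
synthetic. Likewise the generator's accessions are syntactically valid
stand-ins, not curated biological claims.

**What passing therefore shows** — that the validator, generator, registry
and serializers agree exactly with each other and with the checklist's
decidable semantics under realistic record shapes. **What it does not
show** — performance on full ontology releases, detection of biologically
implausible but well-formed annotations, statistical realism of curated
networks, or accession existence in live databases.

## Problem sizes and tolerances

The equivalence benchmark uses n = 1000 statements at rate 0.1 per seedable
rule (about 800 injected violations), and the branch-membership oracle an
exhaustive 200-term × 200-root comparison (40 000 pairs) against a
memoization-free DFS; both complete in about a second and leave generous
headroom, and the agreement criteria are exact (precision = recall = 1.0,
zero disagreements) rather than toleranced — every check here is discrete,
so nothing is compared approximately.

## Known limitations

* The registry ships one curated table; real curation workflows may need
  resource-specific namespaces (edit or replace `data/namespaces.tsv`).
* Minimality/sufficiency of a reference set is not verifiable — only
  non-emptiness and well-formedness are checked.
* Interaction-level taxon is recorded but never cross-checked against
  entity taxa (heterologous assays make equality a non-requirement).
* MITAB cells written by other tools may use conventions (e.g. multiple
  ids per column, checksum columns) the reader does not interpret; the
  reader targets the documented mapping plus `-` placeholders.
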