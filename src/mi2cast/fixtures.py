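"""Synthetic causal-statement generator with seeded rule violations.

The generator emits fully context-enriched statements built from the bundled
fixture vocabulary (entity classes with their recommended namespaces, causal
relation terms from the RO/PSI-MI causal branches, ECO evidence, context
terms) and, on request, injects precisely known violations.  Each injected
violation is a minimal corruption of its own statement site, so corruptions
never interact; the accompanying :class:`GroundTruth` lists the exact
(rule_id, path) findings the validator must produce.  A single explicit
pseudo-random stream drives everything — same seed, same corpus, byte for
byte.

The vocabulary emulates curated signaling/regulation statements; it makes no
attempt at statistical realism of biological networks (degree distributions
and the like are out of scope).  Identifiers are syntactically valid
accessions used as stand-ins, not curated claims about the named molecules.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

from .model import (
    BioEntity,
    CausalRelation,
    CausalStatement,
    EntityContext,
    Evidence,
    Identifier,
    ModificationState,
)
from .registry import parse_identifier as _id

__all__ = ["ViolationSpec", "GroundTruth", "generate", "worked_example", "SEEDABLE_RULES"]

#: rule ids the generator can seed violations for
SEEDABLE_RULES = (
    "R1.entity",
    "R1.components",
    "R2.relation",
    "R3.1.reference",
    "R3.2.evidence",
    "R4.2.biotype",
    "R4.3.modification",
    "X.syntax",
)


@dataclass(frozen=True)
class ViolationSpec:
    """How many statements to generate and the per-rule corruption rates."""

    n: int
    seed: int
    rates: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for rule_id, rate in self.rates.items():
            if rule_id not in SEEDABLE_RULES:
                raise ValueError(
                    f"cannot seed violations for {rule_id!r}; "
                    f"seedable: {', '.join(SEEDABLE_RULES)}"
                )
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate for {rule_id} must be in [0, 1], got {rate}")


@dataclass(frozen=True)
class GroundTruth:
    """Per-statement multisets of injected (rule_id, path) violations.

    ``violations[i]`` is the exact sorted tuple of findings statement *i*
    must trigger; empty for statements generated valid.
    """

    violations: Tuple[Tuple[Tuple[str, str], ...], ...]

    def counts(self) -> Counter:
        return Counter(rule_id for stmt in self.violations for rule_id, _ in stmt)

    def __len__(self) -> int:
        return len(self.violations)


# ---------------------------------------------------------------------------
# vocabulary pools (all accessions syntactically valid for their namespace)

_PROTEINS = ["uniprotkb:P08631", "uniprotkb:P29350", "uniprotkb:P04637",
             "uniprotkb:Q9Y243", "uniprotkb:O15530", "uniprotkb:P42345"]
_GENES = ["ensembl:ENSG00000141510", "ensembl:ENSG00000254087",
          "ensembl:ENSG00000171791"]
_CHEMICALS = ["chebi:15422", "chebi:16240", "chebi:45863"]
_TAXA = ["ncbitaxon:9606", "ncbitaxon:10090"]
_CELLS = ["cl:0000084", "cl:0000057", "cl:0000236"]
_COMPARTMENTS = ["go:0005829", "go:0005634", "go:0005737", "go:0005886"]
_TISSUES = ["bto:0000089", "bto:0000142", "uberon:0002107"]
_EVIDENCE = ["eco:0000006", "eco:0005805", "eco:0000068", "eco:0000270"]
_SETUP = ["mi:0506", "mi:0331"]
_POSITIVE_RELATIONS = ["ro:0002213", "ro:0002629", "mi:2235", "mi:2236"]
_NEGATIVE_RELATIONS = ["ro:0002212", "ro:0002630", "mi:2240", "mi:2241"]

_PHOSPHO_EFFECTS = [("mod:00048", "chebi:46858"), ("mod:00046", "chebi:29999")]


def _context(rng: random.Random, activity: Optional[str], with_setup: bool) -> EntityContext:
    return EntityContext(
        biological_activity=_id(activity) if activity else None,
        taxon=_id(rng.choice(_TAXA)),
        compartment=_id(rng.choice(_COMPARTMENTS)),
        experimental_setup=(_id(rng.choice(_SETUP)),) if with_setup else (),
    )


def _protein(rng: random.Random, activity: str, with_setup: bool) -> BioEntity:
    return BioEntity(
        identifier=_id(rng.choice(_PROTEINS)),
        context=_context(rng, activity, with_setup),
    )


def _modifying_relation(rng: random.Random, positive: bool) -> CausalRelation:
    mech, effects = rng.choice(
        [("mi:0217", _PHOSPHO_EFFECTS), ("mi:0203", [("mod:01875", "chebi:46858")])]
    )
    mod_type, residue = rng.choice(effects)
    pool = _POSITIVE_RELATIONS if positive else _NEGATIVE_RELATIONS
    return CausalRelation(
        relation_term=_id(rng.choice(pool)),
        mechanism=_id(mech),
        target_modification_effect=ModificationState(
            modification_type=_id(mod_type),
            residue=_id(residue),
            position=rng.randint(1, 999),
        ),
    )


def _evidence(rng: random.Random) -> Evidence:
    return Evidence(
        references=(_id(f"pubmed:{rng.randint(1_000_000, 35_000_000)}"),),
        evidence_types=(_id(rng.choice(_EVIDENCE)),),
        interaction_context=EntityContext(
            taxon=_id(rng.choice(_TAXA)),
            cell=_id(rng.choice(_CELLS)),
            tissue=_id(rng.choice(_TISSUES)),
        ),
    )


def _template_kinase(rng: random.Random) -> CausalStatement:
    """A phosphorylates B (direct, signed, with resulting phospho-site)."""
    return CausalStatement(
        source=_protein(rng, "go:0016301", with_setup=True),
        target=_protein(rng, "go:0016791", with_setup=False),
        relation=_modifying_relation(rng, positive=rng.random() < 0.7),
        evidence=_evidence(rng),
    )


def _template_chemical(rng: random.Random) -> CausalStatement:
    """Small molecule inhibits a protein through direct interaction."""
    return CausalStatement(
        source=BioEntity(
            identifier=_id(rng.choice(_CHEMICALS)),
            context=_context(rng, "chebi:35222", with_setup=True),
        ),
        target=_protein(rng, "go:0016301", with_setup=False),
        relation=CausalRelation(
            relation_term=_id(rng.choice(_NEGATIVE_RELATIONS)),
            mechanism=_id("mi:0407"),
        ),
        evidence=_evidence(rng),
    )


def _template_tf(rng: random.Random) -> CausalStatement:
    """Transcription factor up-regulates a gene (indirect, transcriptional)."""
    return CausalStatement(
        source=_protein(rng, "go:0003700", with_setup=True),
        target=BioEntity(
            identifier=_id(rng.choice(_GENES)),
            biological_type=_id("mi:0250"),
            context=_context(rng, "so:0000409", with_setup=False),
        ),
        relation=CausalRelation(
            relation_term=_id(rng.choice(_POSITIVE_RELATIONS)),
            mechanism=_id("mi:2246"),
        ),
        evidence=_evidence(rng),
    )


def _template_translocation(rng: random.Random) -> CausalStatement:
    """Source drives nuclear import of the target (origin compartment kept
    on the entity; destination conveyed by the mechanism term)."""
    target = BioEntity(
        identifier=_id(rng.choice(_PROTEINS)),
        context=replace(
            _context(rng, "go:0003700", with_setup=False),
            compartment=_id("go:0005737"),
        ),
    )
    return CausalStatement(
        source=_protein(rng, "go:0005488", with_setup=True),
        target=target,
        relation=CausalRelation(
            relation_term=_id(rng.choice(_POSITIVE_RELATIONS)),
            mechanism=_id("go:0051170"),
        ),
        evidence=_evidence(rng),
    )


def _template_complex(rng: random.Random) -> CausalStatement:
    """A transient complex regulates a protein; components listed."""
    members = rng.sample(_PROTEINS, 2)
    return CausalStatement(
        source=BioEntity(
            identifier=_id(f"complexportal:CPX-{rng.randint(1, 9999)}"),
            biological_type=_id("mi:0314"),
            components=tuple(_id(m) for m in members),
            context=_context(rng, "go:0005488", with_setup=True),
        ),
        target=_protein(rng, "go:0016301", with_setup=False),
        relation=CausalRelation(
            relation_term=_id(rng.choice(_POSITIVE_RELATIONS)),
            mechanism=_id("mi:0407"),
        ),
        evidence=_evidence(rng),
    )


def _template_family(rng: random.Random) -> CausalStatement:
    """A kinase family phosphorylates a target; members listed."""
    members = rng.sample(_PROTEINS, 3)
    return CausalStatement(
        source=BioEntity(
            identifier=_id(f"interpro:IPR{rng.randint(0, 999999):06d}"),
            biological_type=_id("mi:1304"),
            components=tuple(_id(m) for m in members),
            context=_context(rng, "go:0016301", with_setup=True),
        ),
        target=_protein(rng, "go:0016791", with_setup=False),
        relation=_modifying_relation(rng, positive=True),
        evidence=_evidence(rng),
    )


def _template_fallback(rng: random.Random) -> CausalStatement:
    """Source carried by a gene-database fallback accession, with the
    mandatory explicit biological type."""
    stmt = _template_kinase(rng)
    source = replace(
        stmt.source,
        identifier=_id(f"ncbigene:{rng.randint(1, 99999)}"),
        biological_type=_id("mi:0326"),
    )
    return replace(stmt, source=source)


_TEMPLATES = (
    _template_kinase,
    _template_chemical,
    _template_tf,
    _template_translocation,
    _template_complex,
    _template_family,
    _template_fallback,
)


# ---------------------------------------------------------------------------
# corruption: one site per rule, applied in a fixed order so that the
# effective findings are exactly the recorded ground truth

def _corrupt(
    stmt: CausalStatement, drawn: List[str], rng: random.Random
) -> Tuple[CausalStatement, Tuple[Tuple[str, str], ...]]:
    truth: List[Tuple[str, str]] = []

    if "R1.components" in drawn:
        stmt = replace(
            stmt,
            source=BioEntity(
                identifier=_id(f"complexportal:CPX-{rng.randint(1, 9999)}"),
                biological_type=_id("mi:0314"),
                components=(),
                context=_context(rng, "go:0005488", with_setup=True),
            ),
        )
        truth.append(("R1.components", "source.components"))
    if "X.syntax" in drawn:
        bad = replace(stmt.source.identifier, local_id="not.a.valid.accession")
        stmt = replace(stmt, source=replace(stmt.source, identifier=bad))
        truth.append(("X.syntax", "source.identifier"))
    if "R4.2.biotype" in drawn:
        stmt = replace(
            stmt,
            target=BioEntity(
                identifier=_id(f"ncbigene:{rng.randint(1, 99999)}"),
                biological_type=None,
                context=_context(rng, "go:0016791", with_setup=False),
            ),
        )
        truth.append(("R4.2.biotype", "target.biological_type"))
    if "R1.entity" in drawn:
        # dropping the target erases a co-drawn R4.2 corruption
        truth = [t for t in truth if not t[1].startswith("target")]
        stmt = replace(stmt, target=None)
        truth.append(("R1.entity", "target"))
    if "R2.relation" in drawn:
        stmt = replace(
            stmt, relation=replace(stmt.relation, relation_term=_id("mi:0326"))
        )
        truth.append(("R2.relation", "relation.relation_term"))
    if "R4.3.modification" in drawn:
        stmt = replace(
            stmt,
            relation=replace(
                stmt.relation,
                mechanism=_id("mi:0217"),
                target_modification_effect=None,
            ),
        )
        truth.append(("R4.3.modification", "relation.target_modification_effect"))
    if "R3.1.reference" in drawn:
        stmt = replace(stmt, evidence=replace(stmt.evidence, references=()))
        truth.append(("R3.1.reference", "evidence.references"))
    if "R3.2.evidence" in drawn:
        stmt = replace(stmt, evidence=replace(stmt.evidence, evidence_types=()))
        truth.append(("R3.2.evidence", "evidence.evidence_types"))
    return stmt, tuple(sorted(truth))


def generate(spec: ViolationSpec) -> Tuple[List[CausalStatement], GroundTruth]:
    """Generate ``spec.n`` statements with violations seeded at
    ``spec.rates``; deterministic for a fixed seed."""
    rng = random.Random(spec.seed)
    statements: List[CausalStatement] = []
    truths: List[Tuple[Tuple[str, str], ...]] = []
    ordered_rules = [r for r in SEEDABLE_RULES if spec.rates.get(r, 0.0) > 0.0]
    for _ in range(spec.n):
        stmt = rng.choice(_TEMPLATES)(rng)
        drawn = [r for r in ordered_rules if rng.random() < spec.rates[r]]
        if drawn:
            stmt, truth = _corrupt(stmt, drawn, rng)
        else:
            truth = ()
        statements.append(stmt)
        truths.append(truth)
    return statements, GroundTruth(violations=tuple(truths))


def worked_example() -> CausalStatement:
    """The tyrosine-kinase statement used throughout the documentation:
    LYN phosphorylates the phosphatase PTPN6 at Tyr-564, stimulating its
    phosphatase activity.

    Encoded as: protein source (UniProtKB, kinase activity), direct positive
    relation with a phosphorylation mechanism, protein target with the
    resulting phospho-tyrosine at position 564 and the affected phosphatase
    activity, one PubMed reference, experimental evidence.
    """
    return CausalStatement(
        source=BioEntity(
            identifier=_id("uniprotkb:P07948"),
            context=EntityContext(
                biological_activity=_id("go:0016301"),
                taxon=_id("ncbitaxon:9606"),
            ),
        ),
        target=BioEntity(
            identifier=_id("uniprotkb:P29350"),
            context=EntityContext(
                biological_activity=_id("go:0004725"),
                taxon=_id("ncbitaxon:9606"),
            ),
        ),
        relation=CausalRelation(
            relation_term=_id("ro:0002629"),
            mechanism=_id("mi:0217"),
            target_modification_effect=ModificationState(
                modification_type=_id("mod:00048"),
                residue=_id("chebi:46858"),
                position=564,
            ),
        ),
        evidence=Evidence(
            references=(_id("pubmed:8995399"),),
            evidence_types=(_id("eco:0000006"),),
            interaction_context=EntityContext(taxon=_id("ncbitaxon:9606")),
        ),
    )
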