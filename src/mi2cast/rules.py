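"""The checklist rule engine.

Evaluates a :class:`~mi2cast.model.CausalStatement` against the four
annotation rules — entities (1), causal relation (2), provenance/evidence
(3), biological context (4) — and produces a deterministic, ordered
:class:`~mi2cast.findings.ValidationReport`.

Severity mapping: a "must" clause (including conditional musts such as the
component list of a complex, or the biological type of an entity carried by a
type-ambiguous fallback namespace) violates as ERROR; "should/recommended"
clauses as WARNING; purely informational or unverifiable checks as INFO.
All problems are findings — validation never raises on bad content.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Dict, List, Optional, Tuple

from .findings import Severity, ValidationFinding, ValidationReport
from .model import (
    BioEntity,
    CausalStatement,
    EntityContext,
    Identifier,
    statement_key,
)
from .ontology import (
    BranchSpec,
    Membership,
    OntologyIndex,
    in_branch,
    is_most_specific_usage,
    load_obo_dir,
)
from . import registry as _registry
from .registry import Registry, parse_identifier

__all__ = [
    "RuleConfig",
    "validate",
    "check_rule1",
    "check_rule2",
    "check_rule3",
    "check_rule4",
    "equivalent_mechanism",
    "equivalent_activity",
    "compliance_level",
    "default_branches",
]

_E = Severity.ERROR
_W = Severity.WARNING
_I = Severity.INFO


def _ids(*curies: str) -> frozenset:
    return frozenset(parse_identifier(c) for c in curies)


def default_branches() -> Dict[str, BranchSpec]:
    """Branch roots for every branch-membership check of the checklist."""
    return {
        # Rule 2: RO "causally related to" or PSI-MI "causal statement"
        "relation.ro": BranchSpec(_ids("ro:0002410"), "causally related to"),
        "relation.mi": BranchSpec(_ids("mi:2233"), "causal statement"),
        # Rule 3
        "evidence": BranchSpec(_ids("eco:0000000"), "evidence"),
        "experimental_evidence": BranchSpec(
            _ids("eco:0000006"), "experimental evidence"
        ),
        "setup": BranchSpec(
            _ids("eco:0000000", "mi:0346", "obi:0000011"),
            "experimental preparation",
        ),
        # Rule 4.1 activity branches by entity class
        "activity.protein": BranchSpec(_ids("go:0003674"), "GO molecular function"),
        "activity.rna": BranchSpec(_ids("go:0003674"), "GO molecular function"),
        "activity.chemical": BranchSpec(_ids("chebi:50906"), "ChEBI role"),
        "activity.gene": BranchSpec(_ids("so:0000110"), "sequence feature"),
        "activity.any": BranchSpec(
            _ids("go:0003674", "chebi:50906", "so:0000110"), "biological activity"
        ),
        "mechanism": BranchSpec(
            _ids("mi:2245", "mi:0190", "go:0008150"), "interaction mechanism"
        ),
        "modifying_mechanism": BranchSpec(_ids("mi:0414"), "enzymatic reaction"),
        # Rule 4.2
        "biotype": BranchSpec(_ids("mi:0313"), "interactor type"),
        "complex_or_family": BranchSpec(
            _ids("mi:0314", "mi:1304"), "complex or molecule set"
        ),
        # Rule 4.5
        "tissue": BranchSpec(
            _ids("bto:0000000", "uberon:0000479", "po:0025131", "fao:0000001"),
            "tissue",
        ),
        "cell": BranchSpec(_ids("cl:0000000", "bto:0000000"), "cell type"),
        "compartment": BranchSpec(_ids("go:0005575"), "GO cellular component"),
        # SIF sign extraction (used by the io module)
        "positive": BranchSpec(_ids("ro:0002213", "mi:2235"), "positive regulation"),
        "negative": BranchSpec(_ids("ro:0002212", "mi:2240"), "negative regulation"),
    }


#: interactor-type terms routing an entity to its activity branch
_TYPE_PROTEIN = parse_identifier("mi:0326")
_TYPE_RNA = parse_identifier("mi:0320")
_TYPE_CHEMICAL = parse_identifier("mi:0328")
_TYPE_GENE = parse_identifier("mi:0250")


@lru_cache(maxsize=4)
def _activity_mechanism_table() -> Tuple[Dict[Identifier, Identifier], ...]:
    text = (resources.files("mi2cast") / "data" / "activity_mechanism.tsv").read_text(
        encoding="utf-8"
    )
    rows = [
        line.split("\t")
        for line in text.splitlines()
        if line and not line.startswith("#")
    ]
    assert rows[0] == ["activity", "mechanism"]
    forward: Dict[Identifier, Identifier] = {}
    inverse: Dict[Identifier, Identifier] = {}
    for activity, mechanism in rows[1:]:
        a, m = parse_identifier(activity), parse_identifier(mechanism)
        if a in forward or m in inverse:
            raise ValueError("activity/mechanism mapping must be bijective")
        forward[a] = m
        inverse[m] = a
    return forward, inverse


def equivalent_mechanism(activity_term: Identifier) -> Optional[Identifier]:
    """Direct-interaction mechanism equivalent to a source activity
    (e.g. kinase activity <-> phosphorylation reaction), or None."""
    return _activity_mechanism_table()[0].get(activity_term)


def equivalent_activity(mechanism_term: Identifier) -> Optional[Identifier]:
    """Inverse of :func:`equivalent_mechanism`."""
    return _activity_mechanism_table()[1].get(mechanism_term)


@dataclass
class RuleConfig:
    """Validation configuration: profile, registry, ontology index, branches.

    ``profile="minimum"`` suppresses WARNING/INFO findings for bulk lint
    runs; ``"strict"`` reports everything.
    """

    profile: str = "strict"
    registry: Registry = field(default_factory=_registry.default_registry)
    index: OntologyIndex = None
    branches: Dict[str, BranchSpec] = field(default_factory=default_branches)

    def __post_init__(self) -> None:
        if self.profile not in ("minimum", "strict"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.index is None:
            self.index = load_obo_dir()

    @classmethod
    def default(cls, ontology_dir=None, profile: str = "strict") -> "RuleConfig":
        return cls(profile=profile, index=load_obo_dir(ontology_dir))


@lru_cache(maxsize=2)
def _default_config(profile: str = "strict") -> RuleConfig:
    return RuleConfig(profile=profile)


# ---------------------------------------------------------------------------
# helpers

def _finding(rule_id, severity, path, message, missing=False) -> ValidationFinding:
    return ValidationFinding(rule_id, severity, path, message, missing)


def _syntax_findings(cfg: RuleConfig, identifier: Identifier, path: str) -> List:
    out = [
        replace(f, path=path)
        for f in _registry.check_accession_syntax(identifier, cfg.registry)
    ]
    if cfg.index.is_obsolete(identifier):
        out.append(
            _finding(
                "X.obsolete",
                _W,
                path,
                f"{identifier.curie} is obsolete; use a current term",
            )
        )
    return out


def _branch_findings(
    cfg: RuleConfig,
    term: Identifier,
    branch_key: str,
    rule_id: str,
    severity: Severity,
    path: str,
) -> List:
    """NO -> a finding at `severity`; UNKNOWN -> an `unverifiable` INFO."""
    branch = cfg.branches[branch_key]
    membership = in_branch(term, branch, cfg.index)
    if membership is Membership.NO:
        return [
            _finding(
                rule_id,
                severity,
                path,
                f"{term.curie} is outside the {branch.label!r} branch",
            )
        ]
    if membership is Membership.UNKNOWN:
        return [
            _finding(
                "X.unverifiable",
                _I,
                path,
                f"{term.curie} cannot be resolved against the loaded ontologies",
            )
        ]
    return []


def _entity_type_term(cfg: RuleConfig, entity: BioEntity) -> Optional[Identifier]:
    if entity.biological_type is not None:
        return entity.biological_type
    return _registry.implied_biological_type(entity.identifier, cfg.registry)


def _activity_branch_key(cfg: RuleConfig, entity: BioEntity) -> str:
    type_term = _entity_type_term(cfg, entity)
    if type_term is None:
        return "activity.any"
    anc = cfg.index.ancestors(type_term) if type_term in cfg.index else {type_term}
    if _TYPE_PROTEIN in anc or _TYPE_RNA in anc:
        return "activity.protein"
    if _TYPE_CHEMICAL in anc:
        return "activity.chemical"
    if _TYPE_GENE in anc:
        return "activity.gene"
    return "activity.any"


def _context_sites(stmt: CausalStatement):
    """(path prefix, EntityContext) for source, target and interaction."""
    sites = []
    if stmt.source is not None:
        sites.append(("source.context", stmt.source.context))
    if stmt.target is not None:
        sites.append(("target.context", stmt.target.context))
    sites.append(("evidence.interaction_context", stmt.evidence.interaction_context))
    return sites


# ---------------------------------------------------------------------------
# cross-cutting identifier syntax / obsolescence sweep

def _check_identifiers(stmt: CausalStatement, cfg: RuleConfig) -> List:
    out: List[ValidationFinding] = []

    def walk_context(prefix: str, ctx: EntityContext):
        for name in ("biological_activity", "taxon", "tissue", "cell", "compartment"):
            term = getattr(ctx, name)
            if term is not None:
                out.extend(_syntax_findings(cfg, term, f"{prefix}.{name}"))
        for i, term in enumerate(ctx.experimental_setup):
            out.extend(_syntax_findings(cfg, term, f"{prefix}.experimental_setup[{i}]"))
        for i, mod in enumerate(ctx.modifications):
            base = f"{prefix}.modifications[{i}]"
            out.extend(
                _syntax_findings(cfg, mod.modification_type, f"{base}.modification_type")
            )
            if mod.residue is not None:
                out.extend(_syntax_findings(cfg, mod.residue, f"{base}.residue"))

    for side in ("source", "target"):
        entity = getattr(stmt, side)
        if entity is None:
            continue
        out.extend(_syntax_findings(cfg, entity.identifier, f"{side}.identifier"))
        if entity.biological_type is not None:
            out.extend(
                _syntax_findings(cfg, entity.biological_type, f"{side}.biological_type")
            )
        for i, comp in enumerate(entity.components):
            out.extend(_syntax_findings(cfg, comp, f"{side}.components[{i}]"))
        walk_context(f"{side}.context", entity.context)

    if stmt.relation is not None:
        rel = stmt.relation
        out.extend(_syntax_findings(cfg, rel.relation_term, "relation.relation_term"))
        if rel.mechanism is not None:
            out.extend(_syntax_findings(cfg, rel.mechanism, "relation.mechanism"))
        if rel.target_modification_effect is not None:
            eff = rel.target_modification_effect
            base = "relation.target_modification_effect"
            out.extend(
                _syntax_findings(cfg, eff.modification_type, f"{base}.modification_type")
            )
            if eff.residue is not None:
                out.extend(_syntax_findings(cfg, eff.residue, f"{base}.residue"))

    for i, ref in enumerate(stmt.evidence.references):
        out.extend(_syntax_findings(cfg, ref, f"evidence.references[{i}]"))
    for i, term in enumerate(stmt.evidence.evidence_types):
        out.extend(_syntax_findings(cfg, term, f"evidence.evidence_types[{i}]"))
    walk_context("evidence.interaction_context", stmt.evidence.interaction_context)
    return out


# ---------------------------------------------------------------------------
# the four rules

def check_rule1(stmt: CausalStatement, cfg: RuleConfig) -> List:
    """Source and target entities must be identified; a complex or family
    must list its components."""
    out: List[ValidationFinding] = []
    for side in ("source", "target"):
        entity = getattr(stmt, side)
        if entity is None:
            out.append(
                _finding(
                    "R1.entity", _E, side, f"the {side} entity is missing its identifier"
                )
            )
            continue
        type_term = entity.biological_type
        if (
            type_term is not None
            and in_branch(type_term, cfg.branches["complex_or_family"], cfg.index)
            is Membership.YES
            and not entity.components
        ):
            out.append(
                _finding(
                    "R1.components",
                    _E,
                    f"{side}.components",
                    f"a {cfg.index.name(type_term) or type_term.curie} must list "
                    "its component entities",
                )
            )
    return out


def check_rule2(stmt: CausalStatement, cfg: RuleConfig) -> List:
    """The regulatory effect must be a term from the RO 'causally related
    to' branch or the PSI-MI 'causal statement' branch."""
    if stmt.relation is None:
        return [
            _finding("R2.relation", _E, "relation", "the causal relation is missing")
        ]
    term = stmt.relation.relation_term
    ro = in_branch(term, cfg.branches["relation.ro"], cfg.index)
    mi = in_branch(term, cfg.branches["relation.mi"], cfg.index)
    path = "relation.relation_term"
    if Membership.YES in (ro, mi):
        out = []
        if not (
            is_most_specific_usage(term, cfg.branches["relation.ro"], cfg.index)
            and is_most_specific_usage(term, cfg.branches["relation.mi"], cfg.index)
        ):
            out.append(
                _finding(
                    "R2.relation",
                    _W,
                    path,
                    f"{term.curie} is a bare causal-branch root (unsigned, "
                    "undirected); use the most specific term the evidence "
                    "justifies",
                )
            )
        return out
    if ro is Membership.NO and mi is Membership.NO:
        return [
            _finding(
                "R2.relation",
                _E,
                path,
                f"{term.curie} is in neither causal-relation branch",
            )
        ]
    return [
        _finding(
            "X.unverifiable",
            _I,
            path,
            f"{term.curie} cannot be resolved against the loaded ontologies",
        )
    ]


def check_rule3(stmt: CausalStatement, cfg: RuleConfig) -> List:
    """References and evidence types must be given; experimental evidence
    should come with experimental-setup qualifiers."""
    out: List[ValidationFinding] = []
    ev = stmt.evidence
    if not ev.references:
        out.append(
            _finding(
                "R3.1.reference",
                _E,
                "evidence.references",
                "the minimal sufficient set of supporting references is empty",
            )
        )
    if not ev.evidence_types:
        out.append(
            _finding(
                "R3.2.evidence",
                _E,
                "evidence.evidence_types",
                "no evidence type (ECO term) is given",
            )
        )
    experimental = False
    for i, term in enumerate(ev.evidence_types):
        path = f"evidence.evidence_types[{i}]"
        out.extend(_branch_findings(cfg, term, "evidence", "R3.2.evidence", _E, path))
        if (
            in_branch(term, cfg.branches["experimental_evidence"], cfg.index)
            is Membership.YES
        ):
            experimental = True
    setup_terms = []
    for prefix, ctx in _context_sites(stmt):
        for i, term in enumerate(ctx.experimental_setup):
            setup_terms.append((f"{prefix}.experimental_setup[{i}]", term))
    if experimental and not setup_terms:
        out.append(
            _finding(
                "R3.3.setup",
                _W,
                "evidence.interaction_context.experimental_setup",
                "experimental evidence without experimental-setup qualifiers",
                missing=True,
            )
        )
    for path, term in setup_terms:
        out.extend(_branch_findings(cfg, term, "setup", "R3.3.setup", _W, path))
    return out


def check_rule4(stmt: CausalStatement, cfg: RuleConfig) -> List:
    """Contextual details: activity/mechanism, biological type, resulting
    modification, taxon, locations."""
    out: List[ValidationFinding] = []
    mechanism = stmt.relation.mechanism if stmt.relation is not None else None

    # 4.1 — activity of the entities / mechanism of the interaction
    source_activity = (
        stmt.source.context.biological_activity if stmt.source is not None else None
    )
    if stmt.source is not None and source_activity is None and mechanism is None:
        out.append(
            _finding(
                "R4.1.activity",
                _W,
                "source.context.biological_activity",
                "neither the source activity nor an interaction mechanism is "
                "annotated",
                missing=True,
            )
        )
    for side in ("source", "target"):
        entity = getattr(stmt, side)
        if entity is None or entity.context.biological_activity is None:
            continue
        out.extend(
            _branch_findings(
                cfg,
                entity.context.biological_activity,
                _activity_branch_key(cfg, entity),
                "R4.1.activity",
                _W,
                f"{side}.context.biological_activity",
            )
        )
    if mechanism is not None:
        out.extend(
            _branch_findings(
                cfg, mechanism, "mechanism", "R4.1.mechanism", _W, "relation.mechanism"
            )
        )
    elif source_activity is not None:
        suggestion = equivalent_mechanism(source_activity)
        if suggestion is not None:
            out.append(
                _finding(
                    "R4.1.mechanism",
                    _I,
                    "relation.mechanism",
                    f"the source activity {source_activity.curie} corresponds to "
                    f"the direct mechanism {suggestion.curie} "
                    f"({cfg.index.name(suggestion) or 'direct interaction'})",
                )
            )

    # 4.2 — biological type
    for side in ("source", "target"):
        entity = getattr(stmt, side)
        if entity is None:
            continue
        implied = _registry.implied_biological_type(entity.identifier, cfg.registry)
        declared = entity.biological_type
        path = f"{side}.biological_type"
        if implied is None and declared is None:
            out.append(
                _finding(
                    "R4.2.biotype",
                    _E,
                    path,
                    f"the namespace {entity.identifier.prefix!r} implies no "
                    "biological type, so the type must be annotated explicitly",
                )
            )
        if declared is not None:
            out.extend(
                _branch_findings(cfg, declared, "biotype", "R4.2.biotype", _W, path)
            )
            if (
                implied is not None
                and in_branch(declared, BranchSpec(frozenset({implied})), cfg.index)
                is Membership.NO
            ):
                out.append(
                    _finding(
                        "R4.2.biotype",
                        _W,
                        path,
                        f"declared type {declared.curie} contradicts the type "
                        f"implied by {entity.identifier.prefix!r} ({implied.curie})",
                    )
                )

    # 4.3 — resulting modification of the target
    if (
        mechanism is not None
        and in_branch(mechanism, cfg.branches["modifying_mechanism"], cfg.index)
        is Membership.YES
        and stmt.relation.target_modification_effect is None
    ):
        out.append(
            _finding(
                "R4.3.modification",
                _W,
                "relation.target_modification_effect",
                f"the mechanism {mechanism.curie} modifies the target; annotate "
                "the resulting modification (type, residue, position)",
                missing=True,
            )
        )

    # 4.4 — taxon
    taxa = []
    for prefix, ctx in _context_sites(stmt):
        if ctx.taxon is not None:
            taxa.append((f"{prefix}.taxon", ctx.taxon))
            if ctx.taxon.prefix != "ncbitaxon" or not ctx.taxon.local_id.isdigit():
                out.append(
                    _finding(
                        "R4.4.taxon",
                        _W,
                        f"{prefix}.taxon",
                        f"{ctx.taxon.curie} is not a numeric NCBI Taxonomy "
                        "identifier",
                    )
                )

    # 4.5 — locations
    _METAZOAN = {"9606", "10090", "10116", "7227", "6239", "7955"}
    _KINGDOM_OF_NS = {"po": "plant", "fao": "fungi"}
    for prefix, ctx in _context_sites(stmt):
        if ctx.tissue is not None:
            out.extend(
                _branch_findings(
                    cfg, ctx.tissue, "tissue", "R4.5.location", _W, f"{prefix}.tissue"
                )
            )
            kingdom = _KINGDOM_OF_NS.get(ctx.tissue.prefix)
            if kingdom and any(t.local_id in _METAZOAN for _, t in taxa):
                out.append(
                    _finding(
                        "R4.5.location",
                        _I,
                        f"{prefix}.tissue",
                        f"a {kingdom} anatomy term is annotated together with a "
                        "metazoan taxon",
                    )
                )
        if ctx.cell is not None and ctx.cell.prefix != "cellosaurus":
            # cell lines (Cellosaurus) are registry/syntax-checked only
            out.extend(
                _branch_findings(
                    cfg, ctx.cell, "cell", "R4.5.location", _W, f"{prefix}.cell"
                )
            )
        if ctx.compartment is not None:
            out.extend(
                _branch_findings(
                    cfg,
                    ctx.compartment,
                    "compartment",
                    "R4.5.location",
                    _W,
                    f"{prefix}.compartment",
                )
            )
    return out


# ---------------------------------------------------------------------------

def validate(stmt: CausalStatement, cfg: Optional[RuleConfig] = None) -> ValidationReport:
    """Evaluate a statement against the full checklist.

    Pure function of (statement, configuration, loaded ontologies): the same
    inputs always give an identical report, with findings sorted by
    (path, rule_id).
    """
    cfg = cfg or _default_config()
    findings = (
        _check_identifiers(stmt, cfg)
        + check_rule1(stmt, cfg)
        + check_rule2(stmt, cfg)
        + check_rule3(stmt, cfg)
        + check_rule4(stmt, cfg)
    )
    if cfg.profile == "minimum":
        findings = [f for f in findings if f.severity is _E]
    return ValidationReport(findings=tuple(findings), statement_ref=statement_key(stmt))


def compliance_level(report: ValidationReport) -> str:
    """Summarize a report: ``non_compliant`` (any ERROR), ``minimum`` (core
    rules met but some recommended context absent), or
    ``context_enriched``."""
    if report.errors:
        return "non_compliant"
    if any(f.missing and f.rule_id.startswith("R4") for f in report.findings):
        return "minimum"
    return "context_enriched"
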