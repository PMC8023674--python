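"""Serialization: canonical JSON, PSI-MITAB 2.8 causal columns, SIF export.

The JSON dialect is lossless on the full model (read(write(S)) == S,
field-for-field).  MITAB 2.8 carries the standard's 46 tab-delimited columns;
fields with a native MITAB home use it (interactor ids, taxids, interactor
types, publication ids, the four trailing causal columns, feature columns),
and fields without one (per-entity locations, experimental setup, complex
components, ECO evidence types, the resulting target modification) are
serialized into the annotation columns under reserved ``mi2cast-*`` topics,
keeping the round trip lossless.  SIF is a deliberately lossy signed-edge
export with no reader.

All writers are deterministic: identical input gives byte-identical output.
"""

from __future__ import annotations

import json
import re
from typing import Dict, List, Optional, Sequence

from .model import (
    BioEntity,
    CausalRelation,
    CausalStatement,
    EntityContext,
    Evidence,
    Identifier,
    ModificationState,
)
from .ontology import Membership, OntologyIndex, in_branch, load_obo_dir
from .registry import ParseError as CurieParseError
from .registry import default_registry, parse_identifier

__all__ = [
    "ParseError",
    "SCHEMA_VERSION",
    "write_json",
    "read_json",
    "write_mitab28",
    "read_mitab28",
    "export_sif",
    "MITAB28_COLUMNS",
]

SCHEMA_VERSION = "1.0"


class ParseError(ValueError):
    """Malformed document; ``path`` locates the offending element."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


# ===========================================================================
# canonical JSON

def _mod_to_dict(mod: ModificationState) -> dict:
    out = {"modification_type": mod.modification_type.curie}
    if mod.residue is not None:
        out["residue"] = mod.residue.curie
    if mod.position is not None:
        out["position"] = mod.position
    return out


def _context_to_dict(ctx: EntityContext) -> dict:
    out: dict = {}
    for name in ("biological_activity", "taxon", "tissue", "cell", "compartment"):
        value = getattr(ctx, name)
        if value is not None:
            out[name] = value.curie
    if ctx.modifications:
        out["modifications"] = [_mod_to_dict(m) for m in ctx.modifications]
    if ctx.experimental_setup:
        out["experimental_setup"] = [t.curie for t in ctx.experimental_setup]
    return out


def _entity_to_dict(entity: BioEntity) -> dict:
    out: dict = {"identifier": entity.identifier.curie}
    if entity.biological_type is not None:
        out["biological_type"] = entity.biological_type.curie
    if entity.components:
        out["components"] = [c.curie for c in entity.components]
    ctx = _context_to_dict(entity.context)
    if ctx:
        out["context"] = ctx
    return out


def statement_to_dict(stmt: CausalStatement) -> dict:
    """Canonical dict form.  The four top-level keys are always present;
    an absent source/target/relation is an explicit ``null`` (a record with
    the key *missing* is malformed, not incomplete)."""
    out: dict = {
        "source": _entity_to_dict(stmt.source) if stmt.source is not None else None,
        "target": _entity_to_dict(stmt.target) if stmt.target is not None else None,
    }
    if stmt.relation is not None:
        rel: dict = {"relation_term": stmt.relation.relation_term.curie}
        if stmt.relation.mechanism is not None:
            rel["mechanism"] = stmt.relation.mechanism.curie
        if stmt.relation.target_modification_effect is not None:
            rel["target_modification_effect"] = _mod_to_dict(
                stmt.relation.target_modification_effect
            )
        out["relation"] = rel
    else:
        out["relation"] = None
    ev: dict = {}
    if stmt.evidence.references:
        ev["references"] = [r.curie for r in stmt.evidence.references]
    if stmt.evidence.evidence_types:
        ev["evidence_types"] = [t.curie for t in stmt.evidence.evidence_types]
    ctx = _context_to_dict(stmt.evidence.interaction_context)
    if ctx:
        ev["interaction_context"] = ctx
    out["evidence"] = ev
    return out


def _need(mapping: dict, path: str) -> dict:
    if not isinstance(mapping, dict):
        raise ParseError(path, f"expected an object, got {type(mapping).__name__}")
    return mapping


def _curie(value, path: str) -> Identifier:
    if not isinstance(value, str):
        raise ParseError(path, "expected a CURIE string")
    try:
        return parse_identifier(value)
    except CurieParseError as exc:
        raise ParseError(path, str(exc)) from exc


def _mod_from_dict(data, path: str) -> ModificationState:
    data = _need(data, path)
    if "modification_type" not in data:
        raise ParseError(f"{path}.modification_type", "missing required key")
    position = data.get("position")
    if position is not None and not isinstance(position, int):
        raise ParseError(f"{path}.position", "expected an integer")
    return ModificationState(
        modification_type=_curie(data["modification_type"], f"{path}.modification_type"),
        residue=(
            _curie(data["residue"], f"{path}.residue") if "residue" in data else None
        ),
        position=position,
    )


def _context_from_dict(data, path: str) -> EntityContext:
    data = _need(data, path)
    kwargs: dict = {}
    for name in ("biological_activity", "taxon", "tissue", "cell", "compartment"):
        if name in data:
            kwargs[name] = _curie(data[name], f"{path}.{name}")
    if "modifications" in data:
        kwargs["modifications"] = tuple(
            _mod_from_dict(m, f"{path}.modifications[{i}]")
            for i, m in enumerate(data["modifications"])
        )
    if "experimental_setup" in data:
        kwargs["experimental_setup"] = tuple(
            _curie(t, f"{path}.experimental_setup[{i}]")
            for i, t in enumerate(data["experimental_setup"])
        )
    return EntityContext(**kwargs)


def _entity_from_dict(data, path: str) -> BioEntity:
    data = _need(data, path)
    if "identifier" not in data:
        raise ParseError(f"{path}.identifier", "missing required key")
    return BioEntity(
        identifier=_curie(data["identifier"], f"{path}.identifier"),
        biological_type=(
            _curie(data["biological_type"], f"{path}.biological_type")
            if "biological_type" in data
            else None
        ),
        components=tuple(
            _curie(c, f"{path}.components[{i}]")
            for i, c in enumerate(data.get("components", ()))
        ),
        context=_context_from_dict(data.get("context", {}), f"{path}.context"),
    )


def statement_from_dict(data, path: str = "statement") -> CausalStatement:
    data = _need(data, path)
    for key in ("source", "target", "relation", "evidence"):
        if key not in data:
            raise ParseError(f"{path}.{key}", "missing required key")
    relation = None
    if data["relation"] is not None:
        rel = _need(data["relation"], f"{path}.relation")
        if "relation_term" not in rel:
            raise ParseError(f"{path}.relation.relation_term", "missing required key")
        relation = CausalRelation(
            relation_term=_curie(rel["relation_term"], f"{path}.relation.relation_term"),
            mechanism=(
                _curie(rel["mechanism"], f"{path}.relation.mechanism")
                if "mechanism" in rel
                else None
            ),
            target_modification_effect=(
                _mod_from_dict(
                    rel["target_modification_effect"],
                    f"{path}.relation.target_modification_effect",
                )
                if "target_modification_effect" in rel
                else None
            ),
        )
    ev = _need(data["evidence"], f"{path}.evidence")
    evidence = Evidence(
        references=tuple(
            _curie(r, f"{path}.evidence.references[{i}]")
            for i, r in enumerate(ev.get("references", ()))
        ),
        evidence_types=tuple(
            _curie(t, f"{path}.evidence.evidence_types[{i}]")
            for i, t in enumerate(ev.get("evidence_types", ()))
        ),
        interaction_context=_context_from_dict(
            ev.get("interaction_context", {}), f"{path}.evidence.interaction_context"
        ),
    )
    return CausalStatement(
        source=(
            _entity_from_dict(data["source"], f"{path}.source")
            if data["source"] is not None
            else None
        ),
        target=(
            _entity_from_dict(data["target"], f"{path}.target")
            if data["target"] is not None
            else None
        ),
        relation=relation,
        evidence=evidence,
    )


def write_json(stmts: Sequence[CausalStatement]) -> str:
    document = {
        "mi2cast_schema": SCHEMA_VERSION,
        "statements": [statement_to_dict(s) for s in stmts],
    }
    return json.dumps(document, sort_keys=True, indent=1) + "\n"


def read_json(document: str) -> List[CausalStatement]:
    try:
        data = json.loads(document)
    except json.JSONDecodeError as exc:
        raise ParseError("$", f"not valid JSON: {exc}") from exc
    data = _need(data, "$")
    version = data.get("mi2cast_schema")
    if version != SCHEMA_VERSION:
        raise ParseError(
            "$.mi2cast_schema",
            f"unsupported schema version {version!r} (expected {SCHEMA_VERSION!r})",
        )
    statements = data.get("statements")
    if not isinstance(statements, list):
        raise ParseError("$.statements", "missing or not a list")
    return [
        statement_from_dict(s, f"$.statements[{i}]") for i, s in enumerate(statements)
    ]


# ===========================================================================
# PSI-MITAB 2.8

MITAB28_COLUMNS = (
    "ID(s) interactor A",
    "ID(s) interactor B",
    "Alt. ID(s) interactor A",
    "Alt. ID(s) interactor B",
    "Alias(es) interactor A",
    "Alias(es) interactor B",
    "Interaction detection method(s)",
    "Publication 1st author(s)",
    "Publication Identifier(s)",
    "Taxid interactor A",
    "Taxid interactor B",
    "Interaction type(s)",
    "Source database(s)",
    "Interaction identifier(s)",
    "Confidence value(s)",
    "Expansion method(s)",
    "Biological role(s) interactor A",
    "Biological role(s) interactor B",
    "Experimental role(s) interactor A",
    "Experimental role(s) interactor B",
    "Type(s) interactor A",
    "Type(s) interactor B",
    "Xref(s) interactor A",
    "Xref(s) interactor B",
    "Interaction Xref(s)",
    "Annotation(s) interactor A",
    "Annotation(s) interactor B",
    "Interaction annotation(s)",
    "Host organism(s)",
    "Interaction parameter(s)",
    "Creation date",
    "Update date",
    "Checksum(s) interactor A",
    "Checksum(s) interactor B",
    "Interaction Checksum(s)",
    "Negative",
    "Feature(s) interactor A",
    "Feature(s) interactor B",
    "Stoichiometry(s) interactor A",
    "Stoichiometry(s) interactor B",
    "Identification method participant A",
    "Identification method participant B",
    "Biological effect of interactor A",
    "Biological effect of interactor B",
    "Causal regulatory mechanism",
    "Causal statement",
)

_EMPTY = "-"
_RESERVED = set('|():"\t')
# namespaces whose terms are conventionally rendered with an upper-case
# CURIE inside the cell, e.g. psi-mi:"MI:0217"(phosphorylation reaction)
_TERM_NS = {
    "go", "mi", "ro", "eco", "mod", "so", "chebi",
    "bto", "cl", "uberon", "obi", "po", "fao",
}
_DISPLAY_PREFIX = {"mi": "psi-mi", "mod": "psi-mod", "ncbitaxon": "taxid"}

_CELL_RE = re.compile(
    r'^(?P<prefix>[^:"]+):(?:"(?P<quoted>[^"]*)"|(?P<raw>[^()"|]*))'
    r"(?:\((?P<name>.*)\))?$"
)
_INNER_CURIE_RE = re.compile(r"[A-Za-z][A-Za-z0-9._\-]*:\S+\Z")
_ANNOT_RE = re.compile(r'^(?P<topic>[A-Za-z0-9_.\-]+):"(?P<value>.*)"$')
_FEATURE_RE = re.compile(
    r"^(?P<type>[a-z0-9._\-]+:[^:()@]+):(?P<a>\d+|\?)-(?P<b>\d+|\?)"
    r"(?:\((?P<residue>[^)]*)\))?$"
)


def _render_plain(identifier: Identifier) -> str:
    local = identifier.local_id
    prefix = _DISPLAY_PREFIX.get(identifier.prefix, identifier.prefix)
    if _RESERVED & set(local):
        return f'{prefix}:"{local}"'
    return f"{prefix}:{local}"


def _render_term(identifier: Identifier, index: Optional[OntologyIndex]) -> str:
    if identifier.prefix in _TERM_NS:
        display = _DISPLAY_PREFIX.get(identifier.prefix, identifier.prefix)
        inner = f"{identifier.prefix.upper()}:{identifier.local_id}"
        name = index.name(identifier) if index is not None else None
        return f'{display}:"{inner}"' + (f"({name})" if name else "")
    return _render_plain(identifier)


def _parse_cell_value(cell: str, path: str) -> Identifier:
    match = _CELL_RE.match(cell)
    if not match:
        raise ParseError(path, f"malformed MITAB cell {cell!r}")
    value = match["quoted"] if match["quoted"] is not None else match["raw"]
    if not value:
        raise ParseError(path, f"empty accession in MITAB cell {cell!r}")
    registry = default_registry()
    if _INNER_CURIE_RE.match(value):
        inner = parse_identifier(value)
        if inner.prefix in registry.by_prefix:
            return inner
    try:
        return parse_identifier(f'{match["prefix"]}:{value}')
    except CurieParseError as exc:
        raise ParseError(path, str(exc)) from exc


def _render_modification(mod: ModificationState) -> str:
    pos = str(mod.position) if mod.position is not None else "?"
    cell = f"{mod.modification_type.curie}:{pos}-{pos}"
    if mod.residue is not None:
        cell += f"({mod.residue.curie})"
    return cell


def _parse_modification(cell: str, path: str) -> ModificationState:
    match = _FEATURE_RE.match(cell)
    if not match:
        raise ParseError(path, f"malformed modification feature {cell!r}")
    position = None if match["a"] == "?" else int(match["a"])
    residue = (
        parse_identifier(match["residue"]) if match["residue"] else None
    )
    return ModificationState(
        modification_type=parse_identifier(match["type"]),
        residue=residue,
        position=position,
    )


def _context_annotations(ctx: EntityContext, interaction: bool) -> List[str]:
    tags: List[str] = []
    if interaction and ctx.biological_activity is not None:
        tags.append(f'mi2cast-activity:"{ctx.biological_activity.curie}"')
    for name in ("tissue", "cell", "compartment"):
        value = getattr(ctx, name)
        if value is not None:
            tags.append(f'mi2cast-{name}:"{value.curie}"')
    for term in ctx.experimental_setup:
        tags.append(f'mi2cast-setup:"{term.curie}"')
    if interaction:
        for mod in ctx.modifications:
            tags.append(f'mi2cast-modification:"{_render_modification(mod)}"')
        if ctx.taxon is None:
            pass  # host taxid column carries it
    return tags


def _split(cell: str) -> List[str]:
    return [] if cell == _EMPTY or cell == "" else cell.split("|")


def _statement_to_row(
    stmt: CausalStatement, index: Optional[OntologyIndex]
) -> List[str]:
    row = [_EMPTY] * 46

    def set_col(number: int, value: str) -> None:
        if value:
            row[number - 1] = value

    for side, id_col, tax_col, type_col, ann_col, feat_col, eff_col in (
        ("source", 1, 10, 21, 26, 37, 43),
        ("target", 2, 11, 22, 27, 38, 44),
    ):
        entity: Optional[BioEntity] = getattr(stmt, side)
        if entity is None:
            continue
        set_col(id_col, _render_plain(entity.identifier))
        ctx = entity.context
        if ctx.taxon is not None:
            set_col(tax_col, _render_plain(ctx.taxon))
        if entity.biological_type is not None:
            set_col(type_col, _render_term(entity.biological_type, index))
        if ctx.biological_activity is not None:
            set_col(eff_col, _render_term(ctx.biological_activity, index))
        if ctx.modifications:
            set_col(feat_col, "|".join(_render_modification(m) for m in ctx.modifications))
        tags = [
            f'mi2cast-component:"{c.curie}"' for c in entity.components
        ] + _context_annotations(ctx, interaction=False)
        set_col(ann_col, "|".join(tags))

    if stmt.relation is not None:
        set_col(46, _render_term(stmt.relation.relation_term, index))
        if stmt.relation.mechanism is not None:
            set_col(45, _render_term(stmt.relation.mechanism, index))

    ev = stmt.evidence
    if ev.references:
        set_col(9, "|".join(_render_plain(r) for r in ev.references))
    if ev.interaction_context.taxon is not None:
        set_col(29, _render_plain(ev.interaction_context.taxon))
    interaction_tags = [
        f'mi2cast-evidence-type:"{t.curie}"' for t in ev.evidence_types
    ] + _context_annotations(ev.interaction_context, interaction=True)
    if stmt.relation is not None and stmt.relation.target_modification_effect is not None:
        interaction_tags.append(
            "mi2cast-effect:"
            f'"{_render_modification(stmt.relation.target_modification_effect)}"'
        )
    set_col(28, "|".join(interaction_tags))
    return row


def write_mitab28(
    stmts: Sequence[CausalStatement], index: Optional[OntologyIndex] = None
) -> str:
    """Render statements as MITAB 2.8, one line each, with a ``#`` header."""
    if index is None:
        index = _default_index()
    lines = ["#" + "\t".join(MITAB28_COLUMNS)]
    for stmt in stmts:
        lines.append("\t".join(_statement_to_row(stmt, index)))
    return "\n".join(lines) + "\n"


_index_cache: Dict[str, OntologyIndex] = {}


def _default_index() -> OntologyIndex:
    if "default" not in _index_cache:
        _index_cache["default"] = load_obo_dir()
    return _index_cache["default"]


def _row_to_statement(row: List[str], line_no: int) -> CausalStatement:
    where = f"line {line_no}"

    def cell(number: int) -> str:
        return row[number - 1]

    def one(number: int) -> Optional[Identifier]:
        values = _split(cell(number))
        if not values:
            return None
        if len(values) > 1:
            raise ParseError(
                f"{where} column {number}", "expected a single value"
            )
        return _parse_cell_value(values[0], f"{where} column {number}")

    def annotations(number: int) -> List:
        out = []
        for item in _split(cell(number)):
            match = _ANNOT_RE.match(item)
            if not match:
                raise ParseError(
                    f"{where} column {number}", f"malformed annotation {item!r}"
                )
            out.append((match["topic"], match["value"]))
        return out

    entities: Dict[str, Optional[BioEntity]] = {}
    for side, id_col, tax_col, type_col, ann_col, feat_col, eff_col in (
        ("source", 1, 10, 21, 26, 37, 43),
        ("target", 2, 11, 22, 27, 38, 44),
    ):
        identifier = one(id_col)
        if identifier is None:
            entities[side] = None
            continue
        components = []
        ctx_kwargs: dict = {"taxon": one(tax_col), "biological_activity": one(eff_col)}
        setup = []
        for topic, value in annotations(ann_col):
            term_path = f"{where} column {ann_col}"
            if topic == "mi2cast-component":
                components.append(_curie(value, term_path))
            elif topic == "mi2cast-setup":
                setup.append(_curie(value, term_path))
            elif topic in ("mi2cast-tissue", "mi2cast-cell", "mi2cast-compartment"):
                ctx_kwargs[topic.removeprefix("mi2cast-")] = _curie(value, term_path)
            else:
                raise ParseError(term_path, f"unknown annotation topic {topic!r}")
        mods = tuple(
            _parse_modification(item, f"{where} column {feat_col}")
            for item in _split(cell(feat_col))
        )
        entities[side] = BioEntity(
            identifier=identifier,
            biological_type=one(type_col),
            components=tuple(components),
            context=EntityContext(
                modifications=mods, experimental_setup=tuple(setup), **ctx_kwargs
            ),
        )

    evidence_types: List[Identifier] = []
    effect: Optional[ModificationState] = None
    ictx_kwargs: dict = {"taxon": one(29)}
    imods: List[ModificationState] = []
    isetup: List[Identifier] = []
    for topic, value in annotations(28):
        term_path = f"{where} column 28"
        if topic == "mi2cast-evidence-type":
            evidence_types.append(_curie(value, term_path))
        elif topic == "mi2cast-effect":
            effect = _parse_modification(value, term_path)
        elif topic == "mi2cast-activity":
            ictx_kwargs["biological_activity"] = _curie(value, term_path)
        elif topic == "mi2cast-modification":
            imods.append(_parse_modification(value, term_path))
        elif topic == "mi2cast-setup":
            isetup.append(_curie(value, term_path))
        elif topic in ("mi2cast-tissue", "mi2cast-cell", "mi2cast-compartment"):
            ictx_kwargs[topic.removeprefix("mi2cast-")] = _curie(value, term_path)
        else:
            raise ParseError(term_path, f"unknown annotation topic {topic!r}")

    relation_term = one(46)
    relation = None
    if relation_term is not None:
        relation = CausalRelation(
            relation_term=relation_term,
            mechanism=one(45),
            target_modification_effect=effect,
        )
    elif effect is not None:
        raise ParseError(
            f"{where} column 28", "a resulting modification requires a causal statement"
        )

    references = tuple(
        _parse_cell_value(v, f"{where} column 9") for v in _split(cell(9))
    )
    return CausalStatement(
        source=entities["source"],
        target=entities["target"],
        relation=relation,
        evidence=Evidence(
            references=references,
            evidence_types=tuple(evidence_types),
            interaction_context=EntityContext(
                modifications=tuple(imods),
                experimental_setup=tuple(isetup),
                **ictx_kwargs,
            ),
        ),
    )


def read_mitab28(document: str) -> List[CausalStatement]:
    statements = []
    for line_no, line in enumerate(document.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        row = line.split("\t")
        if len(row) != 46:
            raise ParseError(
                f"line {line_no}",
                f"expected 46 MITAB 2.8 columns, got {len(row)}",
            )
        statements.append(_row_to_statement(row, line_no))
    return statements


# ===========================================================================
# SIF

DEFAULT_SIGN_TOKENS = {"positive": "->", "negative": "-|", "unsigned": "--"}


def relation_sign(
    relation: Optional[CausalRelation],
    index: OntologyIndex,
    branches: Optional[dict] = None,
) -> str:
    """Classify a relation term as positive / negative / unsigned by its
    position under the sign sub-branches; unknown terms are unsigned."""
    if branches is None:
        from .rules import default_branches

        branches = default_branches()
    if relation is None:
        return "unsigned"
    if in_branch(relation.relation_term, branches["positive"], index) is Membership.YES:
        return "positive"
    if in_branch(relation.relation_term, branches["negative"], index) is Membership.YES:
        return "negative"
    return "unsigned"


def export_sif(
    stmts: Sequence[CausalStatement],
    index: Optional[OntologyIndex] = None,
    sign_tokens: Optional[Dict[str, str]] = None,
) -> str:
    """One ``source <token> target`` line per statement (lossy; no reader)."""
    if index is None:
        index = _default_index()
    tokens = dict(DEFAULT_SIGN_TOKENS)
    if sign_tokens:
        tokens.update(sign_tokens)
    from .rules import default_branches

    branches = default_branches()
    lines = []
    for stmt in stmts:
        token = tokens[relation_sign(stmt.relation, index, branches)]
        source = stmt.source.identifier.curie if stmt.source else _EMPTY
        target = stmt.target.identifier.curie if stmt.target else _EMPTY
        lines.append(f"{source} {token} {target}")
    return "\n".join(lines) + "\n"
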