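"""Typed data model for molecular-interaction causal statements.

A causal statement records that the activity (or quantity) of a *source*
biomolecule influences a *target* biomolecule, together with the causal
relation term, the supporting evidence and the biological context in which
the causality was observed.  All types are immutable; list-valued fields are
stored as tuples.  Construction enforces only *structural* invariants (an
identifier is syntactically a CURIE, a sequence position has a residue, ...);
checklist compliance is the job of :mod:`mi2cast.rules`, so that incomplete
records can still be parsed and linted.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, fields
from typing import Any, Optional

__all__ = [
    "ModelError",
    "Identifier",
    "ModificationState",
    "EntityContext",
    "BioEntity",
    "CausalRelation",
    "Evidence",
    "CausalStatement",
    "statement_key",
    "RELATION_PREFIXES",
    "REFERENCE_PREFIXES",
]

_PREFIX_RE = re.compile(r"[a-z0-9.\-_]+\Z")

#: CURIE prefixes accepted for causal relation terms (Relation Ontology and
#: the PSI-MI controlled vocabulary).  "psi-mi" is normalized to "mi" at
#: parse time by :func:`mi2cast.registry.parse_identifier`.
RELATION_PREFIXES = frozenset({"ro", "mi"})

#: CURIE prefixes accepted for literature references.
REFERENCE_PREFIXES = frozenset({"pubmed", "doi"})


class ModelError(ValueError):
    """Structural invariant violation, naming the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


def _tuple(value: Any) -> tuple:
    return tuple(value) if value is not None else ()


@dataclass(frozen=True)
class Identifier:
    """A namespace-prefixed accession (CURIE), e.g. ``go:0016301``.

    The prefix is a lower-case registry key; the accession's case is
    preserved.  Rendering with :attr:`curie` and re-parsing with
    :func:`mi2cast.registry.parse_identifier` is the identity.
    """

    prefix: str
    local_id: str

    def __post_init__(self) -> None:
        if not self.prefix or not _PREFIX_RE.match(self.prefix):
            raise ModelError(
                "prefix",
                f"must be a non-empty lower-case namespace token, got {self.prefix!r}",
            )
        if not self.local_id or any(c.isspace() for c in self.local_id):
            raise ModelError(
                "local_id",
                f"must be non-empty and whitespace-free, got {self.local_id!r}",
            )

    @property
    def curie(self) -> str:
        return f"{self.prefix}:{self.local_id}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.curie


@dataclass(frozen=True)
class ModificationState:
    """A physical modification of an entity (e.g. a phosphorylated residue).

    ``position`` is a 1-based sequence coordinate (protein residue numbering
    convention).  A bare position without a residue is uninterpretable and is
    rejected at construction.
    """

    modification_type: Identifier
    residue: Optional[Identifier] = None
    position: Optional[int] = None

    def __post_init__(self) -> None:
        if not isinstance(self.modification_type, Identifier):
            raise ModelError("modification_type", "must be an Identifier")
        if self.position is not None:
            if self.residue is None:
                raise ModelError(
                    "position", "a sequence position requires a residue term"
                )
            if not isinstance(self.position, int) or self.position < 1:
                raise ModelError(
                    "position", f"must be a 1-based integer, got {self.position!r}"
                )


@dataclass(frozen=True)
class EntityContext:
    """Contextual annotations attachable to an entity or to the interaction.

    Covers the biological activity, prior modification state, taxon, and the
    three location levels (tissue, cell type/line, cellular compartment), plus
    experimental-setup qualifiers (e.g. "over expressed level").
    """

    biological_activity: Optional[Identifier] = None
    modifications: tuple = ()
    taxon: Optional[Identifier] = None
    tissue: Optional[Identifier] = None
    cell: Optional[Identifier] = None
    compartment: Optional[Identifier] = None
    experimental_setup: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "modifications", _tuple(self.modifications))
        object.__setattr__(
            self, "experimental_setup", _tuple(self.experimental_setup)
        )
        for name in ("biological_activity", "taxon", "tissue", "cell", "compartment"):
            value = getattr(self, name)
            if value is not None and not isinstance(value, Identifier):
                raise ModelError(name, "must be an Identifier or None")
        for i, mod in enumerate(self.modifications):
            if not isinstance(mod, ModificationState):
                raise ModelError(f"modifications[{i}]", "must be a ModificationState")
        for i, term in enumerate(self.experimental_setup):
            if not isinstance(term, Identifier):
                raise ModelError(f"experimental_setup[{i}]", "must be an Identifier")

    def is_empty(self) -> bool:
        return self == EntityContext()


@dataclass(frozen=True)
class BioEntity:
    """A source or target participant of a causal statement."""

    identifier: Identifier
    biological_type: Optional[Identifier] = None
    components: tuple = ()
    context: EntityContext = field(default_factory=EntityContext)

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", _tuple(self.components))
        if not isinstance(self.identifier, Identifier):
            raise ModelError("identifier", "must be an Identifier")
        if self.biological_type is not None and not isinstance(
            self.biological_type, Identifier
        ):
            raise ModelError("biological_type", "must be an Identifier or None")
        for i, comp in enumerate(self.components):
            if not isinstance(comp, Identifier):
                raise ModelError(f"components[{i}]", "must be an Identifier")
        if self.components and self.biological_type is None:
            raise ModelError(
                "biological_type",
                "an entity with components must declare its biological type "
                "(complex vs family is otherwise ambiguous)",
            )
        if len(set(self.components)) != len(self.components):
            raise ModelError("components", "must be pairwise distinct")


@dataclass(frozen=True)
class CausalRelation:
    """The causal relation of a statement: regulatory effect, optional
    mechanism, and the modification the mechanism produces on the target."""

    relation_term: Identifier
    mechanism: Optional[Identifier] = None
    target_modification_effect: Optional[ModificationState] = None

    def __post_init__(self) -> None:
        if not isinstance(self.relation_term, Identifier):
            raise ModelError("relation_term", "must be an Identifier")
        if self.relation_term.prefix not in RELATION_PREFIXES:
            raise ModelError(
                "relation_term",
                f"prefix must be one of {sorted(RELATION_PREFIXES)}, "
                f"got {self.relation_term.prefix!r}",
            )
        if self.mechanism is not None and not isinstance(self.mechanism, Identifier):
            raise ModelError("mechanism", "must be an Identifier or None")
        if self.target_modification_effect is not None and not isinstance(
            self.target_modification_effect, ModificationState
        ):
            raise ModelError(
                "target_modification_effect", "must be a ModificationState or None"
            )


@dataclass(frozen=True)
class Evidence:
    """Provenance of a statement: one minimal sufficient set of references,
    evidence types (ECO), and interaction-level context."""

    references: tuple = ()
    evidence_types: tuple = ()
    interaction_context: EntityContext = field(default_factory=EntityContext)

    def __post_init__(self) -> None:
        object.__setattr__(self, "references", _tuple(self.references))
        object.__setattr__(self, "evidence_types", _tuple(self.evidence_types))
        for i, ref in enumerate(self.references):
            if not isinstance(ref, Identifier):
                raise ModelError(f"references[{i}]", "must be an Identifier")
            if ref.prefix not in REFERENCE_PREFIXES:
                raise ModelError(
                    f"references[{i}]",
                    f"prefix must be one of {sorted(REFERENCE_PREFIXES)}, "
                    f"got {ref.prefix!r}",
                )
        if len(set(self.references)) != len(self.references):
            raise ModelError("references", "must be pairwise distinct")
        for i, term in enumerate(self.evidence_types):
            if not isinstance(term, Identifier):
                raise ModelError(f"evidence_types[{i}]", "must be an Identifier")


@dataclass(frozen=True)
class CausalStatement:
    """A full causal statement.

    ``source``, ``target`` and ``relation`` may be ``None`` so that invalid
    records can be represented and reported by the validator rather than
    rejected at parse time.
    """

    source: Optional[BioEntity] = None
    target: Optional[BioEntity] = None
    relation: Optional[CausalRelation] = None
    evidence: Evidence = field(default_factory=Evidence)

    def __post_init__(self) -> None:
        if self.source is not None and not isinstance(self.source, BioEntity):
            raise ModelError("source", "must be a BioEntity or None")
        if self.target is not None and not isinstance(self.target, BioEntity):
            raise ModelError("target", "must be a BioEntity or None")
        if self.relation is not None and not isinstance(self.relation, CausalRelation):
            raise ModelError("relation", "must be a CausalRelation or None")
        if not isinstance(self.evidence, Evidence):
            raise ModelError("evidence", "must be an Evidence")


# ---------------------------------------------------------------------------
# Canonical digest

def _canon(obj: Any) -> Any:
    """Canonical JSON-able form with list-valued fields sorted."""
    if obj is None:
        return None
    if isinstance(obj, Identifier):
        return obj.curie
    if isinstance(obj, (str, int)):
        return obj
    if isinstance(obj, tuple):
        return sorted((_canon(x) for x in obj), key=json.dumps)
    # dataclass
    return {f.name: _canon(getattr(obj, f.name)) for f in fields(obj)}


def statement_key(stmt: CausalStatement) -> str:
    """Deterministic digest identifying one context-distinct causal interaction.

    Two statements that differ in any entity, relation or context field have
    different keys; provenance (the references and evidence types) is
    excluded, so independent observations of the same interaction in the same
    context share a key.  List-valued fields are sorted before hashing, so
    reference/component order never matters.
    """
    payload = {
        "source": _canon(stmt.source),
        "target": _canon(stmt.target),
        "relation": _canon(stmt.relation),
        "interaction_context": _canon(stmt.evidence.interaction_context),
    }
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:32]
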