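"""OBO term subsets and branch-membership queries.

Every "term must come from branch X" check in the checklist reduces to a
reflexive-transitive ``is_a`` traversal from a term up to a designated branch
root (subsumption only; ``part_of`` and other relations are ignored on
purpose, since all the checklist's branch constraints are subsumption
branches).  Missing terms or roots yield the third truth value ``UNKNOWN``,
which the validator reports as "unverifiable" instead of failing — the
checklist stays usable without full ontology downloads.
"""

from __future__ import annotations

import enum
import io as _io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, Optional

import networkx as nx
import obonet

from .model import Identifier
from .registry import parse_identifier

__all__ = [
    "Membership",
    "TermRecord",
    "OntologyIndex",
    "BranchSpec",
    "OntologyLoadError",
    "load_obo",
    "load_obo_file",
    "load_obo_dir",
    "bundled_ontology_dir",
    "in_branch",
    "is_most_specific_usage",
]


class OntologyLoadError(ValueError):
    pass


class Membership(enum.Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class TermRecord:
    name: str
    parents: frozenset
    obsolete: bool = False


class OntologyIndex:
    """An acyclic ``is_a`` term graph supporting branch queries."""

    def __init__(self, terms: Dict[Identifier, TermRecord]):
        self.terms = dict(terms)
        self._validate()
        self._ancestors: Dict[Identifier, frozenset] = {}

    def _validate(self) -> None:
        graph = nx.DiGraph()
        for term, record in self.terms.items():
            graph.add_node(term)
            for parent in record.parents:
                if parent not in self.terms:
                    raise OntologyLoadError(
                        f"dangling is_a parent {parent.curie} of {term.curie}"
                    )
                graph.add_edge(term, parent)
        if not nx.is_directed_acyclic_graph(graph):
            member = next(iter(nx.find_cycle(graph)))[0]
            raise OntologyLoadError(
                f"is_a cycle detected involving {member.curie}"
            )

    @property
    def roots(self) -> frozenset:
        return frozenset(t for t, r in self.terms.items() if not r.parents)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: Identifier) -> bool:
        return term in self.terms

    def name(self, term: Identifier) -> Optional[str]:
        record = self.terms.get(term)
        return record.name if record else None

    def is_obsolete(self, term: Identifier) -> bool:
        record = self.terms.get(term)
        return bool(record and record.obsolete)

    def ancestors(self, term: Identifier) -> frozenset:
        """Reflexive-transitive is_a closure of ``term`` (memoized)."""
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        closure = {term}
        stack = [term]
        while stack:
            current = stack.pop()
            record = self.terms.get(current)
            if record is None:
                continue
            for parent in record.parents:
                if parent not in closure:
                    closure.add(parent)
                    stack.append(parent)
        result = frozenset(closure)
        self._ancestors[term] = result
        return result

    def merged_with(self, other: "OntologyIndex") -> "OntologyIndex":
        terms = dict(self.terms)
        terms.update(other.terms)
        return OntologyIndex(terms)

    @classmethod
    def merge(cls, indexes: Iterable["OntologyIndex"]) -> "OntologyIndex":
        terms: Dict[Identifier, TermRecord] = {}
        for index in indexes:
            terms.update(index.terms)
        return cls(terms)


@dataclass(frozen=True)
class BranchSpec:
    """A named branch: everything reaching one of ``roots`` via is_a."""

    roots: frozenset
    label: str = ""

    def __post_init__(self) -> None:
        if not self.roots:
            raise ValueError("a branch needs at least one root")
        object.__setattr__(self, "roots", frozenset(self.roots))


def load_obo(document: str) -> OntologyIndex:
    """Parse OBO 1.2/1.4 stanza text into an :class:`OntologyIndex`.

    Only the subset the checklist needs is interpreted: ``[Term]`` stanzas
    with ``id``, ``name``, ``is_a`` and ``is_obsolete``.  Obsolete terms are
    retained but flagged.  Cycles and dangling parents are load errors.
    """
    graph = obonet.read_obo(_io.StringIO(document), ignore_obsolete=False)
    terms: Dict[Identifier, TermRecord] = {}
    for node, data in graph.nodes(data=True):
        if not data:
            # a bare edge target materialized by the parser, not a stanza:
            # surfaces as a dangling parent in _validate()
            continue
        term = parse_identifier(node)
        parents = frozenset(parse_identifier(p) for p in data.get("is_a", ()))
        terms[term] = TermRecord(
            name=data.get("name", ""),
            parents=parents,
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
        )
    return OntologyIndex(terms)


def load_obo_file(path) -> OntologyIndex:
    return load_obo(Path(path).read_text(encoding="utf-8"))


def bundled_ontology_dir() -> Path:
    """Directory of the bundled synthetic mini-ontology fixtures."""
    return Path(str(resources.files("mi2cast") / "data" / "ontologies"))


def load_obo_dir(directory=None) -> OntologyIndex:
    """Load and merge every ``*.obo`` file in a directory (bundled fixtures
    by default)."""
    directory = Path(directory) if directory else bundled_ontology_dir()
    paths = sorted(directory.glob("*.obo"))
    if not paths:
        raise OntologyLoadError(f"no .obo files in {directory}")
    return OntologyIndex.merge(load_obo_file(p) for p in paths)


def in_branch(
    term: Identifier, branch: BranchSpec, index: OntologyIndex
) -> Membership:
    """Is ``term`` inside ``branch``?

    YES iff the term reaches any branch root by reflexive-transitive is_a
    traversal (so a root is inside its own branch); UNKNOWN when the term —
    or every root — is absent from the index.
    """
    if term in branch.roots:
        return Membership.YES
    if term not in index:
        return Membership.UNKNOWN
    if not any(root in index for root in branch.roots):
        return Membership.UNKNOWN
    if branch.roots & index.ancestors(term):
        return Membership.YES
    return Membership.NO


def is_most_specific_usage(
    term: Identifier, branch: BranchSpec, index: OntologyIndex
) -> bool:
    """Root-usage proxy for the "use the lowest possible level term" advice.

    False exactly when the term *is* a branch root (maximally generic usage);
    whether a non-root term could have been more specific is context
    dependent and not decidable from the ontology alone, so any non-root
    usage passes.
    """
    return term not in branch.roots
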