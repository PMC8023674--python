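"""Identifier-namespace registry.

Maps CURIE prefixes to accession syntax, the interactor type a namespace
implies (a UniProtKB accession names a protein, a ChEBI accession a small
molecule, ...) and per-entity-class database preferences (primary vs
alternative).  Accession *existence* is never checked remotely — syntax only,
so everything runs offline and reproducibly.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional

from .findings import Severity, ValidationFinding
from .model import Identifier, ModelError

__all__ = [
    "NamespaceSpec",
    "Registry",
    "RegistryError",
    "ParseError",
    "default_registry",
    "parse_identifier",
    "check_accession_syntax",
    "implied_biological_type",
    "allowed_namespaces",
    "curation_note",
]

#: Prefix aliases normalized at parse time (identifiers.org-style lower-case
#: canonical prefixes).
PREFIX_ALIASES = {
    "psi-mi": "mi",
    "psimod": "mod",
    "psi-mod": "mod",
    "entrez": "ncbigene",
    "entrezgene/locuslink": "ncbigene",
    "taxid": "ncbitaxon",
    "ncbitaxid": "ncbitaxon",
    "cvcl": "cellosaurus",
    "brenda": "bto",
}


class RegistryError(ValueError):
    pass


class ParseError(ValueError):
    """Malformed CURIE string."""


@dataclass(frozen=True)
class NamespaceSpec:
    """One registry row: a namespace and how its accessions look."""

    prefix: str
    accession_pattern: str
    implied_type: Optional[Identifier]
    applicable_entity_types: frozenset
    rank: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "_regex", re.compile(self.accession_pattern + r"\Z"))
        if self.rank not in ("primary", "alternative"):
            raise RegistryError(f"{self.prefix}: bad rank {self.rank!r}")

    def matches(self, local_id: str) -> bool:
        return bool(self._regex.match(local_id))


class Registry:
    """An ordered collection of :class:`NamespaceSpec` rows."""

    def __init__(self, specs):
        self.specs = list(specs)
        self.by_prefix = {}
        for spec in self.specs:
            if spec.prefix in self.by_prefix:
                raise RegistryError(f"duplicate prefix {spec.prefix!r}")
            self.by_prefix[spec.prefix] = spec
        self.entity_types = frozenset(
            t for s in self.specs for t in s.applicable_entity_types
        )

    @classmethod
    def from_tsv(cls, text: str) -> "Registry":
        specs = []
        reader = csv.reader(
            (line for line in text.splitlines() if line and not line.startswith("#")),
            delimiter="\t",
        )
        header = next(reader)
        expected = ["prefix", "pattern", "implied_type", "entity_types", "rank"]
        if header != expected:
            raise RegistryError(f"bad registry header {header!r}")
        for row in reader:
            prefix, pattern, implied, types, rank = row
            try:
                re.compile(pattern)
            except re.error as exc:  # pragma: no cover - table is curated
                raise RegistryError(f"{prefix}: bad pattern: {exc}") from exc
            specs.append(
                NamespaceSpec(
                    prefix=prefix,
                    accession_pattern=pattern,
                    implied_type=None if implied == "-" else parse_identifier(implied),
                    applicable_entity_types=frozenset(
                        () if types == "-" else types.split(";")
                    ),
                    rank=rank,
                )
            )
        return cls(specs)

    @classmethod
    def from_file(cls, path) -> "Registry":
        return cls.from_tsv(Path(path).read_text(encoding="utf-8"))


@lru_cache(maxsize=1)
def default_registry() -> Registry:
    """The bundled registry mirroring the checklist's entity-type/database
    recommendations."""
    text = (resources.files("mi2cast") / "data" / "namespaces.tsv").read_text(
        encoding="utf-8"
    )
    return Registry.from_tsv(text)


def parse_identifier(curie: str) -> Identifier:
    """Parse ``prefix:accession``, splitting on the first ``:``.

    The prefix is lower-cased (and aliases like ``psi-mi`` normalized);
    the accession's case is preserved.  Unknown prefixes parse fine — they
    are flagged by validation, not here.
    """
    if not isinstance(curie, str) or ":" not in curie:
        raise ParseError(f"not a CURIE (missing ':'): {curie!r}")
    prefix, _, local = curie.partition(":")
    prefix = prefix.strip().lower()
    prefix = PREFIX_ALIASES.get(prefix, prefix)
    if not prefix or not local:
        raise ParseError(f"empty prefix or accession in {curie!r}")
    try:
        return Identifier(prefix=prefix, local_id=local)
    except ModelError as exc:
        raise ParseError(f"malformed CURIE {curie!r}: {exc}") from exc


def check_accession_syntax(
    identifier: Identifier, registry: Optional[Registry] = None
) -> list:
    """Syntax-check an identifier against its namespace's accession pattern.

    Returns a (possibly empty) list of ``X.syntax`` findings; never raises.
    """
    registry = registry or default_registry()
    spec = registry.by_prefix.get(identifier.prefix)
    if spec is None:
        return [
            ValidationFinding(
                rule_id="X.syntax",
                severity=Severity.WARNING,
                path="",
                message=f"unknown identifier namespace {identifier.prefix!r} "
                f"in {identifier.curie!r}",
            )
        ]
    if not spec.matches(identifier.local_id):
        return [
            ValidationFinding(
                rule_id="X.syntax",
                severity=Severity.WARNING,
                path="",
                message=f"accession {identifier.local_id!r} does not match the "
                f"{identifier.prefix!r} pattern /{spec.accession_pattern}/",
            )
        ]
    return []


def implied_biological_type(
    identifier: Identifier, registry: Optional[Registry] = None
) -> Optional[Identifier]:
    """The interactor-type term a namespace implies, or None for
    type-ambiguous namespaces (e.g. a gene database used as protein
    fallback) and unknown prefixes."""
    registry = registry or default_registry()
    spec = registry.by_prefix.get(identifier.prefix)
    return spec.implied_type if spec else None


def allowed_namespaces(entity_type: str, registry: Optional[Registry] = None) -> list:
    """Recommended namespaces for an entity class, primary-ranked first.

    ``entity_type`` is one of the registry's class tokens (gene, mrna,
    protein, chemical, complex, family, phenotype); matching is
    case-insensitive.
    """
    registry = registry or default_registry()
    token = entity_type.lower()
    if token not in registry.entity_types:
        raise RegistryError(
            f"unknown entity type {entity_type!r}; valid: "
            + ", ".join(sorted(registry.entity_types))
        )
    matching = [s for s in registry.specs if token in s.applicable_entity_types]
    # stable: primary block first, file order within each block
    return [s for s in matching if s.rank == "primary"] + [
        s for s in matching if s.rank == "alternative"
    ]


def curation_note(identifier: Identifier) -> Optional[str]:
    """Informational curation reminder for a namespace, if any.

    Swiss-Prot vs TrEMBL preference is not decidable from accession syntax,
    so it is surfaced as a note (CLI verbose mode), never as a finding.
    """
    if identifier.prefix == "uniprotkb":
        return (
            "prefer a UniProtKB/Swiss-Prot-reviewed accession (and the isoform "
            "accession when the isoform is known) over UniProtKB/TrEMBL"
        )
    return None
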