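"""Validation finding and report types shared by the registry and the rule
engine."""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = ["Severity", "ValidationFinding", "ValidationReport", "RULE_IDS"]

#: The rule catalogue.  R* ids map to checklist rules; X.* ids are
#: cross-cutting checks (identifier syntax, unverifiable terms, obsolete
#: terms).
RULE_IDS = (
    "R1.entity",
    "R1.components",
    "R2.relation",
    "R3.1.reference",
    "R3.2.evidence",
    "R3.3.setup",
    "R4.1.activity",
    "R4.1.mechanism",
    "R4.2.biotype",
    "R4.3.modification",
    "R4.4.taxon",
    "R4.5.location",
    "X.syntax",
    "X.unverifiable",
    "X.obsolete",
)


class Severity(enum.Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"
    INFO = "INFO"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class ValidationFinding:
    """One rule-check outcome.

    ``path`` locates the offending field in the statement (dotted, with
    ``[i]`` list indices, e.g. ``target.context.modifications[0].position``).
    ``missing`` marks absence-of-context findings, which distinguish the
    ``minimum`` from the ``context_enriched`` compliance level.
    """

    rule_id: str
    severity: Severity
    path: str
    message: str
    missing: bool = False

    def __post_init__(self) -> None:
        if self.rule_id not in RULE_IDS:
            raise ValueError(f"unknown rule id {self.rule_id!r}")


@dataclass(frozen=True)
class ValidationReport:
    """Findings for one statement, sorted by (path, rule_id)."""

    findings: tuple
    statement_ref: str

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.findings, key=lambda f: (f.path, f.rule_id))
        )
        object.__setattr__(self, "findings", ordered)

    @property
    def errors(self) -> tuple:
        return tuple(f for f in self.findings if f.severity is Severity.ERROR)

    def __iter__(self):
        return iter(self.findings)

    def __len__(self) -> int:
        return len(self.findings)
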