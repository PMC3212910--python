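"""Validation findings and reports.

Shared by the archetype validator and the lifecycle checks: validation never
throws on bad data — every problem is a finding, so a payer-side adjudicator
always receives a complete report rather than a first failure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum


class Rule(str, Enum):
    RM_TYPE_MISMATCH = "RM_TYPE_MISMATCH"
    NODE_ID_UNKNOWN = "NODE_ID_UNKNOWN"
    OCCURRENCES_EXCEEDED = "OCCURRENCES_EXCEEDED"
    OCCURRENCES_UNMET = "OCCURRENCES_UNMET"
    CARDINALITY_VIOLATION = "CARDINALITY_VIOLATION"
    VALUE_TYPE_MISMATCH = "VALUE_TYPE_MISMATCH"
    SLOT_INCLUDE_VIOLATION = "SLOT_INCLUDE_VIOLATION"
    SLOT_FILLER_INVALID = "SLOT_FILLER_INVALID"
    # Template-level rule: a coded element whose code falls outside the
    # template's terminology binding for that path.
    CODE_BINDING_VIOLATION = "CODE_BINDING_VIOLATION"
    # Lifecycle rules (claim status histories).
    LIFECYCLE_BAD_INITIAL_STATE = "LIFECYCLE_BAD_INITIAL_STATE"
    LIFECYCLE_ILLEGAL_TRANSITION = "LIFECYCLE_ILLEGAL_TRANSITION"
    LIFECYCLE_TIME_REGRESSION = "LIFECYCLE_TIME_REGRESSION"


class Severity(str, Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"


@dataclass(frozen=True)
class ValidationFinding:
    path: str
    rule: Rule
    detail: str
    severity: Severity = Severity.ERROR

    def to_dict(self) -> dict:
        return {
            "path": self.path,
            "rule": self.rule.value,
            "detail": self.detail,
            "severity": self.severity.value,
        }


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not any(f.severity is Severity.ERROR for f in self.findings)

    def add(self, path: str, rule: Rule, detail: str,
            severity: Severity = Severity.ERROR) -> None:
        self.findings.append(ValidationFinding(path, rule, detail, severity))

    def sorted(self) -> "ValidationReport":
        """Findings in canonical (path, rule) order — byte-stable output."""
        return ValidationReport(
            sorted(self.findings, key=lambda f: (f.path, f.rule.value, f.detail)))

    def by_rule(self, rule: Rule) -> list[ValidationFinding]:
        return [f for f in self.findings if f.rule is rule]

    def to_dict(self) -> dict:
        return {"valid": self.valid,
                "findings": [f.to_dict() for f in self.findings]}

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.sorted().to_dict(), indent=indent, sort_keys=False)
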