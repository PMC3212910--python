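"""Extract container types (shared by the serializers and the exchange)."""

from __future__ import annotations

from dataclasses import dataclass, field

from .rm_core import Composition, PartyIdentified


@dataclass
class ExtractItem:
    subject: PartyIdentified
    compositions: list[Composition] = field(default_factory=list)


@dataclass
class Extract:
    """A transferable bundle of compositions sent between organizations
    (provider → payer and back), grouped by record subject."""

    extract_id: str
    source_org: PartyIdentified
    target_org: PartyIdentified
    created_at: str
    items: list[ExtractItem] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("an extract must contain at least one item")

    def compositions(self) -> list[Composition]:
        return [c for item in self.items for c in item.compositions]
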