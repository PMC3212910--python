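"""Canonical XML and JSON serializations of compositions and extracts.

The mapping is bespoke and documented in ``docs/formats.md`` (it is *not*
the official TISS message schema, which is out of scope): an instance node
serializes under the name of the reference-model attribute it occupies, with
its RM type in ``rm``, its node id in ``archetype_node_id``, and — on
archetype roots — ``archetype_id``.  Monetary amounts are canonicalized with
banker's rounding to two decimals, so both serializations round-trip to
structurally equal trees, including cross-format (XML → model → JSON →
model).  UTF-8 throughout.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Optional, Union

from lxml import etree

from . import rm_core
from .rm_core import (
    Action,
    AdminEntry,
    CodedTextValue,
    Composition,
    CountValue,
    DataValue,
    DateTimeValue,
    DateValue,
    Element,
    Entry,
    IdentifierValue,
    ItemList,
    ItemSingle,
    ItemStructure,
    ItemTable,
    ItemTree,
    Link,
    Locatable,
    MoneyValue,
    NodeId,
    Participation,
    PartyIdentified,
    PartyProxy,
    PartySelf,
    QuantityValue,
    Section,
    TextValue,
)
from .rm_extension import (
    Annex,
    Authorization,
    Claim,
    ClaimStatus,
    DateInterval,
    InstitutionalClaim,
    IsmTransition,
    ProfessionalClaim,
    Submission,
)
from .exchange_types import Extract, ExtractItem

__all__ = [
    "composition_to_json", "composition_from_json",
    "composition_to_xml", "composition_from_xml",
    "extract_to_json", "extract_from_json",
    "extract_to_xml", "extract_from_xml",
    "to_json_str", "money_str",
]

_CENTS = Decimal("0.01")


def money_str(amount: Decimal) -> str:
    return str(amount.quantize(_CENTS, rounding=ROUND_HALF_EVEN))


# ---------------------------------------------------------------------------
# JSON
# ---------------------------------------------------------------------------

def _value_to_dict(v: DataValue) -> dict:
    if isinstance(v, CodedTextValue):
        return {"_dv": "DV_CODED_TEXT", "value": v.value, "code": v.code,
                "terminology_id": v.terminology_id}
    if isinstance(v, TextValue):
        return {"_dv": "DV_TEXT", "value": v.value}
    if isinstance(v, DateTimeValue):
        return {"_dv": "DV_DATE_TIME", "value": v.value}
    if isinstance(v, DateValue):
        return {"_dv": "DV_DATE", "value": v.value}
    if isinstance(v, CountValue):
        return {"_dv": "DV_COUNT", "value": v.value}
    if isinstance(v, QuantityValue):
        return {"_dv": "DV_QUANTITY", "magnitude": str(v.magnitude), "units": v.units}
    if isinstance(v, MoneyValue):
        return {"_dv": "DV_MONEY", "amount": money_str(v.amount), "currency": v.currency}
    if isinstance(v, IdentifierValue):
        return {"_dv": "DV_IDENTIFIER", "id": v.id, "issuer": v.issuer, "type": v.type}
    raise TypeError(f"unknown data value {type(v).__name__}")


def _value_from_dict(d: dict) -> DataValue:
    dv = d["_dv"]
    if dv == "DV_CODED_TEXT":
        return CodedTextValue(value=d["value"], code=d["code"],
                              terminology_id=d["terminology_id"])
    if dv == "DV_TEXT":
        return TextValue(d["value"])
    if dv == "DV_DATE_TIME":
        return DateTimeValue(d["value"])
    if dv == "DV_DATE":
        return DateValue(d["value"])
    if dv == "DV_COUNT":
        return CountValue(d["value"])
    if dv == "DV_QUANTITY":
        return QuantityValue(Decimal(d["magnitude"]), d["units"])
    if dv == "DV_MONEY":
        return MoneyValue(Decimal(d["amount"]), d["currency"])
    if dv == "DV_IDENTIFIER":
        return IdentifierValue(d["id"], d["issuer"], d["type"])
    raise ValueError(f"unknown data value tag {dv!r}")


def _party_to_dict(p: Optional[PartyProxy]) -> Optional[dict]:
    if p is None:
        return None
    if isinstance(p, PartySelf):
        return {"_party": "PARTY_SELF"}
    assert isinstance(p, PartyIdentified)
    return {"_party": "PARTY_IDENTIFIED", "name": p.name,
            "identifiers": [{"id": i.id, "issuer": i.issuer, "type": i.type}
                            for i in p.identifiers]}


def _party_from_dict(d: Optional[dict]) -> Optional[PartyProxy]:
    if d is None:
        return None
    if d["_party"] == "PARTY_SELF":
        return PartySelf()
    return PartyIdentified(
        name=d["name"],
        identifiers=tuple(IdentifierValue(i["id"], i["issuer"], i["type"])
                          for i in d["identifiers"]))


def _common_to_dict(node: Locatable) -> dict:
    d: dict = {
        "_rm": rm_core.rm_type_name(node),
        "name": node.name,
        "archetype_node_id": node.archetype_node_id.code,
    }
    if node.archetype_id is not None:
        d["archetype_id"] = node.archetype_id
    if node.links:
        d["links"] = [{"meaning": l.meaning, "type": l.type, "target": l.target}
                      for l in node.links]
    return d


def locatable_to_dict(node: Locatable) -> dict:
    d = _common_to_dict(node)
    if isinstance(node, Element):
        d["value"] = _value_to_dict(node.value) if node.value is not None else None
    elif isinstance(node, rm_core.Cluster):
        d["items"] = [locatable_to_dict(i) for i in node.items]
    elif isinstance(node, (ItemTree, ItemList)):
        d["items"] = [locatable_to_dict(i) for i in node.items]
    elif isinstance(node, ItemTable):
        d["rows"] = [locatable_to_dict(r) for r in node.rows]
    elif isinstance(node, ItemSingle):
        d["item"] = locatable_to_dict(node.item) if node.item is not None else None
    elif isinstance(node, Entry):
        d["subject"] = _party_to_dict(node.subject)
        d["provider"] = _party_to_dict(node.provider)
        d["other_participations"] = [
            {"function": p.function, "mode": p.mode,
             "performer": _party_to_dict(p.performer)}
            for p in node.other_participations]
        d["data"] = locatable_to_dict(node.data) if node.data is not None else None
        if isinstance(node, Submission):
            d["submission_id"] = node.submission_id
            d["submission_date"] = node.submission_date
            d["original_submission"] = node.original_submission
            d["submitter"] = _party_to_dict(node.submitter)
            d["submittee"] = _party_to_dict(node.submittee)
        if isinstance(node, Claim):
            d["billing_date"] = node.billing_date
        if isinstance(node, ProfessionalClaim):
            d["performer"] = _party_to_dict(node.performer)
        if isinstance(node, InstitutionalClaim):
            d["participants"] = [_party_to_dict(p) for p in node.participants]
        if isinstance(node, Authorization):
            d["requester"] = _party_to_dict(node.requester)
            d["authorization_id"] = node.authorization_id
            d["validity"] = str(node.validity) if node.validity else None
            d["is_response"] = node.is_response
        if isinstance(node, Annex):
            d["complements"] = node.complements
    elif isinstance(node, Section):
        d["items"] = [locatable_to_dict(i) for i in node.items]
    elif isinstance(node, Composition):
        d["composer"] = _party_to_dict(node.composer)
        d["context_start_time"] = (node.context_start_time.value
                                   if node.context_start_time else None)
        d["ism_transition"] = (
            {"current_state": node.ism_transition.current_state.value,
             "careflow_step": node.ism_transition.careflow_step,
             "timestamp": node.ism_transition.timestamp}
            if node.ism_transition is not None else None)
        d["content"] = [locatable_to_dict(c) for c in node.content]
    return d


def locatable_from_dict(d: dict) -> Locatable:
    rm = d["_rm"]
    cls = rm_core.RM_CLASS_REGISTRY.get(rm)
    if cls is None:
        raise ValueError(f"unknown rm type {rm!r}")
    common = dict(
        name=d["name"],
        archetype_node_id=NodeId(d["archetype_node_id"]),
        archetype_id=d.get("archetype_id"),
        links=[Link(l["meaning"], l["type"], l["target"])
               for l in d.get("links", [])],
    )
    if issubclass(cls, Element):
        return cls(**common,
                   value=_value_from_dict(d["value"]) if d.get("value") else None)
    if cls is rm_core.Cluster:
        return cls(**common, items=[locatable_from_dict(i) for i in d["items"]])
    if cls in (ItemTree, ItemList):
        return cls(**common, items=[locatable_from_dict(i) for i in d["items"]])
    if cls is ItemTable:
        return cls(**common, rows=[locatable_from_dict(r) for r in d["rows"]])
    if cls is ItemSingle:
        return cls(**common,
                   item=locatable_from_dict(d["item"]) if d.get("item") else None)
    if issubclass(cls, Entry):
        kwargs = dict(
            common,
            subject=_party_from_dict(d.get("subject")) or PartySelf(),
            provider=_party_from_dict(d.get("provider")),
            other_participations=[
                Participation(performer=_party_from_dict(p["performer"]),
                              function=p["function"], mode=p.get("mode"))
                for p in d.get("other_participations", [])],
            data=locatable_from_dict(d["data"]) if d.get("data") else None,
        )
        if issubclass(cls, Submission):
            kwargs.update(
                submission_id=d["submission_id"],
                submission_date=d.get("submission_date"),
                original_submission=d.get("original_submission"),
                submitter=_party_from_dict(d.get("submitter")),
                submittee=_party_from_dict(d.get("submittee")),
            )
        if issubclass(cls, Claim):
            kwargs.update(billing_date=d.get("billing_date"))
        if issubclass(cls, ProfessionalClaim):
            kwargs.update(performer=_party_from_dict(d.get("performer")))
        if issubclass(cls, InstitutionalClaim):
            kwargs.update(participants=[_party_from_dict(p)
                                        for p in d.get("participants", [])])
        if issubclass(cls, Authorization):
            kwargs.update(
                requester=_party_from_dict(d.get("requester")),
                authorization_id=d.get("authorization_id"),
                validity=(DateInterval.parse(d["validity"])
                          if d.get("validity") else None),
                is_response=d.get("is_response", False),
            )
        if issubclass(cls, Annex):
            kwargs.update(complements=d.get("complements", ""))
        return cls(**kwargs)
    if cls is Section:
        return cls(**common, items=[locatable_from_dict(i) for i in d["items"]])
    if cls is Composition:
        ism = d.get("ism_transition")
        return cls(
            **common,
            composer=_party_from_dict(d.get("composer")) or PartySelf(),
            context_start_time=(DateTimeValue(d["context_start_time"])
                                if d.get("context_start_time") else None),
            ism_transition=(IsmTransition(
                current_state=ClaimStatus(ism["current_state"]),
                careflow_step=ism.get("careflow_step"),
                timestamp=ism["timestamp"]) if ism else None),
            content=[locatable_from_dict(c) for c in d.get("content", [])],
        )
    raise ValueError(f"cannot deserialize rm type {rm!r}")


def to_json_str(d: dict, indent: Optional[int] = 2) -> str:
    return json.dumps(d, indent=indent, sort_keys=True, ensure_ascii=False)


def composition_to_json(comp: Composition, indent: Optional[int] = 2) -> str:
    return to_json_str(locatable_to_dict(comp), indent)


def composition_from_json(text: str) -> Composition:
    node = locatable_from_dict(json.loads(text))
    if not isinstance(node, Composition):
        raise ValueError("JSON document is not a composition")
    return node


# ---------------------------------------------------------------------------
# XML
# ---------------------------------------------------------------------------

def _party_to_xml(parent: etree._Element, tag: str, p: Optional[PartyProxy]) -> None:
    if p is None:
        return
    el = etree.SubElement(parent, tag)
    if isinstance(p, PartySelf):
        el.set("type", "PARTY_SELF")
        return
    assert isinstance(p, PartyIdentified)
    el.set("type", "PARTY_IDENTIFIED")
    el.set("name", p.name)
    for i in p.identifiers:
        etree.SubElement(el, "identifier", id=i.id, issuer=i.issuer, type=i.type)


def _party_from_xml(el: Optional[etree._Element]) -> Optional[PartyProxy]:
    if el is None:
        return None
    if el.get("type") == "PARTY_SELF":
        return PartySelf()
    return PartyIdentified(
        name=el.get("name", ""),
        identifiers=tuple(IdentifierValue(i.get("id", ""), i.get("issuer", ""),
                                          i.get("type", ""))
                          for i in el.findall("identifier")))


def _value_to_xml(parent: etree._Element, v: DataValue) -> None:
    el = etree.SubElement(parent, "value")
    if isinstance(v, CodedTextValue):
        el.set("dv", "DV_CODED_TEXT")
        el.set("code", v.code)
        el.set("terminology_id", v.terminology_id)
        el.text = v.value
    elif isinstance(v, TextValue):
        el.set("dv", "DV_TEXT")
        el.text = v.value
    elif isinstance(v, DateTimeValue):
        el.set("dv", "DV_DATE_TIME")
        el.text = v.value
    elif isinstance(v, DateValue):
        el.set("dv", "DV_DATE")
        el.text = v.value
    elif isinstance(v, CountValue):
        el.set("dv", "DV_COUNT")
        el.text = str(v.value)
    elif isinstance(v, QuantityValue):
        el.set("dv", "DV_QUANTITY")
        el.set("units", v.units)
        el.text = str(v.magnitude)
    elif isinstance(v, MoneyValue):
        el.set("dv", "DV_MONEY")
        el.set("currency", v.currency)
        el.text = money_str(v.amount)
    elif isinstance(v, IdentifierValue):
        el.set("dv", "DV_IDENTIFIER")
        el.set("id", v.id)
        el.set("issuer", v.issuer)
        el.set("identifier_type", v.type)
    else:
        raise TypeError(type(v).__name__)


def _value_from_xml(el: etree._Element) -> DataValue:
    dv = el.get("dv")
    text = el.text or ""
    if dv == "DV_CODED_TEXT":
        return CodedTextValue(value=text, code=el.get("code", ""),
                              terminology_id=el.get("terminology_id", ""))
    if dv == "DV_TEXT":
        return TextValue(text)
    if dv == "DV_DATE_TIME":
        return DateTimeValue(text)
    if dv == "DV_DATE":
        return DateValue(text)
    if dv == "DV_COUNT":
        return CountValue(int(text))
    if dv == "DV_QUANTITY":
        return QuantityValue(Decimal(text), el.get("units", ""))
    if dv == "DV_MONEY":
        return MoneyValue(Decimal(text), el.get("currency", "BRL"))
    if dv == "DV_IDENTIFIER":
        return IdentifierValue(el.get("id", ""), el.get("issuer", ""),
                               el.get("identifier_type", ""))
    raise ValueError(f"unknown dv {dv!r}")


def _node_to_xml(parent: Optional[etree._Element], tag: str, node: Locatable) -> etree._Element:
    if parent is None:
        el = etree.Element(tag)
    else:
        el = etree.SubElement(parent, tag)
    el.set("rm", rm_core.rm_type_name(node))
    el.set("name", node.name)
    el.set("archetype_node_id", node.archetype_node_id.code)
    if node.archetype_id is not None:
        el.set("archetype_id", node.archetype_id)
    for l in node.links:
        etree.SubElement(el, "link", meaning=l.meaning, type=l.type, target=l.target)

    if isinstance(node, Element):
        if node.value is not None:
            _value_to_xml(el, node.value)
    elif isinstance(node, rm_core.Cluster):
        for i in node.items:
            _node_to_xml(el, "items", i)
    elif isinstance(node, (ItemTree, ItemList)):
        for i in node.items:
            _node_to_xml(el, "items", i)
    elif isinstance(node, ItemTable):
        for r in node.rows:
            _node_to_xml(el, "rows", r)
    elif isinstance(node, ItemSingle):
        if node.item is not None:
            _node_to_xml(el, "item", node.item)
    elif isinstance(node, Entry):
        _party_to_xml(el, "subject", node.subject)
        _party_to_xml(el, "provider", node.provider)
        for p in node.other_participations:
            pe = etree.SubElement(el, "participation", function=p.function)
            if p.mode:
                pe.set("mode", p.mode)
            _party_to_xml(pe, "performer", p.performer)
        if isinstance(node, Submission):
            el.set("submission_id", node.submission_id)
            if node.submission_date:
                el.set("submission_date", node.submission_date)
            if node.original_submission:
                el.set("original_submission", node.original_submission)
            _party_to_xml(el, "submitter", node.submitter)
            _party_to_xml(el, "submittee", node.submittee)
        if isinstance(node, Claim) and node.billing_date:
            el.set("billing_date", node.billing_date)
        if isinstance(node, ProfessionalClaim):
            _party_to_xml(el, "performer", node.performer)
        if isinstance(node, InstitutionalClaim):
            for p in node.participants:
                _party_to_xml(el, "participant", p)
        if isinstance(node, Authorization):
            _party_to_xml(el, "requester", node.requester)
            if node.authorization_id:
                el.set("authorization_id", node.authorization_id)
            if node.validity:
                etree.SubElement(el, "validity", start=node.validity.start,
                                 end=node.validity.end)
            el.set("is_response", "true" if node.is_response else "false")
        if isinstance(node, Annex):
            el.set("complements", node.complements)
        if node.data is not None:
            _node_to_xml(el, "data", node.data)
    elif isinstance(node, Section):
        for i in node.items:
            _node_to_xml(el, "items", i)
    elif isinstance(node, Composition):
        _party_to_xml(el, "composer", node.composer)
        if node.context_start_time is not None:
            el.set("context_start_time", node.context_start_time.value)
        if node.ism_transition is not None:
            it = etree.SubElement(el, "ism_transition",
                                  current_state=node.ism_transition.current_state.value,
                                  timestamp=node.ism_transition.timestamp)
            if node.ism_transition.careflow_step:
                it.set("careflow_step", node.ism_transition.careflow_step)
        for c in node.content:
            _node_to_xml(el, "content", c)
    return el


def _node_from_xml(el: etree._Element) -> Locatable:
    rm = el.get("rm")
    cls = rm_core.RM_CLASS_REGISTRY.get(rm or "")
    if cls is None:
        raise ValueError(f"unknown rm type {rm!r}")
    common = dict(
        name=el.get("name", ""),
        archetype_node_id=NodeId(el.get("archetype_node_id", "")),
        archetype_id=el.get("archetype_id"),
        links=[Link(l.get("meaning", ""), l.get("type", ""), l.get("target", ""))
               for l in el.findall("link")],
    )
    if issubclass(cls, Element):
        v = el.find("value")
        return cls(**common, value=_value_from_xml(v) if v is not None else None)
    if cls is rm_core.Cluster:
        return cls(**common, items=[_node_from_xml(i) for i in el.findall("items")])
    if cls in (ItemTree, ItemList):
        return cls(**common, items=[_node_from_xml(i) for i in el.findall("items")])
    if cls is ItemTable:
        return cls(**common, rows=[_node_from_xml(r) for r in el.findall("rows")])
    if cls is ItemSingle:
        item = el.find("item")
        return cls(**common, item=_node_from_xml(item) if item is not None else None)
    if issubclass(cls, Entry):
        data = el.find("data")
        kwargs = dict(
            common,
            subject=_party_from_xml(el.find("subject")) or PartySelf(),
            provider=_party_from_xml(el.find("provider")),
            other_participations=[
                Participation(performer=_party_from_xml(p.find("performer")),
                              function=p.get("function", ""),
                              mode=p.get("mode"))
                for p in el.findall("participation")],
            data=_node_from_xml(data) if data is not None else None,
        )
        if issubclass(cls, Submission):
            kwargs.update(
                submission_id=el.get("submission_id", ""),
                submission_date=el.get("submission_date"),
                original_submission=el.get("original_submission"),
                submitter=_party_from_xml(el.find("submitter")),
                submittee=_party_from_xml(el.find("submittee")),
            )
        if issubclass(cls, Claim):
            kwargs.update(billing_date=el.get("billing_date"))
        if issubclass(cls, ProfessionalClaim):
            kwargs.update(performer=_party_from_xml(el.find("performer")))
        if issubclass(cls, InstitutionalClaim):
            kwargs.update(participants=[_party_from_xml(p)
                                        for p in el.findall("participant")])
        if issubclass(cls, Authorization):
            val = el.find("validity")
            kwargs.update(
                requester=_party_from_xml(el.find("requester")),
                authorization_id=el.get("authorization_id"),
                validity=(DateInterval(val.get("start"), val.get("end"))
                          if val is not None else None),
                is_response=el.get("is_response") == "true",
            )
        if issubclass(cls, Annex):
            kwargs.update(complements=el.get("complements", ""))
        return cls(**kwargs)
    if cls is Section:
        return cls(**common, items=[_node_from_xml(i) for i in el.findall("items")])
    if cls is Composition:
        it = el.find("ism_transition")
        cst = el.get("context_start_time")
        return cls(
            **common,
            composer=_party_from_xml(el.find("composer")) or PartySelf(),
            context_start_time=DateTimeValue(cst) if cst else None,
            ism_transition=(IsmTransition(
                current_state=ClaimStatus(it.get("current_state")),
                careflow_step=it.get("careflow_step"),
                timestamp=it.get("timestamp")) if it is not None else None),
            content=[_node_from_xml(c) for c in el.findall("content")],
        )
    raise ValueError(f"cannot deserialize rm type {rm!r}")


def composition_to_xml(comp: Composition) -> bytes:
    el = _node_to_xml(None, "composition", comp)
    return etree.tostring(el, pretty_print=True, encoding="UTF-8",
                          xml_declaration=True)


def composition_from_xml(data: Union[bytes, str]) -> Composition:
    if isinstance(data, str):
        data = data.encode("utf-8")
    node = _node_from_xml(etree.fromstring(data))
    if not isinstance(node, Composition):
        raise ValueError("XML document is not a composition")
    return node


# ---------------------------------------------------------------------------
# Extracts
# ---------------------------------------------------------------------------

def extract_to_json(ex: Extract, indent: Optional[int] = 2) -> str:
    return to_json_str({
        "extract_id": ex.extract_id,
        "source_org": _party_to_dict(ex.source_org),
        "target_org": _party_to_dict(ex.target_org),
        "created_at": ex.created_at,
        "items": [{"subject": _party_to_dict(i.subject),
                   "compositions": [locatable_to_dict(c) for c in i.compositions]}
                  for i in ex.items],
    }, indent)


def extract_from_json(text: str) -> Extract:
    d = json.loads(text)
    return Extract(
        extract_id=d["extract_id"],
        source_org=_party_from_dict(d["source_org"]),
        target_org=_party_from_dict(d["target_org"]),
        created_at=d["created_at"],
        items=[ExtractItem(
            subject=_party_from_dict(i["subject"]),
            compositions=[locatable_from_dict(c) for c in i["compositions"]])
            for i in d["items"]],
    )


def extract_to_xml(ex: Extract) -> bytes:
    root = etree.Element("extract", extract_id=ex.extract_id,
                         created_at=ex.created_at)
    _party_to_xml(root, "source_org", ex.source_org)
    _party_to_xml(root, "target_org", ex.target_org)
    for item in ex.items:
        ie = etree.SubElement(root, "item")
        _party_to_xml(ie, "subject", item.subject)
        for comp in item.compositions:
            _node_to_xml(ie, "composition", comp)
    return etree.tostring(root, pretty_print=True, encoding="UTF-8",
                          xml_declaration=True)


def extract_from_xml(data: Union[bytes, str]) -> Extract:
    if isinstance(data, str):
        data = data.encode("utf-8")
    root = etree.fromstring(data)
    return Extract(
        extract_id=root.get("extract_id", ""),
        source_org=_party_from_xml(root.find("source_org")),
        target_org=_party_from_xml(root.find("target_org")),
        created_at=root.get("created_at", ""),
        items=[ExtractItem(
            subject=_party_from_xml(ie.find("subject")),
            compositions=[_node_from_xml(c) for c in ie.findall("composition")])
            for ie in root.findall("item")],
    )
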