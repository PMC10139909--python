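"""Bibliography extraction from JATS/NLM-DTD documents.

References live under ``<ref>`` elements. A single ``<ref>`` may bundle
several cited works, each tagged by its own ``*-citation`` element carrying
an ``id`` attribute; those ids are collected as *member ids* so that inline
cross-references can target either level.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional
from xml.etree.ElementTree import Element

logger = logging.getLogger(__name__)

_PMID_RE = re.compile(r"^\d{1,8}$")
_LEADING_INT_RE = re.compile(r"^\s*(\d+)")


def normalize_ws(text: str) -> str:
    """Collapse runs of whitespace into single spaces and strip the ends."""
    return " ".join(text.split())


def flatten_text(elem: Element, skip: frozenset[str] = frozenset()) -> str:
    """Concatenated visible text of ``elem``, skipping subtrees in ``skip``."""
    parts: list[str] = []
    _collect_text(elem, skip, parts)
    return normalize_ws("".join(parts))


def _collect_text(elem: Element, skip: frozenset[str], parts: list[str]) -> None:
    if elem.text:
        parts.append(elem.text)
    for child in elem:
        if child.tag not in skip:
            _collect_text(child, skip, parts)
        if child.tail:
            parts.append(child.tail)


@dataclass
class ReferenceEntry:
    """One bibliography item (possibly bundling several cited works)."""

    ref_id: str
    member_ids: list[str] = field(default_factory=list)
    raw_text: str = ""
    xml_pmid: Optional[str] = None
    order_index: int = 1
    label: Optional[str] = None
    # PMIDs of nested cited works, keyed by their citation-element id.
    member_pmids: dict[str, Optional[str]] = field(default_factory=dict)


class ReferenceRegistry:
    """Ordered reference entries with an index over ref ids and member ids."""

    def __init__(self, entries: Optional[list[ReferenceEntry]] = None):
        self.entries: list[ReferenceEntry] = []
        self.id_index: dict[str, ReferenceEntry] = {}
        self._flat_ids: list[str] = []
        self._positions: dict[str, int] = {}
        self._label_index: dict[str, ReferenceEntry] = {}
        for entry in entries or []:
            self.add(entry)

    def add(self, entry: ReferenceEntry) -> None:
        if entry.ref_id in self.id_index:
            raise ValueError(f"duplicate reference id {entry.ref_id!r}")
        self.entries.append(entry)
        self.id_index[entry.ref_id] = entry
        for mid in entry.member_ids:
            self.id_index.setdefault(mid, entry)
        if entry.member_ids:
            for mid in entry.member_ids:
                self._positions.setdefault(mid, len(self._flat_ids))
                self._flat_ids.append(mid)
            self._positions.setdefault(entry.ref_id, self._positions[entry.member_ids[0]])
        else:
            self._positions[entry.ref_id] = len(self._flat_ids)
            self._flat_ids.append(entry.ref_id)
        if entry.label is not None and entry.label not in self._label_index:
            self._label_index[entry.label] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ReferenceEntry]:
        return iter(self.entries)

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self.id_index

    def resolve(self, ref_id: str) -> Optional[ReferenceEntry]:
        return self.id_index.get(ref_id)

    def position_of(self, ref_id: str) -> Optional[int]:
        """Position of an id in the flat (member-expanded) ordering."""
        return self._positions.get(ref_id)

    def flat_ids(self) -> list[str]:
        return list(self._flat_ids)

    def slice_between(self, first_id: str, second_id: str) -> list[str]:
        """Ids strictly between two resolved ids in flat registry order."""
        p1 = self.position_of(first_id)
        p2 = self.position_of(second_id)
        if p1 is None or p2 is None or p2 <= p1:
            return []
        return self._flat_ids[p1 + 1:p2]

    def entry_by_label(self, label: str) -> Optional[ReferenceEntry]:
        return self._label_index.get(label)

    @property
    def has_labels(self) -> bool:
        return bool(self._label_index)

    def pmid_for(self, ref_id: str) -> Optional[str]:
        """XML-tagged PMID for a resolved id (member ids get their own PMID)."""
        entry = self.id_index.get(ref_id)
        if entry is None:
            return None
        if ref_id in entry.member_pmids:
            return entry.member_pmids[ref_id]
        return entry.xml_pmid


def extract_pmid(reference_element: Element) -> Optional[str]:
    """PMID of a reference element, read from its first pmid-typed pub-id.

    Non-numeric content signals a publisher tagging error: a warning is
    logged and ``None`` returned.
    """
    for pub_id in reference_element.iter("pub-id"):
        if pub_id.get("pub-id-type") != "pmid":
            continue
        text = (pub_id.text or "").strip()
        if _PMID_RE.match(text):
            return text
        logger.warning("non-numeric pmid %r on element %r", text,
                       reference_element.get("id"))
        return None
    return None


def extract_references(article_document: Element) -> ReferenceRegistry:
    """Build the ReferenceRegistry of a parsed article.

    One entry per ``<ref>`` element in document order; ``*-citation``
    children carrying ``id`` attributes become member ids. Documents with
    no reference list yield an empty registry. Duplicate ref ids keep the
    first occurrence (a warning names both positions).
    """
    registry = ReferenceRegistry()
    seen_positions: dict[str, int] = {}
    for position, ref in enumerate(article_document.iter("ref"), start=1):
        ref_id = (ref.get("id") or "").strip()
        if not ref_id:
            logger.warning("ref element #%d has no id attribute; skipped", position)
            continue
        if ref_id in seen_positions:
            logger.warning("duplicate ref id %r at positions %d and %d; keeping first",
                           ref_id, seen_positions[ref_id], position)
            continue
        seen_positions[ref_id] = position
        entry = _build_entry(ref, ref_id, len(registry) + 1)
        registry.add(entry)
    return registry


def _build_entry(ref: Element, ref_id: str, order_index: int) -> ReferenceEntry:
    member_ids: list[str] = []
    member_pmids: dict[str, Optional[str]] = {}
    for node in ref.iter():
        if node is ref:
            continue
        if "citation" in node.tag and node.get("id"):
            mid = node.get("id", "").strip()
            if mid and mid != ref_id and mid not in member_ids:
                member_ids.append(mid)
                member_pmids[mid] = extract_pmid(node)
    raw_text = flatten_text(ref)
    label = _extract_label(ref, raw_text)
    # A multi-work reference has no single PMID of its own.
    xml_pmid = None if member_ids else extract_pmid(ref)
    return ReferenceEntry(
        ref_id=ref_id,
        member_ids=member_ids,
        raw_text=raw_text,
        xml_pmid=xml_pmid,
        order_index=order_index,
        label=label,
        member_pmids=member_pmids,
    )


def _extract_label(ref: Element, raw_text: str) -> Optional[str]:
    label_el = ref.find("label")
    if label_el is not None:
        text = flatten_text(label_el).rstrip(".")
        if text:
            return text
    m = _LEADING_INT_RE.match(raw_text)
    if m:
        return m.group(1)
    return None
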