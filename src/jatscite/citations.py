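"""Inline-citation detection and annotation.

Explicit citations are ``<xref>`` elements whose ``rid`` resolves in the
reference registry; cross-references to figures or tables never resolve
there and are left as plain text. Implicitly-mentioned citations come in
two tagging styles:

* *paired*: two xrefs separated only by a range separator, e.g.
  ``[<xref>3</xref>–<xref>6</xref>]`` — the works strictly between the two
  endpoints are implied;
* *single*: one xref whose visible marker is itself a numeric range, e.g.
  ``[<xref>3–6</xref>]`` — enumeration runs from the left label to the end
  of the marker.

Recognized range separators are the hyphen-minus, the en dash (U+2013),
the minus sign (U+2212), and doubled runs of any of these, optionally
surrounded by whitespace.

Every detected citation marker is rewritten as a ``|ref-id|`` token;
implicit citations append their tokens, comma-separated, right after the
closing explicit token of their range.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional
from xml.etree.ElementTree import Element

from .references import ReferenceRegistry, normalize_ws

logger = logging.getLogger(__name__)

_SEPARATOR_CHARS = "-–−"  # hyphen-minus, en dash, minus sign
_SINGLE_RANGE_RE = re.compile(
    r"^\s*(\d+)\s*([" + _SEPARATOR_CHARS + r"]{1,2})\s*(\d+)\s*$")
TOKEN_RE = re.compile(r"\|([^|]+)\|")


@dataclass
class InlineCitation:
    """One resolved citation occurrence within a text fragment."""

    intxt_id: str
    intxt_mark: str
    implicit: bool = False
    span: Optional[tuple[int, int]] = None
    fragment_ref: Optional[int] = None


def is_range_separator(between_text: str) -> bool:
    """True iff the text between two markers denotes a citation range."""
    t = between_text.strip()
    return 1 <= len(t) <= 2 and all(c in _SEPARATOR_CHARS for c in t)


def find_explicit(fragment_element: Element,
                  registry: ReferenceRegistry) -> list[InlineCitation]:
    """Explicit inline citations of a fragment, in document order.

    An xref whose ``rid`` holds several whitespace-separated ids yields one
    citation per resolvable id, all sharing the visible marker.
    """
    citations: list[InlineCitation] = []
    for item in _collect_items(fragment_element, registry):
        if item[0] == "cite":
            _, marker, ids = item
            citations.extend(
                InlineCitation(intxt_id=i, intxt_mark=marker) for i in ids)
    return citations


def expand_paired_range(first: InlineCitation, second: InlineCitation,
                        registry: ReferenceRegistry,
                        mark: Optional[str] = None) -> list[InlineCitation]:
    """Implicit citations strictly between two explicit range endpoints.

    Enumeration runs over the flat (member-expanded) registry order; a
    reversed or degenerate pair expands to nothing, with a warning for the
    reversed case since it signals publisher mis-tagging.
    """
    p1 = registry.position_of(first.intxt_id)
    p2 = registry.position_of(second.intxt_id)
    if p1 is None or p2 is None:
        return []
    if p2 < p1:
        logger.warning("reversed citation range %r..%r; not expanded",
                       first.intxt_id, second.intxt_id)
        return []
    if mark is None:
        mark = f"{first.intxt_mark}–{second.intxt_mark}"
    return [InlineCitation(intxt_id=i, intxt_mark=mark, implicit=True)
            for i in registry.slice_between(first.intxt_id, second.intxt_id)]


def expand_single_range(citation: InlineCitation,
                        registry: ReferenceRegistry) -> list[InlineCitation]:
    """Implicit citations implied by a single range marker such as ``3–6``.

    The enumeration covers the labels strictly after the left label up to
    and including the right one. Resolution is by reference label, falling
    back to flat registry positions when the registry carries no labels.
    Unresolvable tails expand to the resolvable prefix with a warning.
    """
    m = _SINGLE_RANGE_RE.match(citation.intxt_mark)
    if m is None:
        return []
    left, right = int(m.group(1)), int(m.group(3))
    if right <= left:
        if right < left:
            logger.warning("reversed range marker %r; not expanded",
                           citation.intxt_mark)
        return []
    expanded: list[InlineCitation] = []
    if registry.has_labels:
        for value in range(left + 1, right + 1):
            entry = registry.entry_by_label(str(value))
            if entry is None:
                logger.warning("range %r: no reference labelled %d; "
                               "expanded prefix only", citation.intxt_mark, value)
                break
            expanded.append(InlineCitation(
                intxt_id=entry.ref_id, intxt_mark=citation.intxt_mark,
                implicit=True))
    else:
        pos = registry.position_of(citation.intxt_id)
        if pos is None:
            return []
        flat = registry.flat_ids()
        stop = pos + (right - left) + 1
        if stop > len(flat):
            logger.warning("range %r overruns the reference list; "
                           "expanded prefix only", citation.intxt_mark)
            stop = len(flat)
        expanded = [InlineCitation(intxt_id=i, intxt_mark=citation.intxt_mark,
                                   implicit=True)
                    for i in flat[pos + 1:stop]]
    return expanded


def annotate_fragment(fragment_element: Element, registry: ReferenceRegistry,
                      skip: frozenset[str] = frozenset()
                      ) -> tuple[str, list[InlineCitation]]:
    """Annotated text of a fragment plus its citations in token order.

    Citation markers are replaced in place by ``|id|`` tokens; implicit
    tokens are appended, comma-separated, after the closing explicit token
    of their range. The returned citations carry their token spans and are
    ordered exactly as their tokens occur in the text, so the multiset of
    tokens equals the multiset of citation ids.
    """
    items = _collect_items(fragment_element, registry, skip)
    builder = _TextBuilder()
    citations: list[InlineCitation] = []
    i = 0
    while i < len(items):
        item = items[i]
        if item[0] == "text":
            builder.emit_text(item[1])
            i += 1
            continue
        _, marker, ids = item
        # Paired style: cite, separator-only text, cite.
        if (i + 2 < len(items) and items[i + 1][0] == "text"
                and is_range_separator(items[i + 1][1])
                and items[i + 2][0] == "cite"):
            sep_text = items[i + 1][1]
            marker2, ids2 = items[i + 2][1], items[i + 2][2]
            combined = f"{marker}{sep_text.strip()}{marker2}"
            first = InlineCitation(intxt_id=ids[-1], intxt_mark=marker)
            second = InlineCitation(intxt_id=ids2[0], intxt_mark=marker2)
            implicit = expand_paired_range(first, second, registry, mark=combined)
            citations.extend(builder.emit_tokens(ids, marker))
            builder.emit_text(sep_text)
            citations.extend(builder.emit_tokens(ids2, marker2))
            citations.extend(builder.emit_implicit(implicit))
            i += 3
            continue
        # Single style: a lone xref whose marker is a numeric range.
        single = _SINGLE_RANGE_RE.match(marker)
        if single and len(ids) == 1:
            explicit = InlineCitation(intxt_id=ids[0], intxt_mark=marker)
            implicit = expand_single_range(explicit, registry)
            # The endpoint may appear in the expansion when labels restart;
            # drop self-references defensively.
            implicit = [c for c in implicit if c.intxt_id != ids[0]]
            citations.extend(builder.emit_tokens(ids, marker))
            citations.extend(builder.emit_implicit(implicit))
            i += 1
            continue
        if single is None and len(ids) == 1 and \
                any(c in marker for c in _SEPARATOR_CHARS) and \
                re.search(r"\d\w*\s*[" + _SEPARATOR_CHARS + r"]", marker):
            logger.warning("non-numeric range marker %r left unexpanded", marker)
        citations.extend(builder.emit_tokens(ids, marker))
        i += 1
    return builder.result(), citations


class _TextBuilder:
    """Accumulates annotated text while recording citation token spans."""

    def __init__(self) -> None:
        self._parts: list[str] = []
        self._length = 0

    def emit_text(self, text: str) -> None:
        text = re.sub(r"\s+", " ", text)
        if not self._parts:
            text = text.lstrip()
        elif text.startswith(" ") and self._parts[-1].endswith(" "):
            text = text[1:]
        if text:
            self._parts.append(text)
            self._length += len(text)

    def emit_tokens(self, ids: list[str], marker: str) -> list[InlineCitation]:
        citations = []
        for n, ref_id in enumerate(ids):
            if n:
                self._append(",")
            citations.append(self._token(ref_id, marker, implicit=False))
        return citations

    def emit_implicit(self, implicit: list[InlineCitation]) -> list[InlineCitation]:
        citations = []
        for cit in implicit:
            self._append(",")
            citations.append(self._token(cit.intxt_id, cit.intxt_mark,
                                         implicit=True))
        return citations

    def _token(self, ref_id: str, marker: str, implicit: bool) -> InlineCitation:
        token = f"|{ref_id}|"
        start = self._length
        self._append(token)
        return InlineCitation(intxt_id=ref_id, intxt_mark=normalize_ws(marker),
                              implicit=implicit, span=(start, start + len(token)))

    def _append(self, s: str) -> None:
        self._parts.append(s)
        self._length += len(s)

    def result(self) -> str:
        return "".join(self._parts).rstrip()


def _collect_items(elem: Element, registry: ReferenceRegistry,
                   skip: frozenset[str] = frozenset()) -> list:
    """Linearize a fragment into text chunks and resolved citation markers."""
    raw: list = []
    _walk_items(elem, registry, skip, raw, top=True)
    # Merge adjacent text chunks so separator detection sees one piece.
    items: list = []
    for item in raw:
        if item[0] == "text" and items and items[-1][0] == "text":
            items[-1] = ("text", items[-1][1] + item[1])
        else:
            items.append(item)
    return [it for it in items if it[0] == "cite" or it[1]]


def _walk_items(elem: Element, registry: ReferenceRegistry,
                skip: frozenset[str], items: list, top: bool = False) -> None:
    if elem.text:
        items.append(("text", elem.text))
    for child in elem:
        if child.tag in skip:
            pass
        elif child.tag == "xref":
            marker = normalize_ws("".join(child.itertext()))
            rids = (child.get("rid") or "").split()
            resolved = [r for r in rids if r in registry]
            if resolved:
                if len(resolved) < len(rids):
                    logger.info("xref rid(s) %r did not resolve; skipped",
                                [r for r in rids if r not in registry])
                items.append(("cite", marker, resolved))
            else:
                if rids and child.get("ref-type") in (None, "bibr"):
                    logger.info("unresolvable xref rid %r kept as text", rids)
                if marker:
                    items.append(("text", marker))
        else:
            _walk_items(child, registry, skip, items)
        if child.tail:
            items.append(("text", child.tail))
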