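"""Split an article into components (abstract, body, table, figure, back)
and ordered text fragments carrying their section context.

Paragraphs and quote blocks are the textual units; tables contribute one
fragment per cell plus their caption; figures contribute their caption.
Figures and tables nested inside paragraphs are lifted out as components of
their own, and their text is excluded from the hosting paragraph.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional
from xml.etree.ElementTree import Element

from .references import flatten_text


class ComponentKind(str, Enum):
    ABSTRACT = "abstract"
    BODY = "body"
    TABLE = "table"
    FIGURE = "figure"
    BACK = "back"


@dataclass(frozen=True)
class SectionContext:
    title: str = ""
    label: str = ""
    sec_type: str = ""

    def as_string(self) -> str:
        """Concatenated title/label/sec-type used for IMRaD matching."""
        return " ".join(p for p in (self.title, self.label, self.sec_type) if p)


@dataclass
class TextFragment:
    component: ComponentKind
    section_path: tuple[SectionContext, ...]
    fragment_kind: str  # paragraph | quote | caption | table_cell
    text: str
    order_index: int
    instance_id: int
    element: Optional[Element] = field(default=None, compare=False, repr=False)


# Subtrees excluded from a paragraph's own text (lifted as components).
PARAGRAPH_SKIP = frozenset({"table-wrap", "table-wrap-group", "fig", "fig-group"})
_TABLE_TAGS = ("table-wrap", "table-wrap-group", "array")
_FIGURE_TAGS = ("fig", "fig-group")


def iter_table_cells(table_element: Element) -> list[Element]:
    """td/th cell elements of a table-wrap, table, tbody or array, row-major."""
    cells: list[Element] = []
    for tr in table_element.iter("tr"):
        for cell in tr:
            if cell.tag in ("td", "th"):
                cells.append(cell)
    return cells


def extract_table_cells(table_element: Element) -> list[TextFragment]:
    """Standalone cell extraction: one table_cell fragment per non-empty cell."""
    fragments: list[TextFragment] = []
    for cell in iter_table_cells(table_element):
        text = flatten_text(cell)
        if not text and cell.find(".//xref") is None:
            continue
        fragments.append(TextFragment(
            component=ComponentKind.TABLE,
            section_path=(),
            fragment_kind="table_cell",
            text=text,
            order_index=len(fragments) + 1,
            instance_id=0,
            element=cell,
        ))
    return fragments


def section_context_of(root: Element, node: Element) -> list[SectionContext]:
    """SectionContexts of the sec ancestors of ``node``, outermost first."""
    parents = {child: parent for parent in root.iter() for child in parent}
    path: list[SectionContext] = []
    current = node
    while current in parents:
        current = parents[current]
        if current.tag == "sec":
            path.append(_section_context(current))
    return list(reversed(path))


def _section_context(sec: Element) -> SectionContext:
    title_el = sec.find("title")
    label_el = sec.find("label")
    return SectionContext(
        title=flatten_text(title_el) if title_el is not None else "",
        label=flatten_text(label_el) if label_el is not None else "",
        sec_type=" ".join((sec.get("sec-type") or "").split()),
    )


class _Segmenter:
    def __init__(self) -> None:
        self.fragments: list[TextFragment] = []
        self._next_instance = 0
        self._order: dict[int, int] = {}
        self._body_instance: Optional[int] = None
        self._back_instance: Optional[int] = None

    def _new_instance(self) -> int:
        self._next_instance += 1
        self._order[self._next_instance] = 0
        return self._next_instance

    def _instance_for(self, component: ComponentKind) -> int:
        if component is ComponentKind.BODY:
            if self._body_instance is None:
                self._body_instance = self._new_instance()
            return self._body_instance
        if component is ComponentKind.BACK:
            if self._back_instance is None:
                self._back_instance = self._new_instance()
            return self._back_instance
        return self._new_instance()

    def _add(self, instance_id: int, component: ComponentKind, kind: str,
             elem: Element, path: tuple[SectionContext, ...],
             skip: frozenset[str] = frozenset()) -> None:
        text = flatten_text(elem, skip)
        if not text and elem.find(".//xref") is None:
            return
        self._order[instance_id] += 1
        self.fragments.append(TextFragment(
            component=component,
            section_path=path,
            fragment_kind=kind,
            text=text,
            order_index=self._order[instance_id],
            instance_id=instance_id,
            element=elem,
        ))

    def walk(self, elem: Element, component: ComponentKind,
             path: tuple[SectionContext, ...]) -> None:
        for child in elem:
            tag = child.tag
            if tag == "sec":
                self.walk(child, component, path + (_section_context(child),))
            elif tag in _TABLE_TAGS:
                self.emit_table(child, path)
            elif tag in _FIGURE_TAGS:
                self.emit_figure(child, path)
            elif tag in ("p", "disp-quote"):
                kind = "paragraph" if tag == "p" else "quote"
                instance = self._instance_for(component)
                self._add(instance, component, kind, child, path, PARAGRAPH_SKIP)
                for sub in child.iter():
                    if sub is child:
                        continue
                    if sub.tag in _TABLE_TAGS:
                        self.emit_table(sub, path)
                    elif sub.tag in _FIGURE_TAGS:
                        self.emit_figure(sub, path)
            elif tag in ("ref-list", "title", "label"):
                continue
            else:
                self.walk(child, component, path)

    def emit_table(self, table: Element, path: tuple[SectionContext, ...]) -> None:
        instance = self._new_instance()
        for child in table:
            tag = child.tag
            if tag == "caption":
                self._emit_caption(instance, ComponentKind.TABLE, child, path)
            elif tag in ("table", "tbody", "thead", "array"):
                self._emit_cells(instance, child, path)
            elif tag == "table-wrap-foot":
                for p in child.iter("p"):
                    self._add(instance, ComponentKind.TABLE, "caption", p, path)
            elif tag == "table-wrap":  # table-wrap-group member
                self.emit_table(child, path)
        if table.tag == "array" and table.find(".//tr") is not None and \
                not any(c.tag in ("table", "tbody", "thead") for c in table):
            self._emit_cells(instance, table, path)

    def _emit_cells(self, instance: int, elem: Element,
                    path: tuple[SectionContext, ...]) -> None:
        for cell in iter_table_cells(elem):
            self._add(instance, ComponentKind.TABLE, "table_cell", cell, path)

    def emit_figure(self, fig: Element, path: tuple[SectionContext, ...]) -> None:
        instance = self._new_instance()
        for caption in fig.iter("caption"):
            self._emit_caption(instance, ComponentKind.FIGURE, caption, path)

    def _emit_caption(self, instance: int, component: ComponentKind,
                      caption: Element, path: tuple[SectionContext, ...]) -> None:
        for child in caption:
            if child.tag in ("title", "p"):
                self._add(instance, component, "caption", child, path)


def segment(article_document: Element) -> list[TextFragment]:
    """All text fragments of an article in document order.

    Abstracts (including trans-abstract) come first, then body content in
    document order (tables and figures as their own component instances),
    then back matter. Reference lists never yield fragments.
    """
    seg = _Segmenter()
    front = article_document.find("front")
    if front is not None:
        for abstract in front.iter():
            if abstract.tag in ("abstract", "trans-abstract"):
                instance = seg._new_instance()
                _walk_abstract(seg, abstract, instance)
    body = article_document.find("body")
    if body is not None:
        seg.walk(body, ComponentKind.BODY, ())
    back = article_document.find("back")
    if back is not None:
        seg.walk(back, ComponentKind.BACK, ())
    return seg.fragments


def _walk_abstract(seg: _Segmenter, elem: Element, instance: int,
                   path: tuple[SectionContext, ...] = ()) -> None:
    for child in elem:
        if child.tag == "sec":
            _walk_abstract(seg, child, instance, path + (_section_context(child),))
        elif child.tag in ("p", "disp-quote"):
            kind = "paragraph" if child.tag == "p" else "quote"
            seg._add(instance, ComponentKind.ABSTRACT, kind, child, path,
                     PARAGRAPH_SKIP)
        elif child.tag in ("title", "label"):
            continue
        else:
            _walk_abstract(seg, child, instance, path)
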