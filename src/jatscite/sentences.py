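"""Sentence tokenization, output-record assembly, and TSV serialization.

The output schema is one row per sentence, duplicated per inline citation
when a sentence hosts several. Sentence ids and totals are per component
instance (each table and each figure is its own instance); progression is
the ceiling centile of the sentence within its component (or within the
whole main text in ``maintext`` mode).
"""
from __future__ import annotations

import io
import math
import re
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO, Union

from .citations import TOKEN_RE
from .components import ComponentKind
from .config import DEFAULT_ABBREVIATIONS, PipelineConfig
from .imrad import label_fragment

COLUMNS = [
    "pmcid", "pmid", "location", "IMRaD", "sentence_id", "total_sentences",
    "intxt_id", "intxt_pmid", "intxt_pmid_source", "intxt_mark",
    "best_id", "best_source", "best_id_diff", "progression",
]
TEXT_COLUMN = "text"

_INT_COLUMNS = {"sentence_id", "total_sentences", "progression"}


@dataclass
class SentenceRecord:
    pmcid: str
    pmid: Optional[str]
    location: str
    imrad: str
    sentence_id: int
    total_sentences: int
    intxt_id: Optional[str] = None
    intxt_pmid: Optional[str] = None
    intxt_pmid_source: str = ""
    intxt_mark: Optional[str] = None
    best_id: Optional[str] = None
    best_source: str = ""
    best_id_diff: Optional[str] = None
    progression: int = 1
    text: str = ""


def compute_progression(sentence_id: int, total_sentences: int) -> int:
    """Ceiling centile of a sentence within its component, in 1..100."""
    if not 1 <= sentence_id <= total_sentences:
        raise ValueError(
            f"sentence_id {sentence_id} outside 1..{total_sentences}")
    return math.ceil(100 * sentence_id / total_sentences)


# Sentence boundary: terminal punctuation, optional closing quotes or
# brackets, whitespace, then an upper-case/digit/opening char.
_BOUNDARY_RE = re.compile(
    r"([.!?])([\"'”’)\]]*)(\s+)(?=[A-Z0-9(\[|\"'“‘])")
_TRAILING_WORD_RE = re.compile(r"([A-Za-z][\w.]*)$")


def tokenize(annotated_text: str,
             abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS) -> list[str]:
    """Deterministic abbreviation-aware sentence segmentation.

    ``|id|`` tokens are never split (they contain no boundary pattern), and
    the concatenation of the output equals the input up to inter-sentence
    whitespace.
    """
    text = annotated_text.strip()
    if not text:
        return []
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        if m.start(1) < start:
            continue
        prev = _TRAILING_WORD_RE.search(text, start, m.start(1))
        if prev is not None:
            word = prev.group(1)
            stem = word.rstrip(".").lower()
            if stem in abbreviations or word.lower() in abbreviations:
                continue
            if len(word) == 1 and word.isupper():
                continue  # personal initial, e.g. "J. Smith"
        sentences.append(text[start:m.start(3)])
        start = m.end(3)
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return [s.strip() for s in sentences]


@dataclass
class AnnotatedFragment:
    fragment: object  # components.TextFragment
    text: str
    citations: list = field(default_factory=list)


@dataclass
class ComponentInstance:
    kind: ComponentKind
    fragments: list[AnnotatedFragment] = field(default_factory=list)


@dataclass
class ArticleContext:
    """Everything build_records needs for one article."""

    pmcid: str
    pmid: Optional[str]
    registry: object  # references.ReferenceRegistry
    instances: list[ComponentInstance]
    reconciliations: dict = field(default_factory=dict)  # intxt_id -> result


_MAINTEXT_KINDS = (ComponentKind.BODY, ComponentKind.TABLE, ComponentKind.FIGURE)


def build_records(article: ArticleContext,
                  config: Optional[PipelineConfig] = None) -> list[SentenceRecord]:
    """Assemble output rows for one article.

    A citation-free sentence yields one row with empty citation fields; a
    sentence with k inline citations yields k rows sharing its sentence_id,
    text, IMRaD label, and progression.
    """
    config = config or PipelineConfig()
    per_instance = []
    for inst in article.instances:
        sentences = []
        for af in inst.fragments:
            if af.fragment.fragment_kind == "table_cell":
                sents = [af.text] if af.text else []
            else:
                sents = tokenize(af.text, config.abbreviations)
            queue = deque(af.citations)
            for sent in sents:
                n_tokens = len(TOKEN_RE.findall(sent))
                cits = [queue.popleft() for _ in range(n_tokens)]
                sentences.append((sent, cits, af.fragment))
        per_instance.append((inst, sentences))

    maintext_total = sum(len(sentences) for inst, sentences in per_instance
                         if inst.kind in _MAINTEXT_KINDS)
    maintext_pos = 0

    records: list[SentenceRecord] = []
    for inst, sentences in per_instance:
        total = len(sentences)
        location = config.location_labels[inst.kind.value]
        for idx, (sent, cits, fragment) in enumerate(sentences, start=1):
            imrad = label_fragment(fragment, config.imrad_rules)
            if (config.progression_mode == "maintext"
                    and inst.kind in _MAINTEXT_KINDS and maintext_total):
                maintext_pos += 1
                progression = compute_progression(maintext_pos, maintext_total)
            else:
                progression = compute_progression(idx, total)
            base = dict(
                pmcid=article.pmcid, pmid=article.pmid, location=location,
                imrad=imrad, sentence_id=idx, total_sentences=total,
                progression=progression, text=sent,
            )
            if not cits:
                if not config.contexts_only:
                    records.append(SentenceRecord(**base))
                continue
            for cit in cits:
                rec = SentenceRecord(**base)
                rec.intxt_id = cit.intxt_id
                rec.intxt_mark = cit.intxt_mark
                recon = article.reconciliations.get(cit.intxt_id)
                if recon is not None:
                    rec.intxt_pmid = recon.intxt_pmid
                    rec.intxt_pmid_source = recon.intxt_pmid_source
                    rec.best_id = recon.best_id
                    rec.best_source = recon.best_source
                    rec.best_id_diff = recon.best_id_diff
                records.append(rec)
    return records


def _sanitize(value: str) -> str:
    return re.sub(r"[\t\n\r]+", " ", value)


def write_tsv(records: Iterable[SentenceRecord],
              sink: Union[str, TextIO], include_text: bool = True) -> None:
    """Write records as UTF-8 TSV: header row, empty optionals as empty
    fields, internal tabs/newlines replaced by spaces, no quoting."""
    own = isinstance(sink, str)
    fh = open(sink, "w", encoding="utf-8", newline="") if own else sink
    try:
        columns = COLUMNS + [TEXT_COLUMN] if include_text else COLUMNS
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            row = [
                rec.pmcid, rec.pmid or "", rec.location, rec.imrad,
                str(rec.sentence_id), str(rec.total_sentences),
                rec.intxt_id or "", rec.intxt_pmid or "",
                rec.intxt_pmid_source or "", rec.intxt_mark or "",
                rec.best_id or "", rec.best_source or "",
                rec.best_id_diff or "", str(rec.progression),
            ]
            if include_text:
                row.append(rec.text)
            fh.write("\t".join(_sanitize(v) for v in row) + "\n")
    finally:
        if own:
            fh.close()


def read_tsv(source: Union[str, TextIO]) -> list[SentenceRecord]:
    """Read back a TSV written by :func:`write_tsv`."""
    own = isinstance(source, str)
    fh = open(source, "r", encoding="utf-8", newline="") if own else source
    try:
        header = fh.readline().rstrip("\n").split("\t")
        has_text = header[-1] == TEXT_COLUMN
        records = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            rec = SentenceRecord(
                pmcid=fields[0], pmid=fields[1] or None, location=fields[2],
                imrad=fields[3], sentence_id=int(fields[4]),
                total_sentences=int(fields[5]), intxt_id=fields[6] or None,
                intxt_pmid=fields[7] or None, intxt_pmid_source=fields[8],
                intxt_mark=fields[9] or None, best_id=fields[10] or None,
                best_source=fields[11], best_id_diff=fields[12] or None,
                progression=int(fields[13]),
                text=fields[14] if has_text and len(fields) > 14 else "",
            )
            records.append(rec)
        return records
    finally:
        if own:
            fh.close()
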