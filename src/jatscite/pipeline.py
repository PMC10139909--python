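"""End-to-end article processing and batch orchestration."""
from __future__ import annotations

import logging
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Optional, Union

from .citations import TOKEN_RE, annotate_fragment
from .components import PARAGRAPH_SKIP, segment
from .config import PipelineConfig
from .reconcile import MatchCandidate, ReconciliationResult, reconcile
from .references import ReferenceRegistry, extract_references
from .sentences import (AnnotatedFragment, ArticleContext, ComponentInstance,
                        SentenceRecord, build_records, tokenize, write_tsv)

logger = logging.getLogger(__name__)


class ArticleParseError(Exception):
    """Raised when an input file is not well-formed XML."""


@dataclass
class ArticleStats:
    pmcid: str = ""
    n_references: int = 0
    n_explicit_citations: int = 0
    n_implicit_citations: int = 0
    n_citation_contexts: int = 0
    n_refs_without_context: int = 0

    @property
    def n_inline_citations(self) -> int:
        return self.n_explicit_citations + self.n_implicit_citations


@dataclass
class RunSummary:
    n_articles_processed: int = 0
    n_articles_with_contexts: int = 0
    n_references: int = 0
    n_explicit_citations: int = 0
    n_implicit_citations: int = 0
    n_citation_contexts: int = 0
    n_refs_without_context: int = 0
    failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_inline_citations(self) -> int:
        return self.n_explicit_citations + self.n_implicit_citations

    def add(self, stats: ArticleStats) -> None:
        self.n_articles_processed += 1
        if stats.n_citation_contexts:
            self.n_articles_with_contexts += 1
        self.n_references += stats.n_references
        self.n_explicit_citations += stats.n_explicit_citations
        self.n_implicit_citations += stats.n_implicit_citations
        self.n_citation_contexts += stats.n_citation_contexts
        self.n_refs_without_context += stats.n_refs_without_context

    def to_dict(self) -> dict:
        return {
            "n_articles_processed": self.n_articles_processed,
            "n_articles_with_contexts": self.n_articles_with_contexts,
            "n_references": self.n_references,
            "n_inline_citations": self.n_inline_citations,
            "n_explicit_citations": self.n_explicit_citations,
            "n_implicit_citations": self.n_implicit_citations,
            "n_citation_contexts": self.n_citation_contexts,
            "n_refs_without_context": self.n_refs_without_context,
            "failures": [{"file": f, "error": e} for f, e in self.failures],
        }


def parse_article(source: Union[str, os.PathLike],
                  text: Optional[str] = None) -> ET.Element:
    """Parse an article file (or raw text), naming the file on parse errors."""
    try:
        if text is not None:
            return ET.fromstring(text)
        return ET.parse(source).getroot()
    except ET.ParseError as exc:
        raise ArticleParseError(f"malformed XML in {source}: {exc}") from exc


def article_ids(root: ET.Element) -> tuple[str, Optional[str]]:
    """(pmcid, pmid) of the citing article, read from front/article-meta."""
    pmcid, pmid = "", None
    meta = root.find("front/article-meta")
    if meta is not None:
        for aid in meta.findall("article-id"):
            kind = (aid.get("pub-id-type") or "").lower()
            value = (aid.text or "").strip()
            if kind in ("pmc", "pmcid") and not pmcid:
                pmcid = value.removeprefix("PMC")
            elif kind == "pmid" and pmid is None:
                pmid = value or None
    return pmcid, pmid


def process_article(root: ET.Element,
                    config: Optional[PipelineConfig] = None,
                    candidates: Optional[dict] = None,
                    entrez: Optional[dict] = None,
                    ) -> tuple[list[SentenceRecord], ArticleStats]:
    """Run the full pipeline on one parsed article.

    ``candidates`` maps (pmcid, ref_id) to MatchCandidate lists;
    ``entrez`` maps pmcid to the set of cited PMIDs. Either may be None.
    """
    config = config or PipelineConfig()
    registry = extract_references(root)
    pmcid, pmid = article_ids(root)
    fragments = segment(root)

    instances: list[ComponentInstance] = []
    by_instance: dict[int, ComponentInstance] = {}
    stats = ArticleStats(pmcid=pmcid, n_references=len(registry))
    cited_ids: set[str] = set()

    for frag in fragments:
        skip = PARAGRAPH_SKIP if frag.fragment_kind in ("paragraph", "quote") \
            else frozenset()
        annotated, cits = annotate_fragment(frag.element, registry, skip)
        if frag.instance_id not in by_instance:
            inst = ComponentInstance(kind=frag.component)
            by_instance[frag.instance_id] = inst
            instances.append(inst)
        by_instance[frag.instance_id].fragments.append(
            AnnotatedFragment(fragment=frag, text=annotated, citations=cits))
        for cit in cits:
            cited_ids.add(cit.intxt_id)
            if cit.implicit:
                stats.n_implicit_citations += 1
            else:
                stats.n_explicit_citations += 1

    reconciliations = _reconcile_all(pmcid, registry, cited_ids,
                                     candidates, entrez, config)
    article = ArticleContext(pmcid=pmcid, pmid=pmid, registry=registry,
                             instances=instances,
                             reconciliations=reconciliations)
    records = build_records(article, config)

    # Distinct citing sentences, independent of the contexts_only flag.
    n_contexts = 0
    for instance_seq, inst in enumerate(instances, start=1):
        sent_index = 0
        for af in inst.fragments:
            if af.fragment.fragment_kind == "table_cell":
                sent_has_cit = [bool(af.citations)] if af.text else []
            else:
                sents = tokenize(af.text, config.abbreviations)
                sent_has_cit = [bool(TOKEN_RE.search(s)) for s in sents]
            for has in sent_has_cit:
                sent_index += 1
                if has:
                    n_contexts += 1
    stats.n_citation_contexts = n_contexts

    for entry in registry:
        mentioned = entry.ref_id in cited_ids or any(
            m in cited_ids for m in entry.member_ids)
        if not mentioned:
            stats.n_refs_without_context += 1
    return records, stats


def _reconcile_all(pmcid: str, registry: ReferenceRegistry,
                   cited_ids: set[str], candidates: Optional[dict],
                   entrez: Optional[dict],
                   config: PipelineConfig) -> dict[str, ReconciliationResult]:
    entrez_cited = (entrez or {}).get(pmcid, set())
    results: dict[str, ReconciliationResult] = {}
    for intxt_id in cited_ids:
        xml_pmid = registry.pmid_for(intxt_id)
        cands: Optional[list[MatchCandidate]] = None
        if candidates is not None:
            key = (pmcid, intxt_id)
            cands = candidates.get(key)
        results[intxt_id] = reconcile(xml_pmid, cands, entrez_cited,
                                      config.thresholds)
    return results


def process_file(path: Union[str, os.PathLike],
                 config: Optional[PipelineConfig] = None,
                 candidates: Optional[dict] = None,
                 entrez: Optional[dict] = None,
                 ) -> tuple[list[SentenceRecord], ArticleStats]:
    root = parse_article(path)
    return process_article(root, config, candidates, entrez)


def run_batch(input_dir: Union[str, os.PathLike], output_path: str,
              config: Optional[PipelineConfig] = None,
              candidates: Optional[dict] = None,
              entrez: Optional[dict] = None) -> RunSummary:
    """Process every .xml file in a directory into one TSV.

    One file's failure never aborts the batch; failures are recorded in the
    summary. Files are processed in sorted name order so reruns are
    byte-identical.
    """
    config = config or PipelineConfig()
    if not os.path.isdir(input_dir):
        raise NotADirectoryError(f"input directory not found: {input_dir}")
    summary = RunSummary()
    all_records: list[SentenceRecord] = []
    files = sorted(f for f in os.listdir(input_dir) if f.endswith(".xml"))
    for name in files:
        path = os.path.join(input_dir, name)
        try:
            records, stats = process_file(path, config, candidates, entrez)
        except (ArticleParseError, OSError) as exc:
            logger.warning("failed to process %s: %s", name, exc)
            summary.failures.append((name, str(exc)))
            continue
        logger.info("processed %s: %d rows", name, len(records))
        all_records.extend(records)
        summary.add(stats)
    write_tsv(all_records, output_path, include_text=config.include_text)
    return summary
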