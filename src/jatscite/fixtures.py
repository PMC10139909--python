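"""Synthetic JATS article generator with ground-truth manifests.

Each generated article carries a manifest enumerating every output row the
pipeline should produce for it, built by construction rather than by
running the pipeline. Dialect knobs cover nested references, both implicit
citation tagging styles, every range-separator variant, plain-string
citation markers (missing xrefs), and untagged PMIDs. Identical config and
seed give byte-identical output.
"""
from __future__ import annotations

import json
import math
import os
import random
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

from .sentences import SentenceRecord, write_tsv

SEPARATORS: dict[str, str] = {
    "hyphen": "-",
    "en_dash": "–",
    "minus": "−",
    "double_hyphen": "--",
    "double_en_dash": "––",
    "double_minus": "−−",
}

IMPLICIT_STYLES = ("none", "paired_xref", "single_xref", "mixed")

_FILLERS = (
    "The assay was repeated three times under identical conditions.",
    "Samples were stored at low temperature before analysis.",
    "The observed signal remained stable across replicates.",
    "Each measurement was recorded by two independent observers.",
    "The cohort included adult participants from four clinics.",
    "Baseline characteristics were balanced between groups.",
    "The model converged after a small number of iterations.",
    "No adverse events were reported during the follow-up period.",
    "All samples passed the initial quality screen.",
    "The protocol was approved by the local committee.",
)

_CITING_TEMPLATES = (
    "Previous reports described a comparable pattern {}.",
    "This approach builds on earlier protocols {}.",
    "Similar effects were documented in other cohorts {}.",
    "The phenomenon has been examined extensively {}.",
    "These observations agree with published estimates {}.",
)

# (title, sec-type, expected IMRaD label)
_SECTION_POOL = (
    ("Introduction", "", "I"),
    ("Materials and Methods", "", "M"),
    ("Results", "", "R"),
    ("Discussion", "", "D"),
    ("Background", "", "I"),
    ("Concluding Remarks", "", "D"),
    ("Study Sites", "", "NoIMRaD"),
    ("", "results", "R"),
    ("Patient Outcomes", "", "NoIMRaD"),
)


@dataclass(frozen=True)
class DialectConfig:
    n_refs: int = 12
    nested_ref_rate: float = 0.0
    implicit_style: str = "mixed"  # none | paired_xref | single_xref | mixed
    separator: str = "random"      # SEPARATORS key, literal string, or "random"
    missing_xref_rate: float = 0.0
    untagged_pmid_rate: float = 0.0
    n_body_sections: int = 4
    include_tables: bool = True
    include_figures: bool = True
    include_back: bool = True
    seed: int = 0

    def __post_init__(self):
        for rate in (self.nested_ref_rate, self.missing_xref_rate,
                     self.untagged_pmid_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0,1]")
        if self.implicit_style not in IMPLICIT_STYLES:
            raise ValueError(f"unknown implicit_style {self.implicit_style!r}")
        if self.n_refs < 1 or self.n_body_sections < 1:
            raise ValueError("n_refs and n_body_sections must be positive")


@dataclass
class ExpectedReference:
    ref_id: str
    member_ids: list[str]
    label: str
    xml_pmid: Optional[str]
    order_index: int


@dataclass
class GroundTruthManifest:
    pmcid: str
    pmid: str
    records: list[SentenceRecord]
    references: list[ExpectedReference]
    has_inline_citation: dict[str, bool]
    n_explicit: int = 0
    n_implicit: int = 0


@dataclass
class _RefPlan:
    ref_id: str
    label: str
    nested: bool = False
    member_ids: list[str] = field(default_factory=list)
    pmid: Optional[str] = None          # tagged PMID (None when untagged/nested)
    display_pmid: Optional[str] = None  # appears in the raw string only
    member_pmids: dict[str, Optional[str]] = field(default_factory=dict)
    faulted: bool = False               # marker rendered without an xref


@dataclass
class _Group:
    kind: str  # plain | single | single_parent | single_member | list2 |
               # multirid | paired | range1
    indices: list[int]
    sep: str = "-"
    spaced: bool = False
    member_pick: int = 0


@dataclass
class _Cit:
    intxt_id: str
    mark: str
    implicit: bool
    pmid: Optional[str]


@dataclass
class _Sentence:
    xml: str
    text: str
    cits: list[_Cit] = field(default_factory=list)


def _pick_sep(config: DialectConfig, rng: random.Random) -> str:
    if config.separator == "random":
        return rng.choice(sorted(SEPARATORS.values()))
    return SEPARATORS.get(config.separator, config.separator)


def _plan_refs(config: DialectConfig, rng: random.Random) -> list[_RefPlan]:
    base = 10_000_000 + (abs(config.seed) % 880) * 100_000
    refs: list[_RefPlan] = []
    counter = 0
    for i in range(1, config.n_refs + 1):
        plan = _RefPlan(ref_id=f"B{i}", label=str(i))
        plan.nested = rng.random() < config.nested_ref_rate
        if plan.nested:
            for suffix in ("a", "b"):
                mid = f"B{i}{suffix}"
                plan.member_ids.append(mid)
                counter += 1
                if rng.random() < config.untagged_pmid_rate:
                    plan.member_pmids[mid] = None
                else:
                    plan.member_pmids[mid] = str(base + counter)
        else:
            counter += 1
            value = str(base + counter)
            if rng.random() < config.untagged_pmid_rate:
                plan.display_pmid = value
            else:
                plan.pmid = value
        plan.faulted = rng.random() < config.missing_xref_rate
        refs.append(plan)
    return refs


def _plan_groups(refs: list[_RefPlan], config: DialectConfig,
                 rng: random.Random) -> list[_Group]:
    groups: list[_Group] = []
    i, n = 0, len(refs)
    while i < n:
        ref = refs[i]
        if ref.faulted:
            groups.append(_Group("plain", [i]))
            i += 1
            continue
        if ref.nested:
            kind = rng.choice(("single_parent", "single_member"))
            groups.append(_Group(kind, [i], member_pick=rng.randrange(2)))
            i += 1
            continue
        run = 0
        while i + run < n and not refs[i + run].faulted and not refs[i + run].nested:
            run += 1
        choices = ["single", "single"]
        if run >= 2:
            choices += ["list2", "multirid"]
        if config.implicit_style in ("paired_xref", "mixed") and run >= 3:
            choices += ["paired", "paired"]
        if config.implicit_style in ("single_xref", "mixed") and run >= 2:
            choices += ["range1", "range1"]
        kind = rng.choice(choices)
        if kind == "single":
            size = 1
        elif kind in ("list2", "multirid"):
            size = 2
        elif kind == "paired":
            size = rng.randint(3, min(run, 5))
        else:
            size = rng.randint(2, min(run, 5))
        groups.append(_Group(kind, list(range(i, i + size)),
                             sep=_pick_sep(config, rng),
                             spaced=rng.random() < 0.25))
        i += size
    return groups


def _xref(rid: str, marker: str) -> str:
    return f'<xref ref-type="bibr" rid="{rid}">{marker}</xref>'


def _render_group(group: _Group, refs: list[_RefPlan]
                  ) -> tuple[str, str, list[_Cit]]:
    """(xml cluster, expected annotated cluster, expected citations)."""
    members = [refs[k] for k in group.indices]
    first = members[0]
    if group.kind == "plain":
        return f"[{first.label}]", f"[{first.label}]", []
    if group.kind == "single":
        mark = f"[{first.label}]"
        return (_xref(first.ref_id, mark), f"|{first.ref_id}|",
                [_Cit(first.ref_id, mark, False, first.pmid)])
    if group.kind == "single_parent":
        mark = f"[{first.label}]"
        return (_xref(first.ref_id, mark), f"|{first.ref_id}|",
                [_Cit(first.ref_id, mark, False, None)])
    if group.kind == "single_member":
        mid = first.member_ids[group.member_pick % len(first.member_ids)]
        mark = f"[{first.label}]"
        return (_xref(mid, mark), f"|{mid}|",
                [_Cit(mid, mark, False, first.member_pmids[mid])])
    if group.kind == "list2":
        a, b = members
        xml = f"{_xref(a.ref_id, f'[{a.label}]')}, {_xref(b.ref_id, f'[{b.label}]')}"
        text = f"|{a.ref_id}|, |{b.ref_id}|"
        return xml, text, [_Cit(a.ref_id, f"[{a.label}]", False, a.pmid),
                           _Cit(b.ref_id, f"[{b.label}]", False, b.pmid)]
    if group.kind == "multirid":
        a, b = members
        mark = f"[{a.label},{b.label}]"
        xml = f'<xref ref-type="bibr" rid="{a.ref_id} {b.ref_id}">{mark}</xref>'
        text = f"|{a.ref_id}|,|{b.ref_id}|"
        return xml, text, [_Cit(a.ref_id, mark, False, a.pmid),
                           _Cit(b.ref_id, mark, False, b.pmid)]
    if group.kind == "paired":
        a, b = members[0], members[-1]
        sep_render = f" {group.sep} " if group.spaced else group.sep
        mark = f"{a.label}{group.sep}{b.label}"
        xml = f"[{_xref(a.ref_id, a.label)}{sep_render}{_xref(b.ref_id, b.label)}]"
        interior = members[1:-1]
        text = (f"[|{a.ref_id}|{sep_render}|{b.ref_id}|"
                + "".join(f",|{m.ref_id}|" for m in interior) + "]")
        cits = [_Cit(a.ref_id, str(a.label), False, a.pmid),
                _Cit(b.ref_id, str(b.label), False, b.pmid)]
        cits += [_Cit(m.ref_id, mark, True, m.pmid) for m in interior]
        return xml, text, cits
    if group.kind == "range1":
        a, b = members[0], members[-1]
        mark = f"{a.label}{group.sep}{b.label}"
        xml = f"[{_xref(a.ref_id, mark)}]"
        rest = members[1:]
        text = (f"[|{a.ref_id}|" + "".join(f",|{m.ref_id}|" for m in rest) + "]")
        cits = [_Cit(a.ref_id, mark, False, a.pmid)]
        cits += [_Cit(m.ref_id, mark, True, m.pmid) for m in rest]
        return xml, text, cits
    raise ValueError(f"unknown group kind {group.kind!r}")


def _citing_sentence(group: _Group, refs: list[_RefPlan],
                     rng: random.Random) -> _Sentence:
    xml_cluster, text_cluster, cits = _render_group(group, refs)
    template = rng.choice(_CITING_TEMPLATES)
    return _Sentence(xml=template.format(xml_cluster),
                     text=template.format(text_cluster), cits=cits)


def _filler(rng: random.Random) -> _Sentence:
    s = rng.choice(_FILLERS)
    return _Sentence(xml=s, text=s)


def _ref_xml(ref: _RefPlan) -> str:
    def citation(pmid: Optional[str], display: Optional[str],
                 label: str, cid: Optional[str] = None) -> str:
        attr = f' id="{cid}"' if cid else ""
        tail = ""
        if pmid:
            tail = f'<pub-id pub-id-type="pmid">{pmid}</pub-id>'
        elif display:
            tail = f" PMID {display}."
        return (f"<mixed-citation{attr}>Author {label}. Study number {label}. "
                f"Synthetic Journal. 2019.{tail}</mixed-citation>")

    if ref.nested:
        inner = "".join(
            citation(ref.member_pmids[mid], None, f"{ref.label}{mid[-1]}", mid)
            for mid in ref.member_ids)
        return f'<ref id="{ref.ref_id}"><label>{ref.label}</label>{inner}</ref>'
    return (f'<ref id="{ref.ref_id}"><label>{ref.label}</label>'
            f"{citation(ref.pmid, ref.display_pmid, ref.label)}</ref>")


def generate_article(config: DialectConfig,
                     pmcid: Optional[str] = None
                     ) -> tuple[str, GroundTruthManifest]:
    """One synthetic article plus the manifest of its expected output."""
    rng = random.Random(config.seed)
    pmcid = pmcid or str(7_000_000 + config.seed % 999_983)
    citing_pmid = str(800_000 + config.seed % 99_991)

    refs = _plan_refs(config, rng)
    groups = _plan_groups(refs, config, rng)

    # Reserve one simple group each for a table cell and a figure caption.
    table_group: Optional[_Group] = None
    figure_group: Optional[_Group] = None
    body_groups: list[_Group] = []
    for group in groups:
        if config.include_tables and table_group is None and group.kind == "single":
            table_group = group
        elif config.include_figures and figure_group is None and group.kind == "single":
            figure_group = group
        else:
            body_groups.append(group)

    sections = [_SECTION_POOL[k % len(_SECTION_POOL)]
                for k in range(config.n_body_sections)]
    per_section: list[list[_Group]] = [[] for _ in sections]
    for k, group in enumerate(body_groups):
        per_section[k % len(sections)].append(group)

    # ---- plan fragments per component instance ----
    abstract_frags = [[_filler(rng), _filler(rng)], [_filler(rng)]]

    body_frags: list[tuple[str, list[_Sentence], str]] = []  # (kind, sents, imrad)
    section_xml_parts: list[str] = []
    for (title, sec_type, imrad), sec_groups in zip(sections, per_section):
        frags_here: list[tuple[str, list[_Sentence]]] = []
        pending = list(sec_groups)
        while pending:
            batch, pending = pending[:2], pending[2:]
            sents = [_filler(rng)]
            sents += [_citing_sentence(g, refs, rng) for g in batch]
            if rng.random() < 0.5:
                sents.append(_filler(rng))
            frags_here.append(("paragraph", sents))
        if not frags_here:
            frags_here.append(("paragraph", [_filler(rng), _filler(rng)]))
        if rng.random() < 0.3:
            frags_here.append(("quote", [_filler(rng)]))
        for kind, sents in frags_here:
            body_frags.append((kind, sents, imrad))
        inner = "".join(
            f"<{'p' if kind == 'paragraph' else 'disp-quote'}>"
            + " ".join(s.xml for s in sents)
            + f"</{'p' if kind == 'paragraph' else 'disp-quote'}>"
            for kind, sents in frags_here)
        attrs = f' sec-type="{sec_type}"' if sec_type else ""
        title_xml = f"<title>{title}</title>" if title else ""
        section_xml_parts.append(f"<sec{attrs}>{title_xml}{inner}</sec>")

    last_imrad = sections[-1][2]

    # Decoy cross-reference to a figure: must survive as plain text.
    decoy = None
    if config.include_figures:
        decoy = _Sentence(
            xml=('The workflow is shown in the supplementary material '
                 '(see <xref ref-type="fig" rid="F1">Figure 1</xref>).'),
            text=('The workflow is shown in the supplementary material '
                  '(see Figure 1).'))
        body_frags.append(("paragraph", [decoy], last_imrad))
        section_xml_parts[-1] = section_xml_parts[-1][:-len("</sec>")] \
            + f"<p>{decoy.xml}</p></sec>"

    table_plan = None
    if config.include_tables:
        caption = _filler(rng)
        cell_sents = [_Sentence(xml="Measure", text="Measure"),
                      _Sentence(xml="Value", text="Value")]
        if table_group is not None:
            xml_cluster, text_cluster, cits = _render_group(table_group, refs)
            cell_sents.append(_Sentence(xml=f"Effect size {xml_cluster}",
                                        text=f"Effect size {text_cluster}",
                                        cits=cits))
        else:
            cell_sents.append(_Sentence(xml="Effect size", text="Effect size"))
        cell_sents.append(_Sentence(xml="Twelve", text="Twelve"))
        table_plan = (caption, cell_sents)
        table_xml = (
            '<table-wrap id="T1"><label>Table 1</label>'
            f"<caption><p>{caption.xml}</p></caption>"
            "<table><thead><tr>"
            f"<th>{cell_sents[0].xml}</th><th>{cell_sents[1].xml}</th>"
            "</tr></thead><tbody><tr>"
            f"<td>{cell_sents[2].xml}</td><td>{cell_sents[3].xml}</td>"
            "</tr></tbody></table></table-wrap>")
        section_xml_parts[-1] = section_xml_parts[-1][:-len("</sec>")] \
            + table_xml + "</sec>"

    figure_plan = None
    if config.include_figures:
        if figure_group is not None:
            xml_cluster, text_cluster, cits = _render_group(figure_group, refs)
            template = rng.choice(_CITING_TEMPLATES)
            cap = _Sentence(xml=template.format(xml_cluster),
                            text=template.format(text_cluster), cits=cits)
        else:
            cap = _filler(rng)
        figure_plan = cap
        fig_xml = (f'<fig id="F1"><label>Figure 1</label>'
                   f"<caption><p>{cap.xml}</p></caption></fig>")
        section_xml_parts[-1] = section_xml_parts[-1][:-len("</sec>")] \
            + fig_xml + "</sec>"

    back_sent = _filler(rng) if config.include_back else None

    # ---- assemble XML ----
    abstract_xml = "".join(
        "<p>" + " ".join(s.xml for s in frag) + "</p>" for frag in abstract_frags)
    refs_xml = "".join(_ref_xml(r) for r in refs)
    back_inner = f"<ack><p>{back_sent.xml}</p></ack>" if back_sent else ""
    xml_text = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        '<article article-type="research-article">'
        "<front><journal-meta><journal-title-group>"
        "<journal-title>Synthetic Journal of Testing</journal-title>"
        "</journal-title-group></journal-meta>"
        "<article-meta>"
        f'<article-id pub-id-type="pmc">{pmcid}</article-id>'
        f'<article-id pub-id-type="pmid">{citing_pmid}</article-id>'
        "<title-group><article-title>A synthetic study of generated "
        "citations</article-title></title-group>"
        f"<abstract>{abstract_xml}</abstract>"
        "</article-meta></front>"
        "<body>" + "".join(section_xml_parts) + "</body>"
        f"<back>{back_inner}<ref-list>{refs_xml}</ref-list></back>"
        "</article>")

    # ---- build expected records ----
    manifest = _build_manifest(config, pmcid, citing_pmid, refs, groups,
                               abstract_frags, body_frags, table_plan,
                               figure_plan, back_sent, last_imrad)
    return xml_text, manifest


def _build_manifest(config, pmcid, citing_pmid, refs, groups, abstract_frags,
                    body_frags, table_plan, figure_plan, back_sent,
                    last_imrad) -> GroundTruthManifest:
    records: list[SentenceRecord] = []

    def emit_instance(location: str, sentences: list[tuple[_Sentence, str]]):
        total = len(sentences)
        for idx, (sent, imrad) in enumerate(sentences, start=1):
            progression = math.ceil(100 * idx / total)
            base = dict(pmcid=pmcid, pmid=citing_pmid, location=location,
                        imrad=imrad, sentence_id=idx, total_sentences=total,
                        progression=progression, text=sent.text)
            if not sent.cits:
                records.append(SentenceRecord(**base))
                continue
            for cit in sent.cits:
                rec = SentenceRecord(**base)
                rec.intxt_id = cit.intxt_id
                rec.intxt_mark = cit.mark
                if cit.pmid:
                    rec.intxt_pmid = cit.pmid
                    rec.intxt_pmid_source = "xml"
                    rec.best_id = cit.pmid
                    rec.best_source = "xml"
                    rec.best_id_diff = "PMID_XML"
                else:
                    rec.best_id_diff = "NONE_XML"
                records.append(rec)

    emit_instance("abstract",
                  [(s, "NoIMRaD") for frag in abstract_frags for s in frag])
    emit_instance("body",
                  [(s, imrad) for kind, sents, imrad in body_frags for s in sents])
    if table_plan is not None:
        caption, cells = table_plan
        emit_instance("table", [(caption, last_imrad)]
                      + [(c, last_imrad) for c in cells])
    if figure_plan is not None:
        emit_instance("fig", [(figure_plan, last_imrad)])
    if back_sent is not None:
        emit_instance("back", [(back_sent, "NoIMRaD")])

    references = [
        ExpectedReference(ref_id=r.ref_id, member_ids=list(r.member_ids),
                          label=r.label, xml_pmid=r.pmid,
                          order_index=i + 1)
        for i, r in enumerate(refs)]
    has_citation = {r.ref_id: False for r in refs}
    n_explicit = n_implicit = 0
    for rec in records:
        if rec.intxt_id:
            # Member ids ("B5a") roll up to their parent reference ("B5").
            rid = rec.intxt_id if rec.intxt_id in has_citation else rec.intxt_id[:-1]
            has_citation[rid] = True
    for group in groups:
        for cit in _render_group(group, refs)[2]:
            if cit.implicit:
                n_implicit += 1
            else:
                n_explicit += 1
    return GroundTruthManifest(
        pmcid=pmcid, pmid=citing_pmid, records=records, references=references,
        has_inline_citation=has_citation, n_explicit=n_explicit,
        n_implicit=n_implicit)


def default_grid() -> list[DialectConfig]:
    """Dialect grid spanning implicit styles, separators, and nesting."""
    grid = []
    for style in IMPLICIT_STYLES:
        for sep in ("hyphen", "en_dash", "minus", "double_hyphen"):
            for nested in (0.0, 0.3):
                grid.append(DialectConfig(implicit_style=style, separator=sep,
                                          nested_ref_rate=nested))
    return grid


def generate_corpus(n_articles: int,
                    config_grid: Optional[list[DialectConfig]] = None,
                    seed: int = 0) -> list[tuple[str, GroundTruthManifest]]:
    """Deterministic corpus cycling through the dialect grid."""
    grid = config_grid or default_grid()
    corpus = []
    for k in range(n_articles):
        cfg = replace(grid[k % len(grid)], seed=seed * 100_003 + k)
        pmcid = str(7_000_000 + k)
        corpus.append(generate_article(cfg, pmcid=pmcid))
    return corpus


def write_corpus(outdir: str, n_articles: int,
                 config_grid: Optional[list[DialectConfig]] = None,
                 seed: int = 0) -> list[str]:
    """Write xml files, a combined manifest TSV, and a config sidecar."""
    os.makedirs(outdir, exist_ok=True)
    grid = config_grid or default_grid()
    corpus = generate_corpus(n_articles, grid, seed)
    paths = []
    all_records: list[SentenceRecord] = []
    for k, (xml_text, manifest) in enumerate(corpus):
        path = os.path.join(outdir, f"article_{k:04d}.xml")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(xml_text)
        paths.append(path)
        all_records.extend(manifest.records)
    write_tsv(all_records, os.path.join(outdir, "manifest.tsv"))
    with open(os.path.join(outdir, "corpus_config.json"), "w",
              encoding="utf-8") as fh:
        json.dump({"n_articles": n_articles, "seed": seed,
                   "grid": [asdict(c) for c in grid]}, fh, indent=2)
    return paths
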