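"""Reconciliation of XML-tagged PMIDs with external candidate-ID tables.

Two optional inputs drive this module: a per-reference candidate table (as
produced by a citation matcher: candidate id, id space, match probability,
confirming sources) and a per-article cited-PMID list (Entrez-style). With
neither input the output degenerates to the XML-tagged values, labelled
PMID_XML / NONE_XML.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Optional

from .config import DEFAULT_THRESHOLDS

logger = logging.getLogger(__name__)

DIFF_LABELS = ("SAME", "NONE", "INSERT", "SWAP", "DELETE", "PMID_XML", "NONE_XML")


@dataclass(frozen=True)
class MatchCandidate:
    pmcid: str
    ref_id: str
    candidate_id: str
    id_space: str  # "pmid" | "non_pmid"
    probability: float
    confirmations: tuple[str, ...] = ()

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0,1]")
        if not self.candidate_id:
            raise ValueError("empty candidate_id")


@dataclass
class ReconciliationResult:
    best_id: Optional[str] = None
    best_source: str = ""
    best_id_diff: str = "NONE_XML"
    intxt_pmid_source: str = ""
    intxt_pmid: Optional[str] = None


def pmid_source(xml_pmid: Optional[str], entrez_cited: set[str]) -> str:
    """Provenance label of an XML-tagged PMID.

    Empty when there is no XML-tagged PMID; ``xml,pmc`` when the Entrez
    cited-PMID list of the citing article confirms it; ``xml`` otherwise.
    """
    if not xml_pmid:
        return ""
    return "xml,pmc" if xml_pmid in entrez_cited else "xml"


def select_best(candidates: list[MatchCandidate],
                thresholds: Optional[dict] = None,
                xml_pmid: Optional[str] = None
                ) -> Optional[tuple[str, str]]:
    """Pick the best candidate id, or None when no candidate is eligible.

    Eligibility thresholds: ``default`` for an unconfirmed PMID,
    ``confirmed_pmid`` for a PMID confirmed by at least one source, and
    ``non_pmid`` for other id spaces. Among eligible candidates the PMID is
    preferred unless a non-PMID's probability exceeds the best PMID's by at
    least ``preference_margin``. The returned source string joins an
    ``xml`` token (when the choice equals the XML-tagged PMID) with the
    candidate's confirmation tokens; a choice confirmed by nothing carries
    the token ``matcher``.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    best_pmid: Optional[MatchCandidate] = None
    best_non: Optional[MatchCandidate] = None
    for cand in candidates:
        if cand.id_space == "pmid":
            bar = th["confirmed_pmid"] if cand.confirmations else th["default"]
            if cand.probability >= bar and (
                    best_pmid is None or cand.probability > best_pmid.probability):
                best_pmid = cand
        else:
            if cand.probability >= th["non_pmid"] and (
                    best_non is None or cand.probability > best_non.probability):
                best_non = cand
    chosen = None
    if best_pmid is not None and best_non is not None:
        if best_non.probability >= best_pmid.probability + th["preference_margin"]:
            chosen = best_non
        else:
            chosen = best_pmid
    else:
        chosen = best_pmid or best_non
    if chosen is None:
        return None
    tokens: list[str] = []
    if xml_pmid and chosen.candidate_id == xml_pmid:
        tokens.append("xml")
    for t in chosen.confirmations:
        if t and t not in tokens:
            tokens.append(t)
    if not tokens:
        tokens.append("matcher")
    return chosen.candidate_id, ",".join(tokens)


def classify_diff(best_id: Optional[str], xml_pmid: Optional[str],
                  crosschecked: bool) -> str:
    """Categorical comparison between the selected id and the XML-tagged PMID."""
    if crosschecked:
        if best_id and xml_pmid:
            return "SAME" if best_id == xml_pmid else "SWAP"
        if best_id:
            return "INSERT"
        if xml_pmid:
            return "DELETE"
        return "NONE"
    return "PMID_XML" if xml_pmid else "NONE_XML"


def reconcile(xml_pmid: Optional[str],
              candidates: Optional[list[MatchCandidate]],
              entrez_cited: set[str],
              thresholds: Optional[dict] = None) -> ReconciliationResult:
    """Full per-reference reconciliation.

    ``candidates=None`` means the reference was never cross-checked with
    the matcher (PMID_XML / NONE_XML outcomes); an empty list means it was
    cross-checked but nothing was found.
    """
    source = pmid_source(xml_pmid, entrez_cited)
    if candidates is None:
        if xml_pmid:
            return ReconciliationResult(
                best_id=xml_pmid, best_source="xml", best_id_diff="PMID_XML",
                intxt_pmid_source=source, intxt_pmid=xml_pmid)
        return ReconciliationResult(
            best_id=None, best_source="", best_id_diff="NONE_XML",
            intxt_pmid_source=source, intxt_pmid=None)
    selected = select_best(candidates, thresholds, xml_pmid=xml_pmid)
    best_id, best_source = selected if selected else (None, "")
    diff = classify_diff(best_id, xml_pmid, crosschecked=True)
    return ReconciliationResult(
        best_id=best_id, best_source=best_source, best_id_diff=diff,
        intxt_pmid_source=source, intxt_pmid=xml_pmid)


def load_candidates(path: str) -> dict[tuple[str, str], list[MatchCandidate]]:
    """Candidate table TSV: pmcid, ref_id, candidate_id, id_space,
    probability, confirmations (semicolon-joined)."""
    table: dict[tuple[str, str], list[MatchCandidate]] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            confirmations = tuple(
                t for t in (row.get("confirmations") or "").split(";") if t)
            cand = MatchCandidate(
                pmcid=row["pmcid"], ref_id=row["ref_id"],
                candidate_id=row["candidate_id"],
                id_space=row.get("id_space") or "pmid",
                probability=float(row["probability"]),
                confirmations=confirmations,
            )
            table.setdefault((cand.pmcid, cand.ref_id), []).append(cand)
    return table


def load_entrez(path: str) -> dict[str, set[str]]:
    """Cited-PMID list TSV: pmcid, cited_pmid."""
    cited: dict[str, set[str]] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            cited.setdefault(row["pmcid"], set()).add(row["cited_pmid"])
    return cited
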