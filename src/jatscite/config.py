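"""Pipeline configuration: rule tables, thresholds, and serialization options.

All knobs are plain data so they can be overridden from a YAML file. The
defaults reproduce the behaviour of the reference pipeline: the IMRaD cue
table, the component location labels, and the ID-selection thresholds.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import yaml

# Ordered cue-rule table: first matching group wins (evaluated I, M, R, D).
# A trailing "*" means "word starting with this prefix"; anything else is a
# plain substring match on the normalized section string.
DEFAULT_IMRAD_RULES: list[tuple[str, list[str]]] = [
    ("I", ["intro*", "overview", "background", "history", "related work",
           "related stud*", "previous work", "previous stud*", "review"]),
    ("M", ["method", "material", "experimental procedure", "protocol", "data"]),
    ("R", ["result", "finding"]),
    ("D", ["conclud*", "conclusion", "summary", "discuss*", "future"]),
]

# Component kind -> string emitted in the "location" column.
DEFAULT_LOCATION_LABELS: dict[str, str] = {
    "abstract": "abstract",
    "body": "body",
    "table": "table",
    "figure": "fig",
    "back": "back",
}

# Thresholds driving best-ID selection from a candidate table.
DEFAULT_THRESHOLDS: dict[str, float] = {
    # minimum match probability for an unconfirmed PMID candidate
    "default": 0.997,
    # lower bar for a PMID confirmed by at least one public source
    "confirmed_pmid": 0.99,
    # lower bar for non-PMID identifiers (e.g. DBLP, ADS)
    "non_pmid": 0.99,
    # a non-PMID wins over a PMID only when its probability exceeds the
    # PMID's by at least this margin
    "preference_margin": 0.005,
}

# Lower-cased tokens that suppress a sentence split when they precede a
# period. Dotted forms (e.g.) are matched including their internal dots.
DEFAULT_ABBREVIATIONS: frozenset[str] = frozenset({
    "fig", "figs", "eq", "eqs", "ref", "refs", "tab", "tabs",
    "al", "e.g", "i.e", "etc", "vs", "cf", "ca", "approx",
    "dr", "mr", "mrs", "ms", "prof", "st", "no", "vol", "pp",
    "ed", "eds", "inc", "ltd",
})


@dataclass(frozen=True)
class PipelineConfig:
    """Aggregate of every configurable behaviour of the pipeline."""

    imrad_rules: tuple = tuple((lbl, tuple(cues)) for lbl, cues in DEFAULT_IMRAD_RULES)
    location_labels: dict = field(default_factory=lambda: dict(DEFAULT_LOCATION_LABELS))
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    abbreviations: frozenset = DEFAULT_ABBREVIATIONS
    include_text: bool = True
    contexts_only: bool = False
    progression_mode: str = "component"  # "component" | "maintext"

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def load_config(path: Optional[str] = None, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from an optional YAML file plus keyword overrides.

    Recognized YAML keys: ``imrad_rules`` (mapping or list of [label, cues]),
    ``location_labels``, ``thresholds``, ``abbreviations``,
    ``progression_mode``, ``include_text``, ``contexts_only``.
    """
    cfg = PipelineConfig()
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path!r} must contain a mapping")
        kwargs = {}
        if "imrad_rules" in data:
            raw = data["imrad_rules"]
            if isinstance(raw, dict):
                items = raw.items()
            else:
                items = [(lbl, cues) for lbl, cues in raw]
            kwargs["imrad_rules"] = tuple((lbl, tuple(cues)) for lbl, cues in items)
        if "location_labels" in data:
            labels = dict(DEFAULT_LOCATION_LABELS)
            labels.update(data["location_labels"])
            kwargs["location_labels"] = labels
        if "thresholds" in data:
            th = dict(DEFAULT_THRESHOLDS)
            th.update(data["thresholds"])
            kwargs["thresholds"] = th
        if "abbreviations" in data:
            kwargs["abbreviations"] = frozenset(
                str(a).lower() for a in data["abbreviations"])
        for key in ("progression_mode", "include_text", "contexts_only"):
            if key in data:
                kwargs[key] = data[key]
        cfg = cfg.with_overrides(**kwargs)
    if overrides:
        cfg = cfg.with_overrides(**overrides)
    if cfg.progression_mode not in ("component", "maintext"):
        raise ValueError(f"unknown progression_mode {cfg.progression_mode!r}")
    return cfg
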