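"""Rule-based mapping of section strings to IMRaD categories.

A section string (title + label + sec-type) is matched against an ordered
cue table. Cues ending in ``*`` match any word starting with the prefix;
all other cues are substring matches on the normalized string. Groups are
evaluated in table order and the first match wins, so a string containing
cues from several groups resolves deterministically.
"""
from __future__ import annotations

import re
from functools import lru_cache

from .components import ComponentKind, TextFragment
from .config import DEFAULT_IMRAD_RULES

NO_IMRAD = "NoIMRaD"
IMRAD_LABELS = ("I", "M", "R", "D", NO_IMRAD)

RuleSet = tuple[tuple[str, tuple[str, ...]], ...]

DEFAULT_RULES: RuleSet = tuple(
    (label, tuple(cues)) for label, cues in DEFAULT_IMRAD_RULES)


def _normalize(s: str) -> str:
    return " ".join(s.lower().split())


@lru_cache(maxsize=32)
def _compile(rules: RuleSet):
    compiled = []
    for label, cues in rules:
        matchers = []
        for cue in cues:
            cue_norm = _normalize(cue.rstrip("*"))
            if cue.endswith("*"):
                words = [re.escape(w) for w in cue_norm.split()]
                pattern = re.compile(r"\b" + r"\s+".join(words) + r"\w*")
                matchers.append(pattern.search)
            else:
                matchers.append(lambda s, c=cue_norm: c in s)
        compiled.append((label, matchers))
    return compiled


def map_imrad(section_string: str, rules: RuleSet = DEFAULT_RULES) -> str:
    """IMRaD label for a section string; NoIMRaD when no cue matches."""
    s = _normalize(section_string)
    if not s:
        return NO_IMRAD
    for label, matchers in _compile(rules):
        for match in matchers:
            if match(s):
                return label
    return NO_IMRAD


def label_fragment(fragment: TextFragment, rules: RuleSet = DEFAULT_RULES) -> str:
    """IMRaD label of a fragment.

    Abstract and back-matter fragments are NoIMRaD unconditionally. For the
    rest, the section path is evaluated innermost-first and the first
    non-NoIMRaD result wins, so subsection titles override their parents.
    """
    if fragment.component in (ComponentKind.ABSTRACT, ComponentKind.BACK):
        return NO_IMRAD
    for ctx in reversed(fragment.section_path):
        label = map_imrad(ctx.as_string(), rules)
        if label != NO_IMRAD:
            return label
    return NO_IMRAD
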