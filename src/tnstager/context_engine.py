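"""Concept mention finding and assertion assignment (affirmed/negated/uncertain).

A ConText/NegEx-style trigger-scope pass: each non-pseudo trigger opens a
scope running from the trigger to the sentence boundary in its direction,
truncated at the first termination trigger or the next non-pseudo trigger.
Mentions inside a negation scope are negated; inside an uncertainty scope
(and not negated) uncertain.  Negation takes precedence over uncertainty.
Scopes never cross sentence boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

from .lexicon import Lexicon
from .preprocess import Sentence

__all__ = ["ConceptMention", "find_mentions", "assign_modifiers"]

AFFIRMED = "affirmed"
NEGATED = "negated"
UNCERTAIN = "uncertain"

# categories that never yield mentions (consumed elsewhere in the pipeline)
_SKIP_CATEGORIES = {"section_header", "modality_cue"}


@dataclass(frozen=True)
class ConceptMention:
    concept_id: str
    category: str
    span: tuple[int, int]  # global offsets into the report text
    sentence_index: int
    text: str
    assertion: str = AFFIRMED
    attributes: dict[str, Any] = field(default_factory=dict)


def find_mentions(sentence: Sentence, lexicon: Lexicon) -> list[ConceptMention]:
    """Match lexicon concepts in one sentence (assertion=affirmed initially).

    Matching is leftmost-longest per concept; overlapping matches of the
    same category are resolved to the longer match (ties: the earlier one).
    """
    raw: list[ConceptMention] = []
    base = sentence.span[0]
    for entry in lexicon.concepts:
        if entry.category in _SKIP_CATEGORIES:
            continue
        spans: list[tuple[int, int]] = []
        for rx in entry.compiled:
            for m in rx.finditer(sentence.text):
                spans.append((m.start(), m.end()))
        for start, end in _leftmost_longest(spans):
            raw.append(
                ConceptMention(
                    concept_id=entry.concept_id,
                    category=entry.category,
                    span=(base + start, base + end),
                    sentence_index=sentence.index,
                    text=sentence.text[start:end],
                    attributes=dict(entry.attributes),
                )
            )
    return _resolve_category_overlaps(raw)


def _leftmost_longest(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Greedy leftmost-longest selection of non-overlapping spans."""
    chosen: list[tuple[int, int]] = []
    for s in sorted(spans, key=lambda x: (x[0], -(x[1] - x[0]))):
        if not any(s[0] < c[1] and c[0] < s[1] for c in chosen):
            chosen.append(s)
    return chosen


def _resolve_category_overlaps(mentions: list[ConceptMention]) -> list[ConceptMention]:
    out: list[ConceptMention] = []
    ordered = sorted(
        mentions, key=lambda m: (m.span[0], -(m.span[1] - m.span[0]), m.concept_id)
    )
    for m in ordered:
        clash = False
        for kept in out:
            if kept.category != m.category:
                continue
            if m.span[0] < kept.span[1] and kept.span[0] < m.span[1]:
                clash = True  # kept is longer-or-equal by sort order
                break
        if not clash:
            out.append(m)
    return out


@dataclass(frozen=True)
class _Trigger:
    modifier_class: str
    direction: str
    span: tuple[int, int]  # sentence-local


def _find_triggers(text: str, lexicon: Lexicon) -> list[_Trigger]:
    raw: list[_Trigger] = []
    for entry in lexicon.modifiers:
        for rx in entry.compiled:
            for m in rx.finditer(text):
                raw.append(_Trigger(entry.modifier_class, entry.direction, (m.start(), m.end())))
    # pseudo triggers are matched first and suppress any overlapping
    # non-pseudo trigger (e.g. "not excluded" swallows the bare "not")
    pseudo = [t for t in raw if t.modifier_class == "pseudo"]
    kept = [
        t
        for t in raw
        if t.modifier_class == "pseudo"
        or not any(t.span[0] < p.span[1] and p.span[0] < t.span[1] for p in pseudo)
    ]
    # longer trigger wins among overlapping same-class matches ("no evidence
    # of" over "no"); keep deterministic order
    result: list[_Trigger] = []
    for t in sorted(kept, key=lambda t: (t.span[0], -(t.span[1] - t.span[0]))):
        if any(
            t.modifier_class == k.modifier_class
            and t.span[0] < k.span[1]
            and k.span[0] < t.span[1]
            for k in result
        ):
            continue
        result.append(t)
    return result


def assign_modifiers(
    sentence: Sentence, mentions: list[ConceptMention], lexicon: Lexicon
) -> list[ConceptMention]:
    """Apply trigger scopes to mentions and return them with final assertions."""
    text = sentence.text
    triggers = _find_triggers(text, lexicon)
    active = [
        t for t in triggers if t.modifier_class in ("negation", "uncertainty")
    ]
    terminations = [t for t in triggers if t.modifier_class == "termination"]

    scopes: list[tuple[str, int, int]] = []  # (class, start, end) sentence-local
    for t in active:
        directions = (
            ("forward", "backward") if t.direction == "bidirectional" else (t.direction,)
        )
        for direction in directions:
            if direction == "forward":
                lo, hi = t.span[1], len(text)
                for other in terminations:
                    if other.span[0] >= t.span[1]:
                        hi = min(hi, other.span[0])
                for other in active:
                    if other is not t and other.span[0] >= t.span[1]:
                        hi = min(hi, other.span[0])
            else:
                lo, hi = 0, t.span[0]
                for other in terminations:
                    if other.span[1] <= t.span[0]:
                        lo = max(lo, other.span[1])
                for other in active:
                    if other is not t and other.span[1] <= t.span[0]:
                        lo = max(lo, other.span[1])
            if lo < hi:
                scopes.append((t.modifier_class, lo, hi))

    base = sentence.span[0]
    out: list[ConceptMention] = []
    for m in mentions:
        local_start = m.span[0] - base
        assertion = AFFIRMED
        in_neg = any(c == "negation" and lo <= local_start < hi for c, lo, hi in scopes)
        in_unc = any(
            c == "uncertainty" and lo <= local_start < hi for c, lo, hi in scopes
        )
        if in_neg:
            assertion = NEGATED
        elif in_unc:
            assertion = UNCERTAIN
        out.append(replace(m, assertion=assertion))
    return out
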