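"""Configurable vocabulary of concepts and context modifiers.

Every matching step in the pipeline (section headers, tumor/node concepts,
stations, avidity cues, negation/uncertainty triggers, measurement blacklist)
is driven by a :class:`Lexicon` loaded from YAML, so the whole vocabulary can
be swapped (e.g. for another language or institution) without code changes.

Patterns are case-insensitive regexes; the loader wraps each in word
boundaries ``\\b(?:...)\\b`` before compiling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable

import yaml

__all__ = [
    "ConceptEntry",
    "ModifierEntry",
    "Lexicon",
    "LexiconError",
    "Violation",
    "load_lexicon",
    "save_lexicon",
    "validate_lexicon",
    "default_lexicon_path",
]

CONCEPT_CATEGORIES = frozenset(
    {
        "tumor",
        "lymph_node",
        "station",
        "invasion_target",
        "satellite_nodule",
        "multilobe_cue",
        "avidity_pos",
        "avidity_neg",
        "laterality",
        "lobe",
        "blacklist_anatomy",
        "section_header",
        "modality_cue",
    }
)
MODIFIER_CLASSES = frozenset({"negation", "uncertainty", "pseudo", "termination"})
DIRECTIONS = frozenset({"forward", "backward", "bidirectional"})
T_FEATURE_CLASSES = frozenset({"T2", "T3", "T4"})


class LexiconError(ValueError):
    """Raised when a lexicon file violates the schema."""


def _compile(pattern: str) -> re.Pattern:
    try:
        return re.compile(r"\b(?:%s)\b" % pattern, re.IGNORECASE)
    except re.error as exc:  # pragma: no cover - exercised via validation
        raise LexiconError(f"pattern does not compile: {pattern!r} ({exc})") from exc


@dataclass(frozen=True)
class ConceptEntry:
    concept_id: str
    category: str
    patterns: tuple[str, ...]
    attributes: dict[str, Any] = field(default_factory=dict)
    compiled: tuple[re.Pattern, ...] = field(
        default=(), compare=False, repr=False
    )

    @staticmethod
    def make(concept_id: str, category: str, patterns: Iterable[str], attributes=None):
        pats = tuple(patterns)
        return ConceptEntry(
            concept_id=concept_id,
            category=category,
            patterns=pats,
            attributes=dict(attributes or {}),
            compiled=tuple(_compile(p) for p in pats),
        )


@dataclass(frozen=True)
class ModifierEntry:
    modifier_id: str
    modifier_class: str
    direction: str
    patterns: tuple[str, ...]
    compiled: tuple[re.Pattern, ...] = field(default=(), compare=False, repr=False)

    @staticmethod
    def make(modifier_id: str, modifier_class: str, direction: str, patterns):
        pats = tuple(patterns)
        return ModifierEntry(
            modifier_id=modifier_id,
            modifier_class=modifier_class,
            direction=direction,
            patterns=pats,
            compiled=tuple(_compile(p) for p in pats),
        )


@dataclass(frozen=True)
class Lexicon:
    concepts: tuple[ConceptEntry, ...]
    modifiers: tuple[ModifierEntry, ...]
    version: str = "0"
    abbreviations: tuple[str, ...] = ()

    def by_category(self, *categories: str) -> list[ConceptEntry]:
        want = set(categories)
        return [c for c in self.concepts if c.category in want]

    def modifier_by_class(self, *classes: str) -> list[ModifierEntry]:
        want = set(classes)
        return [m for m in self.modifiers if m.modifier_class in want]


@dataclass(frozen=True)
class Violation:
    severity: str  # "error" | "warning"
    message: str


def default_lexicon_path() -> Path:
    return Path(resources.files("tnstager") / "data" / "default_lexicon.yaml")


def load_lexicon(path: str | Path | None = None) -> Lexicon:
    """Load and validate a lexicon; with ``path=None`` the built-in default.

    Raises :class:`LexiconError` naming the offending entry on any
    error-severity violation (schema, regex compilation, missing categories).
    """
    if path is None:
        path = default_lexicon_path()
    path = Path(path)
    if not path.exists():
        raise LexiconError(f"lexicon file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise LexiconError(f"lexicon file {path} is not a YAML mapping")
    lexicon = _from_mapping(raw)
    errors = [v for v in validate_lexicon(lexicon) if v.severity == "error"]
    if errors:
        raise LexiconError("; ".join(v.message for v in errors))
    return lexicon


def _from_mapping(raw: dict) -> Lexicon:
    concepts = []
    for i, entry in enumerate(raw.get("concepts", []) or []):
        try:
            concepts.append(
                ConceptEntry.make(
                    concept_id=str(entry["id"]),
                    category=str(entry["category"]),
                    patterns=[str(p) for p in entry.get("patterns", [])],
                    attributes=entry.get("attributes") or {},
                )
            )
        except KeyError as exc:
            raise LexiconError(f"concept #{i} is missing key {exc}") from exc
    modifiers = []
    for i, entry in enumerate(raw.get("modifiers", []) or []):
        try:
            modifiers.append(
                ModifierEntry.make(
                    modifier_id=str(entry["id"]),
                    modifier_class=str(entry["modifier_class"]),
                    direction=str(entry.get("direction", "forward")),
                    patterns=[str(p) for p in entry.get("patterns", [])],
                )
            )
        except KeyError as exc:
            raise LexiconError(f"modifier #{i} is missing key {exc}") from exc
    return Lexicon(
        concepts=tuple(concepts),
        modifiers=tuple(modifiers),
        version=str(raw.get("version", "0")),
        abbreviations=tuple(str(a).lower() for a in raw.get("abbreviations", []) or []),
    )


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Write a lexicon back to YAML such that load(save(x)) == x."""
    data = {
        "version": lexicon.version,
        "abbreviations": list(lexicon.abbreviations),
        "concepts": [
            {
                "id": c.concept_id,
                "category": c.category,
                "patterns": list(c.patterns),
                "attributes": dict(c.attributes),
            }
            for c in lexicon.concepts
        ],
        "modifiers": [
            {
                "id": m.modifier_id,
                "modifier_class": m.modifier_class,
                "direction": m.direction,
                "patterns": list(m.patterns),
            }
            for m in lexicon.modifiers
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False, allow_unicode=True)


def validate_lexicon(lexicon: Lexicon) -> list[Violation]:
    """Check a lexicon candidate; returns violations (empty => valid).

    Error severity: duplicate ids, unknown categories/classes, non-compiling
    patterns, out-of-range station numbers, missing required categories.
    Warning severity: incomplete station coverage of 1..14.
    """
    out: list[Violation] = []
    seen: set[str] = set()
    for c in lexicon.concepts:
        if c.concept_id in seen:
            out.append(Violation("error", f"duplicate concept_id {c.concept_id!r}"))
        seen.add(c.concept_id)
        if c.category not in CONCEPT_CATEGORIES:
            out.append(
                Violation("error", f"{c.concept_id}: unknown category {c.category!r}")
            )
        if not c.patterns:
            out.append(Violation("error", f"{c.concept_id}: no patterns"))
        for p in c.patterns:
            try:
                _compile(p)
            except LexiconError:
                out.append(
                    Violation("error", f"{c.concept_id}: pattern does not compile: {p!r}")
                )
        if c.category == "station":
            num = c.attributes.get("station_number")
            if not isinstance(num, int) or not 1 <= num <= 14:
                out.append(
                    Violation(
                        "error",
                        f"{c.concept_id}: station_number must be an int in [1, 14], got {num!r}",
                    )
                )
        if c.category == "invasion_target":
            cls = c.attributes.get("t_feature_class")
            if cls not in T_FEATURE_CLASSES:
                out.append(
                    Violation(
                        "error",
                        f"{c.concept_id}: t_feature_class must be one of {sorted(T_FEATURE_CLASSES)}, got {cls!r}",
                    )
                )
    mod_seen: set[str] = set()
    for m in lexicon.modifiers:
        if m.modifier_id in mod_seen:
            out.append(Violation("error", f"duplicate modifier id {m.modifier_id!r}"))
        mod_seen.add(m.modifier_id)
        if m.modifier_class not in MODIFIER_CLASSES:
            out.append(
                Violation(
                    "error", f"{m.modifier_id}: unknown modifier_class {m.modifier_class!r}"
                )
            )
        if m.direction not in DIRECTIONS:
            out.append(
                Violation("error", f"{m.modifier_id}: unknown direction {m.direction!r}")
            )
        for p in m.patterns:
            try:
                _compile(p)
            except LexiconError:
                out.append(
                    Violation(
                        "error", f"{m.modifier_id}: pattern does not compile: {p!r}"
                    )
                )
    # required categories
    cats = {c.category for c in lexicon.concepts}
    for required in ("tumor", "lymph_node"):
        if required not in cats:
            out.append(Violation("error", f"no {required} concept entry"))
    classes = {m.modifier_class for m in lexicon.modifiers}
    for required in ("negation", "uncertainty"):
        if required not in classes:
            out.append(Violation("error", f"no {required} modifier entry"))
    # station coverage 1..14 (warnings only)
    stations = {
        c.attributes.get("station_number")
        for c in lexicon.concepts
        if c.category == "station"
    }
    for num in range(1, 15):
        if num not in stations:
            out.append(Violation("warning", f"station {num} unmapped"))
    return out
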