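"""Text cleaning, sentence splitting and size-measurement extraction.

``clean_text`` is strictly length-preserving (1:1 character substitutions
only) so that all downstream spans stay valid against the original text.
Sizes are normalized to millimeters internally; cm values are multiplied by
10 at extraction time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .corpus_io import SectionedReport
from .lexicon import Lexicon

__all__ = [
    "Sentence",
    "Measurement",
    "clean_text",
    "split_sentences",
    "extract_measurements",
    "apply_blacklist",
]

# 1:1 character maps: unicode spaces -> ASCII space, unicode dashes -> '-'
_SPACE_CHARS = (
    "         "
    "     　"
)
_DASH_CHARS = "‐‑‒–—―−"
_CLEAN_TABLE = str.maketrans(
    {**{c: " " for c in _SPACE_CHARS}, **{c: "-" for c in _DASH_CHARS}}
)
_DECIMAL_COMMA = re.compile(r"(?<=\d),(?=\d)")


def clean_text(text: str) -> str:
    """Length-preserving normalization: unify unicode spaces and dashes, and
    turn a decimal comma between digits into a point ("3,2 cm" -> "3.2 cm")."""
    return _DECIMAL_COMMA.sub(".", text.translate(_CLEAN_TABLE))


@dataclass(frozen=True)
class Sentence:
    index: int
    span: tuple[int, int]  # global, 0-based half-open
    section_label: str
    text: str


_SENT_BOUNDARY = re.compile(r"[.!?]|\n")
_TRAILING_TOKEN = re.compile(r"([\w.]+)\Z")


def split_sentences(report: SectionedReport, lexicon: Optional[Lexicon] = None) -> list[Sentence]:
    """Split each section body into sentences on final punctuation/newlines,
    protecting decimal numbers and the lexicon's abbreviation list."""
    abbrevs = set(lexicon.abbreviations) if lexicon is not None else set()
    sentences: list[Sentence] = []
    text = report.text
    for section in report.sections:
        start, end = section.content_start, section.span[1]
        pos = start  # start of current sentence
        cursor = start  # scan position
        while cursor < end:
            m = _SENT_BOUNDARY.search(text, cursor, end)
            if m is None:
                break
            b = m.start()
            if m.group(0) == ".":
                prev_c = text[b - 1] if b > 0 else ""
                next_c = text[b + 1] if b + 1 < len(text) else ""
                if prev_c.isdigit() and next_c.isdigit():
                    cursor = b + 1  # decimal point, not a boundary
                    continue
                tok = _TRAILING_TOKEN.search(text[pos:b])
                if tok and tok.group(1).lower().rstrip(".") in abbrevs:
                    cursor = b + 1  # protected abbreviation
                    continue
            _push(sentences, text, pos, b + 1, section.canonical_label)
            pos = cursor = b + 1
        if pos < end:
            _push(sentences, text, pos, end, section.canonical_label)
    # re-number after filtering empties
    return [
        Sentence(i, s.span, s.section_label, s.text) for i, s in enumerate(sentences)
    ]


def _push(sentences: list, text: str, start: int, end: int, label: str) -> None:
    raw = text[start:end]
    stripped = raw.strip()
    if not stripped:
        return
    lead = len(raw) - len(raw.lstrip())
    trail = len(raw) - len(raw.rstrip())
    span = (start + lead, end - trail)
    sentences.append(Sentence(len(sentences), span, label, text[span[0] : span[1]]))


@dataclass
class Measurement:
    dims_mm: tuple[float, ...]
    span: tuple[int, int]  # global
    sentence_index: int
    blacklisted: bool = False
    blacklist_tie: bool = False
    attached_concept: Optional[str] = None

    @property
    def long_axis_mm(self) -> float:
        return max(self.dims_mm)

    @property
    def short_axis_mm(self) -> float:
        return min(self.dims_mm)


_NUM = r"\d+(?:\.\d+)?"
_MEAS_RE = re.compile(
    rf"(?<![\w.])({_NUM})"
    rf"(?:\s*-\s*({_NUM}))?"  # range: upper bound is taken
    rf"(?:\s*[x×]\s*({_NUM})(?:\s*[x×]\s*({_NUM}))?)?"
    rf"\s*(mm|cm|millimet\w*|centimet\w*)\b",
    re.IGNORECASE,
)


def extract_measurements(sentence: Sentence) -> list[Measurement]:
    """Extract "<n> mm", "<n> cm", ranges ("1-2 cm" -> upper bound) and 2-3
    dimension forms ("32 x 21 mm"); cm are converted to mm.  Numbers without
    a length unit are ignored."""
    out: list[Measurement] = []
    for m in _MEAS_RE.finditer(sentence.text):
        unit = m.group(5).lower()
        factor = 10.0 if unit.startswith("c") else 1.0
        first = float(m.group(1))
        if m.group(2):  # range: conservative upper bound
            first = max(first, float(m.group(2)))
        dims = [first]
        for g in (m.group(3), m.group(4)):
            if g:
                dims.append(float(g))
        dims_mm = tuple(round(d * factor, 3) for d in dims)
        if any(d <= 0 or d >= 1000 for d in dims_mm):
            continue
        out.append(
            Measurement(
                dims_mm=dims_mm,
                span=(sentence.span[0] + m.start(), sentence.span[0] + m.end()),
                sentence_index=sentence.index,
            )
        )
    return out


def _span_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    if a[1] <= b[0]:
        return b[0] - a[1]
    if b[1] <= a[0]:
        return a[0] - b[1]
    return 0


def apply_blacklist(
    measurements: list[Measurement],
    sentences: list[Sentence],
    lexicon: Lexicon,
) -> list[Measurement]:
    """Flag measurements whose nearest anatomical context is a blacklisted
    organ (adrenal gland, renal cyst, fluid collection, ...).

    A measurement is blacklisted iff a blacklist_anatomy concept occurs in
    the same sentence and no tumor/lymph-node concept sits nearer (in
    characters).  An exact proximity tie keeps the measurement but flags it
    (``blacklist_tie``) for the trace.
    """
    by_index = {s.index: s for s in sentences}
    bl_entries = lexicon.by_category("blacklist_anatomy")
    keep_entries = lexicon.by_category("tumor", "lymph_node")
    for meas in measurements:
        sent = by_index.get(meas.sentence_index)
        if sent is None:
            continue
        local = (meas.span[0] - sent.span[0], meas.span[1] - sent.span[0])
        bl_d = _min_distance(sent.text, bl_entries, local)
        if bl_d is None:
            continue
        keep_d = _min_distance(sent.text, keep_entries, local)
        if keep_d is None or bl_d < keep_d:
            meas.blacklisted = True
        elif bl_d == keep_d:
            meas.blacklist_tie = True
    return measurements


def _min_distance(text: str, entries, span: tuple[int, int]) -> Optional[int]:
    best = None
    for entry in entries:
        for rx in entry.compiled:
            for m in rx.finditer(text):
                d = _span_distance((m.start(), m.end()), span)
                if best is None or d < best:
                    best = d
    return best
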