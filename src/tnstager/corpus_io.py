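"""Corpus reading/writing, report sectionizing and modality detection.

Reports come in as plain UTF-8 text files (one report per file) or as
JSON-lines records with keys ``report_id``, ``text`` and optionally
``modality``, ``gold_t``, ``gold_n``.  Sectionizing splits a report into
labeled sections using the lexicon's ``section_header`` concepts; character
offsets are 0-based half-open into the (cleaned, length-preserved) report
text throughout.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .lexicon import Lexicon

__all__ = [
    "RawReport",
    "LabeledReport",
    "Section",
    "SectionedReport",
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
    "sectionize",
    "detect_modality",
]

MODALITIES = ("CT", "PETCT")


class CorpusFormatError(ValueError):
    pass


@dataclass(frozen=True)
class RawReport:
    report_id: str
    text: str
    modality_hint: Optional[str] = None  # "CT" | "PETCT" | None

    def __post_init__(self):
        if not self.report_id:
            raise CorpusFormatError("report_id must be non-empty")
        if not self.text or not self.text.strip():
            raise CorpusFormatError(f"report {self.report_id!r}: empty text")
        if self.modality_hint not in (None, *MODALITIES):
            raise CorpusFormatError(
                f"report {self.report_id!r}: bad modality {self.modality_hint!r}"
            )


@dataclass(frozen=True)
class LabeledReport(RawReport):
    gold_t: str = ""
    gold_n: str = ""

    def __post_init__(self):
        super().__post_init__()
        from .staging import T_LABELS, N_LABELS

        if self.gold_t not in T_LABELS:
            raise CorpusFormatError(
                f"report {self.report_id!r}: bad gold_t {self.gold_t!r}"
            )
        if self.gold_n not in N_LABELS:
            raise CorpusFormatError(
                f"report {self.report_id!r}: bad gold_n {self.gold_n!r}"
            )


@dataclass(frozen=True)
class Section:
    canonical_label: str
    heading_text: str
    span: tuple[int, int]  # 0-based half-open, includes the heading
    content_start: int  # first character after the heading (== span[0] if none)


@dataclass
class SectionedReport:
    report_id: str
    text: str
    sections: list[Section]
    modality: str = "CT"
    modality_hint: Optional[str] = None

    def section_text(self, section: Section) -> str:
        return self.text[section.content_start : section.span[1]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "report_id": self.report_id,
                "modality": self.modality,
                "sections": [
                    {
                        "canonical_label": s.canonical_label,
                        "heading_text": s.heading_text,
                        "span": list(s.span),
                    }
                    for s in self.sections
                ],
            }
        )


def read_corpus(path: str | Path, format: str = "jsonl"):
    """Read a corpus of reports; returns ``RawReport``s, or ``LabeledReport``s
    when gold labels are supplied.  Order is preserved; duplicate report ids
    and malformed lines raise :class:`CorpusFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusFormatError(f"corpus path does not exist: {path}")
    if format == "txt_dir":
        reports = []
        for f in sorted(path.glob("*.txt")):
            reports.append(RawReport(report_id=f.stem, text=f.read_text("utf-8")))
        _check_unique(reports)
        return reports
    if format != "jsonl":
        raise CorpusFormatError(f"unknown corpus format {format!r}")
    reports = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: malformed JSON ({exc})") from exc
            if not isinstance(obj, dict):
                raise CorpusFormatError(f"line {lineno}: not a JSON object")
            for key in ("report_id", "text"):
                if key not in obj:
                    raise CorpusFormatError(f"line {lineno}: missing key {key!r}")
            kwargs = dict(
                report_id=str(obj["report_id"]),
                text=str(obj["text"]),
                modality_hint=obj.get("modality"),
            )
            try:
                if "gold_t" in obj or "gold_n" in obj:
                    reports.append(
                        LabeledReport(
                            gold_t=str(obj.get("gold_t", "")),
                            gold_n=str(obj.get("gold_n", "")),
                            **kwargs,
                        )
                    )
                else:
                    reports.append(RawReport(**kwargs))
            except CorpusFormatError as exc:
                raise CorpusFormatError(f"line {lineno}: {exc}") from exc
    _check_unique(reports)
    return reports


def _check_unique(reports) -> None:
    seen: set[str] = set()
    for r in reports:
        if r.report_id in seen:
            raise CorpusFormatError(f"duplicate report_id {r.report_id!r}")
        seen.add(r.report_id)


def write_corpus(reports, path: str | Path) -> None:
    """Write reports as JSON-lines (labeled fields included when present)."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in reports:
            obj = {"report_id": r.report_id, "text": r.text}
            if r.modality_hint:
                obj["modality"] = r.modality_hint
            if isinstance(r, LabeledReport):
                obj["gold_t"] = r.gold_t
                obj["gold_n"] = r.gold_n
            fh.write(json.dumps(obj) + "\n")


def _heading_regexes(lexicon: Lexicon):
    out = []
    for entry in lexicon.by_category("section_header"):
        label = entry.attributes.get("canonical", "unsectioned")
        for pat in entry.patterns:
            # anchored at line start, case-insensitive, colon optional (but a
            # bare heading must then be alone on its line)
            out.append(
                (re.compile(r"[ \t]*(?:%s)[ \t]*(?::|$)" % pat, re.IGNORECASE), label)
            )
    return out


def sectionize(report: RawReport, section_lexicon: Lexicon) -> SectionedReport:
    """Split a report into labeled sections at heading lines.

    Every heading match opens a section running to the next heading or the
    end of text; text before the first heading — or a report with no headings
    at all — becomes a single ``unsectioned`` section.  Sections tile the
    whole text (spans are non-overlapping, ordered, and cover everything).
    """
    text = report.text
    regexes = _heading_regexes(section_lexicon)
    headings: list[tuple[int, int, str, str]] = []  # (start, content_start, label, heading_text)
    offset = 0
    for line in text.splitlines(keepends=True):
        stripped = line.rstrip("\r\n")
        best = None
        for rx, label in regexes:
            m = rx.match(stripped)
            if m and (best is None or m.end() > best[0]):
                best = (m.end(), label, stripped[: m.end()].strip().rstrip(":").strip())
        if best is not None:
            headings.append((offset, offset + best[0], best[1], best[2]))
        offset += len(line)

    sections: list[Section] = []
    if not headings or headings[0][0] > 0:
        end = headings[0][0] if headings else len(text)
        if text[:end].strip() or not headings:
            sections.append(
                Section("unsectioned", "", (0, end), content_start=0)
            )
        elif headings:  # whitespace-only prefix: fold into first section
            headings[0] = (0, headings[0][1], headings[0][2], headings[0][3])
    for i, (start, content_start, label, heading_text) in enumerate(headings):
        end = headings[i + 1][0] if i + 1 < len(headings) else len(text)
        sections.append(Section(label, heading_text, (start, end), content_start))

    sectioned = SectionedReport(
        report_id=report.report_id,
        text=text,
        sections=sections,
        modality_hint=report.modality_hint,
    )
    sectioned.modality = detect_modality(sectioned, section_lexicon)
    return sectioned


def detect_modality(report: SectionedReport, lexicon: Lexicon) -> str:
    """CT vs PETCT: an explicit hint wins; otherwise PETCT iff a PET cue
    matches in a modality_description section or >= 2 non-chest body-part
    sections exist; else CT."""
    if report.modality_hint in MODALITIES:
        return report.modality_hint
    cues = lexicon.by_category("modality_cue")
    for section in report.sections:
        if section.canonical_label != "modality_description":
            continue
        body = report.section_text(section)
        for entry in cues:
            if any(rx.search(body) for rx in entry.compiled):
                return "PETCT"
    non_chest = {
        s.canonical_label
        for s in report.sections
        if s.canonical_label.startswith("body_part:")
        and s.canonical_label != "body_part:chest"
    }
    if len(non_chest) >= 2:
        return "PETCT"
    return "CT"
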