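"""Aggregate mentions and measurements into tumor and node findings.

Association is sentence-scoped: a measurement, station, laterality or
avidity cue counts for a tumor/node only when it occurs in the same sentence
(with a nearest-in-characters tie-break), except that a tumor with no size
in its own sentence may pick one up from an adjacent sentence of the same
section that does not describe lymph nodes.

Only *affirmed* mentions contribute pathology; uncertain mentions are
tracked in the trace but excluded (certainty policy), negated mentions yield
nothing.  Evidence is restricted to chest body-part sections, the
impression, and unsectioned text; other body-part sections contribute only
blacklist context.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .context_engine import AFFIRMED, NEGATED, UNCERTAIN, ConceptMention
from .preprocess import Measurement, Sentence

__all__ = ["TumorFinding", "NodeFinding", "extract_tumor", "extract_nodes", "match_avidity"]

EVIDENCE_LABELS = {"impression", "unsectioned", "body_part:chest"}

LOBES = ("RUL", "RML", "RLL", "LUL", "LLL")


@dataclass
class TumorFinding:
    present: bool = False
    size_mm: Optional[float] = None  # long axis
    side: str = "unknown"  # left | right | unknown
    lobes: set[str] = field(default_factory=set)
    invasion_features: set[str] = field(default_factory=set)  # subset of {T2,T3,T4}
    satellite_same_lobe: bool = False
    separate_nodule_other_lobe_same_lung: bool = False
    avid: Optional[bool] = None
    source_sentences: list[int] = field(default_factory=list)


@dataclass
class NodeFinding:
    station: Optional[int] = None  # 1..14 or None (unknown)
    side: str = "unknown"  # left | right | midline | unknown
    size_mm: Optional[float] = None  # short axis
    described_pathologic: bool = False
    avid: Optional[bool] = None  # None == unstated (always for pure CT)
    region: Optional[str] = None  # mediastinal | hilar | supraclavicular
    source_sentence: int = -1


def _evidence_indices(sentences: list[Sentence]) -> set[int]:
    return {s.index for s in sentences if s.section_label in EVIDENCE_LABELS}


def _distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    if a[1] <= b[0]:
        return b[0] - a[1]
    if b[1] <= a[0]:
        return a[0] - b[1]
    return 0


def extract_tumor(
    mentions: list[ConceptMention],
    measurements: list[Measurement],
    sentences: list[Sentence],
) -> tuple[TumorFinding, list[str]]:
    """Build the single TumorFinding for a report.

    Size is the largest long-axis over non-blacklisted measurements in
    sentences carrying an affirmed tumor mention; if those sentences carry no
    measurement, adjacent same-section sentences without node mentions are
    searched as a fallback.
    """
    notes: list[str] = []
    evidence = _evidence_indices(sentences)
    by_index = {s.index: s for s in sentences}

    tumor_mentions = [
        m for m in mentions if m.category == "tumor" and m.sentence_index in evidence
    ]
    affirmed = [m for m in tumor_mentions if m.assertion == AFFIRMED]
    finding = TumorFinding()
    if not affirmed:
        if any(m.assertion == UNCERTAIN for m in tumor_mentions):
            notes.append("context:uncertain_tumor_excluded")
        return finding, notes
    finding.present = True
    tumor_sents = sorted({m.sentence_index for m in affirmed})
    finding.source_sentences = tumor_sents
    node_sents = {
        m.sentence_index for m in mentions if m.category == "lymph_node"
    }

    pool = [
        m
        for m in measurements
        if not m.blacklisted and m.sentence_index in tumor_sents
    ]
    if not pool:
        adjacent: list[Measurement] = []
        for meas in measurements:
            if meas.blacklisted or meas.sentence_index in node_sents:
                continue
            sent = by_index.get(meas.sentence_index)
            if sent is None or sent.index not in evidence:
                continue
            for ts in tumor_sents:
                t_sent = by_index[ts]
                if (
                    abs(sent.index - ts) == 1
                    and sent.section_label == t_sent.section_label
                ):
                    adjacent.append(meas)
                    break
        pool = adjacent
        if pool:
            notes.append("measurement:adjacent_sentence_fallback")
    if pool:
        best = max(pool, key=lambda m: m.long_axis_mm)
        finding.size_mm = best.long_axis_mm
        best.attached_concept = "tumor"
        if any(m.blacklist_tie for m in pool):
            notes.append("measurement:blacklist_tie")
    else:
        notes.append("measurement:no_tumor_size")

    for m in mentions:
        if m.sentence_index not in evidence or m.assertion != AFFIRMED:
            continue
        if m.category == "invasion_target":
            cls = m.attributes.get("t_feature_class")
            if cls:
                finding.invasion_features.add(cls)
        elif m.category == "satellite_nodule":
            finding.satellite_same_lobe = True
        elif m.category == "multilobe_cue":
            finding.separate_nodule_other_lobe_same_lung = True

    finding.lobes = {
        m.attributes["lobe"]
        for m in mentions
        if m.category == "lobe" and m.sentence_index in tumor_sents
    }
    finding.side = _tumor_side(affirmed, mentions, tumor_sents, evidence)
    return finding, notes


def _tumor_side(affirmed, mentions, tumor_sents, evidence) -> str:
    anchor = affirmed[0]
    best_side, best_d = "unknown", None
    for m in mentions:
        if m.category not in ("lobe", "laterality"):
            continue
        side = m.attributes.get("side")
        if side not in ("left", "right"):
            continue
        if m.sentence_index == anchor.sentence_index:
            d = _distance(m.span, anchor.span)
        elif m.sentence_index in tumor_sents:
            d = 10_000 + m.sentence_index
        elif m.sentence_index in evidence:
            d = 100_000 + m.sentence_index
        else:
            continue
        if best_d is None or d < best_d:
            best_side, best_d = side, d
    return best_side


_TRAILING_SIDE = re.compile(r"(?:^|\s|\d)([rl])\s*$", re.IGNORECASE)


def extract_nodes(
    mentions: list[ConceptMention],
    measurements: list[Measurement],
    sentences: list[Sentence],
) -> tuple[list[NodeFinding], list[str]]:
    """One NodeFinding per sentence holding >= 1 affirmed lymph-node mention.

    Station and side come from station/laterality mentions in the same
    sentence (a trailing R/L on the station text wins); size from the
    nearest non-blacklisted measurement (short axis).  Negated node
    sentences yield nothing; sentences whose nodes sit in blacklisted
    anatomy (mesentery, axilla, ...) are excluded as non-thoracic.
    """
    notes: list[str] = []
    evidence = _evidence_indices(sentences)
    findings: list[NodeFinding] = []
    by_sentence: dict[int, list[ConceptMention]] = {}
    for m in mentions:
        by_sentence.setdefault(m.sentence_index, []).append(m)

    for idx in sorted(by_sentence):
        if idx not in evidence:
            continue
        group = by_sentence[idx]
        node_mentions = [m for m in group if m.category == "lymph_node"]
        if not node_mentions:
            continue
        affirmed = [m for m in node_mentions if m.assertion == AFFIRMED]
        if not affirmed:
            if any(m.assertion == UNCERTAIN for m in node_mentions):
                notes.append(f"context:uncertain_node_excluded:sentence_{idx}")
            continue
        station_mentions = [m for m in group if m.category == "station"]
        if not station_mentions and any(
            m.category == "blacklist_anatomy" for m in group
        ):
            notes.append(f"concept:nonthoracic_node_excluded:sentence_{idx}")
            continue
        finding = NodeFinding(source_sentence=idx)
        anchor = affirmed[0]
        if station_mentions:
            st = min(station_mentions, key=lambda m: _distance(m.span, anchor.span))
            finding.station = st.attributes.get("station_number")
            side_m = _TRAILING_SIDE.search(st.text)
            if side_m:
                finding.side = "right" if side_m.group(1).lower() == "r" else "left"
        if finding.side == "unknown":
            lat = [
                m
                for m in group
                if m.category == "laterality"
                and m.attributes.get("side") in ("left", "right", "midline")
            ]
            if lat:
                nearest = min(lat, key=lambda m: _distance(m.span, anchor.span))
                finding.side = nearest.attributes["side"]
        sizes = [
            m
            for m in measurements
            if m.sentence_index == idx and not m.blacklisted
        ]
        if sizes:
            nearest = min(sizes, key=lambda m: _distance(m.span, anchor.span))
            finding.size_mm = nearest.short_axis_mm
            nearest.attached_concept = "lymph_node"
        finding.described_pathologic = any(
            m.attributes.get("pathologic") for m in affirmed
        )
        for m in node_mentions:
            region = m.attributes.get("region")
            if region and finding.region is None:
                finding.region = region
        findings.append(finding)
    return findings, notes


def match_avidity(
    mentions: list[ConceptMention],
    tumor: TumorFinding,
    nodes: list[NodeFinding],
    modality: str,
) -> tuple[TumorFinding, list[NodeFinding]]:
    """Set ``avid`` per finding from avidity cues in the same sentence.

    Only meaningful for PETCT; for CT everything stays unstated (None).  A
    negated avidity_pos mention, or an affirmed avidity_neg mention, counts
    as avid=False; avidity=False wins over True within one sentence.
    """
    if modality != "PETCT":
        tumor.avid = None
        for n in nodes:
            n.avid = None
        return tumor, nodes

    pos_by_sent: dict[int, str] = {}
    for m in mentions:
        if m.category == "avidity_pos":
            if m.assertion == NEGATED:
                pos_by_sent[m.sentence_index] = "neg"
            elif m.assertion == AFFIRMED and pos_by_sent.get(m.sentence_index) != "neg":
                pos_by_sent.setdefault(m.sentence_index, "pos")
        elif m.category == "avidity_neg" and m.assertion in (AFFIRMED, UNCERTAIN):
            pos_by_sent[m.sentence_index] = "neg"

    def verdict(sent_idx: int) -> Optional[bool]:
        v = pos_by_sent.get(sent_idx)
        if v == "pos":
            return True
        if v == "neg":
            return False
        return None

    for n in nodes:
        n.avid = verdict(n.source_sentence)
    tumor.avid = None
    for idx in tumor.source_sentences:
        v = verdict(idx)
        if v is not None:
            tumor.avid = v
            break
    return tumor, nodes
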