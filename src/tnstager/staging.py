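"""TNM-8 T/N mapping with feature overruling and the PET metabolic layer.

The numeric staging tables (T size buckets, node size cutoff, station -> N
map) live in a versioned YAML rules file, not in code, so another edition
can be dropped in.  Size thresholds are inclusive upper bounds in mm.

The metabolic layer: on PET-CT, stated FDG avidity overrules the CT size
criterion for node pathology in both directions — an enlarged node without
uptake is non-pathological, a small avid node is pathological.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .corpus_io import RawReport, sectionize
from .findings import (
    NodeFinding,
    TumorFinding,
    extract_nodes,
    extract_tumor,
    match_avidity,
)
from .lexicon import Lexicon, load_lexicon
from .preprocess import apply_blacklist, clean_text, extract_measurements, split_sentences
from .context_engine import assign_modifiers, find_mentions

__all__ = [
    "T_LABELS",
    "N_LABELS",
    "StagingRules",
    "TNResult",
    "load_rules",
    "map_t",
    "map_n",
    "decide_node_pathologic",
    "stage_report",
]

# total order; generic T2 (feature-based, no size) sits just below T2a
T_LABELS = ("T0", "T1a", "T1b", "T1c", "T2", "T2a", "T2b", "T3", "T4")
N_LABELS = ("N0", "N1", "N2", "N3")
_T_RANK = {label: i for i, label in enumerate(T_LABELS)}
_N_RANK = {label: i for i, label in enumerate(N_LABELS)}


@dataclass(frozen=True)
class StagingRules:
    t_size_thresholds_mm: tuple[tuple[Optional[float], str], ...]
    feature_to_t: dict[str, str]
    node_size_cutoff_mm: float
    station_to_n: dict[int, dict[str, str]]
    region_to_n: dict[str, str]
    version: str = "tnm8"


def default_rules_path() -> Path:
    return Path(resources.files("tnstager") / "data" / "rules" / "tnm8.yaml")


def load_rules(path: str | Path | None = None) -> StagingRules:
    if path is None:
        path = default_rules_path()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    thresholds = tuple(
        (None if t is None else float(t), str(label))
        for t, label in raw["t_size_thresholds_mm"]
    )
    finite = [t for t, _ in thresholds if t is not None]
    if finite != sorted(finite) or len(set(finite)) != len(finite):
        raise ValueError("t_size_thresholds_mm must be strictly increasing")
    station_to_n = {
        int(k): {rel: str(lbl) for rel, lbl in v.items()}
        for k, v in raw["station_to_n"].items()
    }
    for num in range(1, 15):
        if num not in station_to_n:
            raise ValueError(f"station_to_n is missing station {num}")
        for rel in ("ipsilateral", "contralateral"):
            if rel not in station_to_n[num]:
                raise ValueError(f"station {num} is missing the {rel} mapping")
    return StagingRules(
        t_size_thresholds_mm=thresholds,
        feature_to_t={str(k): str(v) for k, v in raw["feature_to_t"].items()},
        node_size_cutoff_mm=float(raw["node_size_cutoff_mm"]),
        station_to_n=station_to_n,
        region_to_n={str(k): str(v) for k, v in raw.get("region_to_n", {}).items()},
        version=str(raw.get("version", "?")),
    )


def _size_stage(size_mm: float, rules: StagingRules) -> str:
    for threshold, label in rules.t_size_thresholds_mm:
        if threshold is None or size_mm <= threshold:
            return label
    return rules.t_size_thresholds_mm[-1][1]  # pragma: no cover


def t_components(tumor: TumorFinding, rules: StagingRules) -> tuple[Optional[str], Optional[str]]:
    """(size-based stage, feature-based stage), either may be None."""
    size_stage = (
        _size_stage(tumor.size_mm, rules) if tumor.size_mm is not None else None
    )
    feature_stages = [
        rules.feature_to_t[f] for f in tumor.invasion_features if f in rules.feature_to_t
    ]
    if tumor.satellite_same_lobe:
        feature_stages.append(rules.feature_to_t.get("satellite_same_lobe", "T3"))
    if tumor.separate_nodule_other_lobe_same_lung:
        feature_stages.append(rules.feature_to_t.get("separate_nodule_other_lobe", "T4"))
    feature_stage = max(feature_stages, key=_T_RANK.__getitem__) if feature_stages else None
    return size_stage, feature_stage


def map_t(tumor: TumorFinding, rules: StagingRules) -> str:
    """Size bucket vs feature overruling: the final T is the max of the two;
    a tumor with a T2 feature but no size gets the generic T2 label; no
    certain tumor at all yields T0."""
    if not tumor.present:
        return "T0"
    size_stage, feature_stage = t_components(tumor, rules)
    candidates = [s for s in (size_stage, feature_stage) if s is not None]
    if not candidates:
        return "T0"
    return max(candidates, key=_T_RANK.__getitem__)


def decide_node_pathologic(
    node: NodeFinding, modality: str, rules: StagingRules
) -> bool:
    """PETCT: stated avidity wins in both directions; unstated avidity (and
    plain CT) falls back to the CT rule: affirmed pathologic wording or
    short axis >= cutoff."""
    if modality == "PETCT" and node.avid is not None:
        return node.avid
    if node.described_pathologic:
        return True
    return node.size_mm is not None and node.size_mm >= rules.node_size_cutoff_mm


def _station_n(station: int, node_side: str, tumor_side: str, rules: StagingRules) -> tuple[str, Optional[str]]:
    """N label for one pathologic node; returns (label, warning-or-None)."""
    mapping = rules.station_to_n[station]
    if node_side in ("midline", "unknown"):
        return mapping["ipsilateral"], None
    if tumor_side == "unknown":
        return mapping["ipsilateral"], (
            f"staging:unknown_tumor_side_station_{station}_assumed_ipsilateral"
        )
    if node_side != tumor_side:
        return mapping["contralateral"], None
    return mapping["ipsilateral"], None


def map_n(
    nodes: list[NodeFinding],
    tumor_side: str,
    modality: str,
    rules: StagingRules,
    trace: Optional[list[str]] = None,
) -> str:
    """Max N over pathologic nodes; station 1 is N3 and station 7 N2
    irrespective of side; a pathologic node with no recognizable station
    degrades to its regional wording (mediastinal -> N2, ...) with a trace
    warning; no pathologic nodes -> N0."""
    best = "N0"
    for node in nodes:
        pathologic = decide_node_pathologic(node, modality, rules)
        if trace is not None and modality == "PETCT" and node.avid is not None:
            size_based = node.described_pathologic or (
                node.size_mm is not None and node.size_mm >= rules.node_size_cutoff_mm
            )
            if size_based != node.avid:
                trace.append(
                    f"context:pet_overruling:sentence_{node.source_sentence}:"
                    f"size_verdict={size_based}:avid={node.avid}"
                )
        if not pathologic:
            continue
        if node.station is not None:
            label, warning = _station_n(node.station, node.side, tumor_side, rules)
            if warning and trace is not None:
                trace.append(warning)
        else:
            region = node.region or "unknown"
            label = rules.region_to_n.get(region, "N2")
            if trace is not None:
                trace.append(
                    f"staging:unknown_station_region_{region}_mapped_{label}"
                )
        if _N_RANK[label] > _N_RANK[best]:
            best = label
    return best


@dataclass
class TNResult:
    report_id: str
    t: str
    n: str
    trace: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"report_id": self.report_id, "t": self.t, "n": self.n, "trace": list(self.trace)}


def stage_report(
    report: RawReport,
    lexicon: Optional[Lexicon] = None,
    rules: Optional[StagingRules] = None,
) -> TNResult:
    """Run the full pipeline on one report and return (T, N) with a trace."""
    if not report.text or not report.text.strip():
        raise ValueError(f"report {report.report_id!r}: empty text")
    if lexicon is None:
        lexicon = load_lexicon()
    if rules is None:
        rules = load_rules()

    trace: list[str] = []
    cleaned = RawReport(
        report_id=report.report_id,
        text=clean_text(report.text),
        modality_hint=report.modality_hint,
    )
    sectioned = sectionize(cleaned, lexicon)
    labels = [s.canonical_label for s in sectioned.sections]
    if labels == ["unsectioned"]:
        trace.append("sectionizer:unsectioned_fallback")
    trace.append(f"sectionizer:{len(labels)}_sections")
    trace.append(f"modality:{sectioned.modality}")

    sentences = split_sentences(sectioned, lexicon)
    mentions = []
    measurements = []
    for sentence in sentences:
        ms = find_mentions(sentence, lexicon)
        ms = assign_modifiers(sentence, ms, lexicon)
        mentions.extend(ms)
        measurements.extend(extract_measurements(sentence))
    apply_blacklist(measurements, sentences, lexicon)
    for meas in measurements:
        if meas.blacklisted:
            trace.append(f"measurement:blacklisted:{meas.dims_mm}mm")

    tumor, tumor_notes = extract_tumor(mentions, measurements, sentences)
    nodes, node_notes = extract_nodes(mentions, measurements, sentences)
    trace.extend(tumor_notes)
    trace.extend(node_notes)
    match_avidity(mentions, tumor, nodes, sectioned.modality)

    t = map_t(tumor, rules)
    size_stage, feature_stage = t_components(tumor, rules)
    if (
        size_stage is not None
        and feature_stage is not None
        and _T_RANK[feature_stage] > _T_RANK[size_stage]
    ):
        trace.append(f"staging:t_feature_overruled_size:{size_stage}->{feature_stage}")
    trace.append(
        f"staging:tumor:present={tumor.present}:size={tumor.size_mm}:side={tumor.side}"
    )
    n = map_n(nodes, tumor.side, sectioned.modality, rules, trace=trace)
    trace.append(f"staging:nodes:{len(nodes)}")
    trace.append(f"result:{t}:{n}")
    return TNResult(report_id=report.report_id, t=t, n=n, trace=trace)
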