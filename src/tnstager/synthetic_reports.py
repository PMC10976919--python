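"""Labeled synthetic CT / PET-CT report generator.

Reports are generated findings-first: a (T, N) plan is drawn, checked
against the staging rules (self-check at generation time), and only then
rendered to text from the template pools, so gold labels are guaranteed by
construction.  Adversarial phenomena (negated/uncertain distractors,
blacklisted organ sizes, missing subheadings, multi-dimension sizes,
implicit satellite/multilobe phrasing, CT-vs-PET avidity conflicts) are
injected as distractors that must not change the gold label.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .corpus_io import LabeledReport
from .findings import NodeFinding, TumorFinding
from .staging import StagingRules, load_rules, map_n, map_t

__all__ = [
    "GeneratorSpec",
    "GenerationError",
    "DEFAULT_STAGE_WEIGHTS",
    "DEFAULT_ADVERSARIAL_RATES",
    "generate_report",
    "generate_corpus",
]


class GenerationError(ValueError):
    pass


# Joint (T, N) weight table; the default shape follows a primary-staging
# cohort mix that is heavy on T4 and sparse in the T1aN1-type cells.
DEFAULT_STAGE_WEIGHTS: dict[tuple[str, str], float] = {
    ("T1a", "N0"): 1,
    ("T1b", "N0"): 4,
    ("T1b", "N2"): 1,
    ("T1c", "N0"): 3,
    ("T1c", "N1"): 1,
    ("T1c", "N2"): 1,
    ("T1c", "N3"): 1,
    ("T2", "N3"): 2,
    ("T2a", "N0"): 4,
    ("T2a", "N2"): 3,
    ("T2a", "N3"): 3,
    ("T2b", "N0"): 2,
    ("T2b", "N2"): 1,
    ("T2b", "N3"): 2,
    ("T3", "N0"): 5,
    ("T3", "N1"): 1,
    ("T3", "N2"): 4,
    ("T3", "N3"): 3,
    ("T4", "N0"): 11,
    ("T4", "N1"): 2,
    ("T4", "N2"): 4,
    ("T4", "N3"): 4,
}

ADVERSARIAL_KNOBS = (
    "negation",
    "uncertainty",
    "blacklist_trap",
    "missing_subheadings",
    "multidim_size",
    "implicit_satellite",
    "avidity_conflict",
)

DEFAULT_ADVERSARIAL_RATES: dict[str, float] = {
    "negation": 0.2,
    "uncertainty": 0.2,
    "blacklist_trap": 0.2,
    "missing_subheadings": 0.1,
    "multidim_size": 0.2,
    "implicit_satellite": 0.2,
    "avidity_conflict": 0.2,
}


@dataclass(frozen=True)
class GeneratorSpec:
    n_reports: int
    modality_mix: float = 0.6  # fraction PET-CT
    stage_distribution: Optional[dict[tuple[str, str], float]] = None
    adversarial_rates: Optional[dict[str, float]] = None
    seed: int = 0

    def resolved_weights(self) -> dict[tuple[str, str], float]:
        weights = dict(self.stage_distribution or DEFAULT_STAGE_WEIGHTS)
        if any(w < 0 for w in weights.values()) or not any(weights.values()):
            raise GenerationError("stage weights must be non-negative, not all zero")
        return weights

    def resolved_rates(self) -> dict[str, float]:
        rates = dict(DEFAULT_ADVERSARIAL_RATES) if self.adversarial_rates is None else {
            **{k: 0.0 for k in ADVERSARIAL_KNOBS},
            **self.adversarial_rates,
        }
        for name, rate in rates.items():
            if name not in ADVERSARIAL_KNOBS:
                raise GenerationError(f"unknown adversarial knob {name!r}")
            if not 0.0 <= rate <= 1.0:
                raise GenerationError(f"adversarial rate {name}={rate} outside [0, 1]")
        return rates


_TEMPLATES_CACHE: dict[str, dict] = {}


def _load_templates(path: str | Path | None = None) -> dict:
    key = str(path or "default")
    if key not in _TEMPLATES_CACHE:
        if path is None:
            path = Path(resources.files("tnstager") / "data" / "templates" / "en_default.yaml")
        with open(path, "r", encoding="utf-8") as fh:
            _TEMPLATES_CACHE[key] = yaml.safe_load(fh)
    return _TEMPLATES_CACHE[key]


_LOBES = {"right": ["right upper lobe", "right lower lobe", "middle lobe"],
          "left": ["left upper lobe", "left lower lobe"]}
_LOBE_IDS = {
    "right upper lobe": "RUL",
    "middle lobe": "RML",
    "right lower lobe": "RLL",
    "left upper lobe": "LUL",
    "left lower lobe": "LLL",
}

_T_SIZE_BUCKETS = {
    "T1a": (6, 10),
    "T1b": (11, 20),
    "T1c": (21, 30),
    "T2a": (31, 40),
    "T2b": (41, 50),
}

_N3_CONTRA_STATIONS = [2, 3, 4, 5, 6, 8, 9, 10, 11, 12, 13, 14]


@dataclass
class _TumorPlan:
    size_mm: Optional[int]
    feature_key: Optional[str] = None  # template key, e.g. "T3_chest_wall"
    satellite: bool = False
    multilobe: bool = False

    @property
    def feature_class(self) -> Optional[str]:
        return self.feature_key.split("_", 1)[0] if self.feature_key else None


@dataclass
class _NodePlan:
    station: int
    letter: str  # "R" | "L" | ""
    size_mm: int
    style: str  # "ct" | "avid" | "avid_enlarged" | "conflict"

    @property
    def side(self) -> str:
        return {"R": "right", "L": "left", "": "unknown"}[self.letter]


def _plan_tumor(t: str, flags: set[str], rng: random.Random, templates: dict) -> _TumorPlan:
    if t in _T_SIZE_BUCKETS:
        lo, hi = _T_SIZE_BUCKETS[t]
        return _TumorPlan(size_mm=rng.randint(lo, hi))
    if t == "T2":
        key = rng.choice([k for k in templates["invasion"] if k.startswith("T2")])
        return _TumorPlan(size_mm=None, feature_key=key)
    if t == "T3":
        variant = "satellite" if "implicit_satellite" in flags else rng.choice(
            ["size", "invasion", "satellite"]
        )
        if variant == "size":
            return _TumorPlan(size_mm=rng.randint(51, 70))
        if variant == "invasion":
            key = rng.choice([k for k in templates["invasion"] if k.startswith("T3")])
            return _TumorPlan(size_mm=rng.randint(11, 45), feature_key=key)
        return _TumorPlan(size_mm=rng.randint(11, 45), satellite=True)
    if t == "T4":
        variant = rng.choice(["size", "invasion", "multilobe"])
        if variant == "size":
            return _TumorPlan(size_mm=rng.randint(71, 95))
        if variant == "invasion":
            key = rng.choice([k for k in templates["invasion"] if k.startswith("T4")])
            return _TumorPlan(size_mm=rng.randint(11, 60), feature_key=key)
        return _TumorPlan(size_mm=rng.randint(11, 60), multilobe=True)
    raise GenerationError(f"cannot generate gold T stage {t!r}")


def _plan_nodes(
    n: str, tumor_side: str, modality: str, flags: set[str], rng: random.Random
) -> list[_NodePlan]:
    ipsi = "R" if tumor_side == "right" else "L"
    contra = "L" if ipsi == "R" else "R"

    def style_and_size() -> tuple[str, int]:
        if modality == "PETCT" and rng.random() < 0.5:
            if rng.random() < 0.5:
                return "avid", rng.randint(6, 9)
            return "avid_enlarged", rng.randint(11, 18)
        return "ct", rng.randint(11, 22)

    plans: list[_NodePlan] = []
    if n == "N1":
        style, size = style_and_size()
        plans.append(_NodePlan(rng.randint(10, 14), ipsi, size, style))
    elif n == "N2":
        station = rng.choice([2, 3, 4, 5, 6, 7, 8, 9])
        letter = "" if station == 7 else ipsi
        style, size = style_and_size()
        plans.append(_NodePlan(station, letter, size, style))
    elif n == "N3":
        style, size = style_and_size()
        if rng.random() < 0.5:
            plans.append(_NodePlan(1, "", size, style))
        else:
            plans.append(_NodePlan(rng.choice(_N3_CONTRA_STATIONS), contra, size, style))
    elif n != "N0":
        raise GenerationError(f"cannot generate gold N stage {n!r}")
    if "avidity_conflict" in flags and modality == "PETCT":
        # enlarged contralateral node explicitly without uptake: PET overrules
        # size, so it must not contribute to N
        plans.append(
            _NodePlan(rng.choice(_N3_CONTRA_STATIONS), contra, rng.randint(12, 18), "conflict")
        )
    return plans


def _station_phrase(plan: _NodePlan, rng: random.Random) -> str:
    if plan.station == 1:
        return rng.choice(["station 1", "the supraclavicular region"])
    if plan.station == 7 and plan.letter == "":
        return rng.choice(["station 7", "the subcarinal region"])
    return f"station {plan.station}{plan.letter}"


def _size_str(size_mm: int, flags: set[str], rng: random.Random, allow_cm: bool = True) -> str:
    if "multidim_size" in flags:
        short = max(1, int(round(size_mm * rng.uniform(0.6, 0.9))))
        if short >= size_mm:
            short = size_mm - 1
        return f"{size_mm} x {short} mm"
    if allow_cm and size_mm % 5 == 0 and rng.random() < 0.5:
        return f"{size_mm / 10:.1f} cm"
    return f"{size_mm} mm"


def _node_sentence(plan: _NodePlan, flags: set[str], rng: random.Random, templates: dict) -> str:
    phrase = _station_phrase(plan, rng)
    if plan.style == "conflict":
        tpl = rng.choice(templates["node_conflict"])
        return tpl.format(station_phrase=phrase, size=plan.size_mm)
    if plan.style == "avid":
        tpl = rng.choice(templates["node_pet_avid"])
        return tpl.format(station_phrase=phrase, size=plan.size_mm)
    if plan.style == "avid_enlarged":
        tpl = rng.choice(templates["node_pet_avid_enlarged"])
        return tpl.format(station_phrase=phrase, size=plan.size_mm)
    size = plan.size_mm
    size_text = str(size)
    if "multidim_size" in flags:
        long_axis = size + rng.randint(2, 6)
        size_text = f"{long_axis} x {size}"
    tpl = rng.choice(templates["node_ct_pathologic"])
    return tpl.format(station_phrase=phrase, size=size_text)


def _self_check(
    t: str,
    n: str,
    tumor_side: str,
    lobe_id: str,
    tumor_plan: _TumorPlan,
    node_plans: list[_NodePlan],
    modality: str,
    rules: StagingRules,
) -> None:
    tumor = TumorFinding(
        present=True,
        size_mm=float(tumor_plan.size_mm) if tumor_plan.size_mm is not None else None,
        side=tumor_side,
        lobes={lobe_id},
        invasion_features={tumor_plan.feature_class} if tumor_plan.feature_class else set(),
        satellite_same_lobe=tumor_plan.satellite,
        separate_nodule_other_lobe_same_lung=tumor_plan.multilobe,
    )
    got_t = map_t(tumor, rules)
    if got_t != t:
        raise GenerationError(f"tumor plan stages to {got_t}, wanted {t}")
    nodes = []
    for plan in node_plans:
        nodes.append(
            NodeFinding(
                station=plan.station,
                side=plan.side,
                size_mm=float(plan.size_mm),
                described_pathologic=plan.style in ("ct", "avid_enlarged", "conflict"),
                avid={"avid": True, "avid_enlarged": True, "conflict": False}.get(
                    plan.style
                )
                if modality == "PETCT"
                else None,
            )
        )
    got_n = map_n(nodes, tumor_side, modality, rules)
    if got_n != n:
        raise GenerationError(f"node plan stages to {got_n}, wanted {n}")


def generate_report(
    t: str,
    n: str,
    modality: str = "CT",
    flags: set[str] | frozenset[str] = frozenset(),
    rng: Optional[random.Random] = None,
    *,
    report_id: str = "synth-0000",
    rules: Optional[StagingRules] = None,
    templates_path: str | Path | None = None,
) -> LabeledReport:
    """Generate one labeled report whose text stages exactly to (t, n)."""
    if rng is None:
        rng = random.Random(0)
    if rules is None:
        rules = load_rules()
    templates = _load_templates(templates_path)
    flags = set(flags)
    if modality not in ("CT", "PETCT"):
        raise GenerationError(f"bad modality {modality!r}")

    tumor_side = rng.choice(["left", "right"])
    lobe_name = rng.choice(_LOBES[tumor_side])
    lobe_id = _LOBE_IDS[lobe_name]
    tumor_plan = _plan_tumor(t, flags, rng, templates)
    node_plans = _plan_nodes(n, tumor_side, modality, flags, rng)
    _self_check(t, n, tumor_side, lobe_id, tumor_plan, node_plans, modality, rules, )

    tumor_word = rng.choice(templates["tumor_word"])
    chest: list[str] = []
    if tumor_plan.size_mm is not None:
        chest.append(
            rng.choice(templates["tumor_with_size"]).format(
                tumor_word=tumor_word,
                lobe_name=lobe_name,
                size_str=_size_str(tumor_plan.size_mm, flags, rng),
            )
        )
    else:
        chest.append(
            rng.choice(templates["tumor_no_size"]).format(
                tumor_word=tumor_word, lobe_name=lobe_name
            )
        )
    if tumor_plan.feature_key:
        chest.append(templates["invasion"][tumor_plan.feature_key].format(tumor_word=tumor_word))
    if tumor_plan.satellite:
        key = "implicit" if "implicit_satellite" in flags else "explicit"
        chest.append(templates["satellite"][key].format(lobe_name=lobe_name))
    if tumor_plan.multilobe:
        key = "implicit" if "implicit_satellite" in flags else "explicit"
        chest.append(templates["multilobe"][key].format(side=tumor_side))

    for plan in node_plans:
        chest.append(_node_sentence(plan, flags, rng, templates))
    if n == "N0":
        chest.append(rng.choice(templates["node_negated"]))

    if "negation" in flags:
        active = {tumor_plan.feature_key or "", "multilobe" if tumor_plan.multilobe else ""}
        options = [
            s
            for s in templates["negation_distractor"]
            if not ("chest wall" in s and tumor_plan.feature_key == "T3_chest_wall")
            and not ("another lobe" in s and tumor_plan.multilobe)
        ]
        chest.append(rng.choice(options))
    uncertainty_sent = (
        rng.choice(templates["uncertainty_distractor"]) if "uncertainty" in flags else None
    )
    trap_sent = (
        rng.choice(templates["blacklist_trap"]).format(size=rng.randint(30, 60))
        if "blacklist_trap" in flags
        else None
    )

    impression = rng.choice(templates["impression"]).format(side=tumor_side)
    impression = impression[0].upper() + impression[1:]
    clinical = rng.choice(templates["clinical"])
    technique = rng.choice(
        templates["technique_petct" if modality == "PETCT" else "technique_ct"]
    )

    headers = templates["headers"]["petct" if modality == "PETCT" else "ct"]
    parts: list[tuple[str, list[str]]] = [
        (headers["clinical"], [clinical]),
        (headers["technique"], [technique]),
    ]
    if modality == "PETCT":
        abdomen = [templates["filler"]["abdomen"]]
        if trap_sent:
            abdomen.append(trap_sent)
        if uncertainty_sent:
            chest_or_abd = rng.choice([chest, abdomen])
            chest_or_abd.append(uncertainty_sent)
        parts.append((headers["neck"], [templates["filler"]["neck"]]))
        parts.append((headers["chest"], chest))
        parts.append((headers["abdomen"], abdomen))
        parts.append((headers["skeleton"], [templates["filler"]["skeleton"]]))
    else:
        if trap_sent:
            chest.append(trap_sent)
        if uncertainty_sent:
            chest.append(uncertainty_sent)
        parts.append((headers["chest"], chest))
    parts.append((headers["impression"], [impression]))

    if "missing_subheadings" in flags:
        text = "\n".join(" ".join(sentences) for _, sentences in parts)
    else:
        text = "\n".join(
            f"{header}: " + " ".join(sentences) for header, sentences in parts
        )

    return LabeledReport(
        report_id=report_id,
        text=text,
        modality_hint=modality,
        gold_t=t,
        gold_n=n,
    )


def generate_corpus(spec: GeneratorSpec) -> list[LabeledReport]:
    """Generate ``spec.n_reports`` labeled reports; deterministic under seed."""
    weights = spec.resolved_weights()
    rates = spec.resolved_rates()
    if not 0.0 <= spec.modality_mix <= 1.0:
        raise GenerationError(f"modality_mix {spec.modality_mix} outside [0, 1]")
    rng = random.Random(spec.seed)
    rules = load_rules()
    population = sorted(weights)
    weight_list = [weights[k] for k in population]
    reports: list[LabeledReport] = []
    for i in range(spec.n_reports):
        t, n = rng.choices(population, weights=weight_list, k=1)[0]
        modality = "PETCT" if rng.random() < spec.modality_mix else "CT"
        flags = {name for name in ADVERSARIAL_KNOBS if rng.random() < rates[name]}
        reports.append(
            generate_report(
                t,
                n,
                modality,
                flags,
                rng,
                report_id=f"synth-{i:04d}",
                rules=rules,
            )
        )
    return reports
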