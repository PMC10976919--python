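import itertools
import random

import pytest

from tnstager.corpus_io import RawReport
from tnstager.findings import NodeFinding, TumorFinding
from tnstager.staging import (
    N_LABELS,
    T_LABELS,
    decide_node_pathologic,
    load_rules,
    map_n,
    map_t,
    stage_report,
)
from tnstager.synthetic_reports import generate_report


def _tumor(size=None, features=(), satellite=False, multilobe=False, present=True, side="right"):
    return TumorFinding(
        present=present,
        size_mm=size,
        side=side,
        invasion_features=set(features),
        satellite_same_lobe=satellite,
        separate_nodule_other_lobe_same_lung=multilobe,
    )


def _node(station=None, side="unknown", size=None, pathologic=False, avid=None, region=None):
    return NodeFinding(
        station=station,
        side=side,
        size_mm=size,
        described_pathologic=pathologic,
        avid=avid,
        region=region,
    )


class TestMapT:
    @pytest.mark.parametrize(
        "size,expected",
        [
            (5, "T1a"),
            (10, "T1a"),
            (11, "T1b"),
            (20, "T1b"),
            (30, "T1c"),
            (31, "T2a"),
            (40, "T2a"),
            (50, "T2b"),
            (70, "T3"),
            (71, "T4"),
            (95, "T4"),
        ],
    )
    def test_size_buckets_inclusive(self, rules, size, expected):
        assert map_t(_tumor(size=size), rules) == expected

    def test_satellite_overrules_size(self, rules):
        assert map_t(_tumor(size=20, satellite=True), rules) == "T3"

    def test_separate_nodule_other_lobe_t4(self, rules):
        assert map_t(_tumor(size=15, multilobe=True), rules) == "T4"

    def test_feature_overrules_size(self, rules):
        assert map_t(_tumor(size=25, features={"T4"}), rules) == "T4"

    def test_size_overrules_lower_feature(self, rules):
        assert map_t(_tumor(size=80, features={"T2"}), rules) == "T4"

    def test_generic_t2_without_size(self, rules):
        assert map_t(_tumor(size=None, features={"T2"}), rules) == "T2"

    def test_absent_tumor_t0(self, rules):
        assert map_t(_tumor(present=False), rules) == "T0"

    def test_monotone_in_size_and_features(self, rules):
        order = {label: i for i, label in enumerate(T_LABELS)}
        flags = [
            {},
            {"features": {"T2"}},
            {"features": {"T3"}},
            {"features": {"T4"}},
            {"satellite": True},
            {"multilobe": True},
        ]
        for kwargs in flags:
            prev = 0
            for size in range(1, 96):
                rank = order[map_t(_tumor(size=size, **kwargs), rules)]
                assert rank >= prev
                prev = rank
        for size in (5, 25, 45, 75):
            base = order[map_t(_tumor(size=size), rules)]
            for kwargs in flags[1:]:
                assert order[map_t(_tumor(size=size, **kwargs), rules)] >= base


class TestDecideNodePathologic:
    def test_pet_enlarged_but_not_avid(self, rules):
        node = _node(size=14, pathologic=True, avid=False)
        assert decide_node_pathologic(node, "PETCT", rules) is False

    def test_pet_small_but_avid(self, rules):
        node = _node(size=7, avid=True)
        assert decide_node_pathologic(node, "PETCT", rules) is True

    def test_ct_size_cutoff(self, rules):
        assert decide_node_pathologic(_node(size=12), "CT", rules) is True
        assert decide_node_pathologic(_node(size=9), "CT", rules) is False
        assert decide_node_pathologic(_node(size=10), "CT", rules) is True

    def test_ct_pathologic_wording(self, rules):
        assert decide_node_pathologic(_node(pathologic=True), "CT", rules) is True

    def test_pet_unstated_falls_back_to_ct_rule(self, rules):
        assert decide_node_pathologic(_node(size=14), "PETCT", rules) is True
        assert decide_node_pathologic(_node(size=8), "PETCT", rules) is False

    def test_avidity_dominance_flip(self, rules):
        # wherever size-based and avidity-based verdicts disagree, flipping
        # avidity must flip the decision
        for size, pathologic in itertools.product((6, 9, 10, 14, None), (False, True)):
            for avid in (True, False):
                node = _node(size=size, pathologic=pathologic, avid=avid)
                size_verdict = pathologic or (size is not None and size >= 10)
                if size_verdict != avid:
                    flipped = _node(size=size, pathologic=pathologic, avid=not avid)
                    assert (
                        decide_node_pathologic(node, "PETCT", rules)
                        != decide_node_pathologic(flipped, "PETCT", rules)
                    )


class TestMapN:
    def test_ipsilateral_mediastinal_n2(self, rules):
        node = _node(station=4, side="right", size=14)
        assert map_n([node], "right", "CT", rules) == "N2"

    def test_contralateral_hilar_n3(self, rules):
        node = _node(station=10, side="left", size=14)
        assert map_n([node], "right", "CT", rules) == "N3"

    def test_no_pathologic_nodes_n0(self, rules):
        assert map_n([], "right", "CT", rules) == "N0"
        small = _node(station=4, side="right", size=6)
        assert map_n([small], "right", "CT", rules) == "N0"

    def test_station_1_always_n3(self, rules):
        for side in ("left", "right", "midline", "unknown"):
            node = _node(station=1, side=side, size=12)
            assert map_n([node], "right", "CT", rules) == "N3"

    def test_station_7_always_n2(self, rules):
        for side in ("left", "right", "midline", "unknown"):
            node = _node(station=7, side=side, size=12)
            assert map_n([node], "right", "CT", rules) == "N2"

    def test_unknown_tumor_side_conservative_with_warning(self, rules):
        trace = []
        node = _node(station=4, side="left", size=14)
        assert map_n([node], "unknown", "CT", rules, trace=trace) == "N2"
        assert any("unknown_tumor_side" in line for line in trace)

    def test_unknown_station_region_fallback(self, rules):
        trace = []
        node = _node(size=14, pathologic=True, region="mediastinal")
        assert map_n([node], "right", "CT", rules, trace=trace) == "N2"
        assert any("unknown_station" in line for line in trace)

    def test_adding_node_never_lowers_n(self, rules):
        rank = {label: i for i, label in enumerate(N_LABELS)}
        rng = random.Random(3)
        for _ in range(200):
            nodes = [
                _node(
                    station=rng.randint(1, 14),
                    side=rng.choice(["left", "right", "midline"]),
                    size=rng.choice([6, 14]),
                )
                for _ in range(rng.randint(0, 3))
            ]
            extra = _node(
                station=rng.randint(1, 14),
                side=rng.choice(["left", "right", "midline"]),
                size=14,
            )
            base = map_n(nodes, "right", "CT", rules)
            more = map_n(nodes + [extra], "right", "CT", rules)
            assert rank[more] >= rank[base]


class TestStageReport:
    def test_generator_round_trip_fixed_seed(self, lexicon, rules):
        rng = random.Random(77)
        report = generate_report("T1c", "N2", "CT", set(), rng, report_id="rt")
        result = stage_report(report, lexicon, rules)
        assert (result.t, result.n) == ("T1c", "N2")

    def test_all_negated_is_t0_n0(self, lexicon, rules):
        report = RawReport(
            "neg", "Chest: no mass is seen. No pathologically enlarged lymph nodes."
        )
        result = stage_report(report, lexicon, rules)
        assert (result.t, result.n) == ("T0", "N0")
        assert result.trace

    def test_pet_overruling_both_ways(self, lexicon, rules):
        text = (
            "Technique: FDG PET-CT of the whole body.\n"
            "Chest: mass in the right upper lobe, 30 mm. "
            "Enlarged lymph node at station 4L, 15 mm, without FDG uptake. "
            "FDG-avid lymph node at station 11R, 7 mm.\n"
            "Impression: known right pulmonary malignancy."
        )
        result = stage_report(RawReport("pet", text, "PETCT"), lexicon, rules)
        assert result.n == "N1"
        assert any("pet_overruling" in line for line in result.trace)

    def test_deterministic(self, lexicon, rules):
        rng = random.Random(5)
        report = generate_report("T3", "N3", "PETCT", {"avidity_conflict"}, rng)
        a = stage_report(report, lexicon, rules)
        b = stage_report(report, lexicon, rules)
        assert (a.t, a.n, a.trace) == (b.t, b.n, b.trace)

    def test_empty_text_raises(self, lexicon, rules):
        report = RawReport.__new__(RawReport)  # bypass validation on purpose
        object.__setattr__(report, "report_id", "e")
        object.__setattr__(report, "text", "   ")
        object.__setattr__(report, "modality_hint", None)
        with pytest.raises(ValueError, match="empty"):
            stage_report(report, lexicon, rules)


class TestRulesLoading:
    def test_default_rules(self, rules):
        assert rules.node_size_cutoff_mm == 10
        assert rules.station_to_n[7]["contralateral"] == "N2"
        assert rules.station_to_n[1]["ipsilateral"] == "N3"

    def test_threshold_monotonicity_enforced(self, tmp_path):
        bad = tmp_path / "r.yaml"
        bad.write_text(
            "t_size_thresholds_mm: [[20, T1b], [10, T1a], [null, T4]]\n"
            "feature_to_t: {T2: T2}\n"
            "node_size_cutoff_mm: 10\n"
            "station_to_n: {"
            + ", ".join(
                f"{i}: {{ipsilateral: N2, contralateral: N3}}" for i in range(1, 15)
            )
            + "}\n"
        )
        with pytest.raises(ValueError, match="increasing"):
            load_rules(bad)

    def test_missing_station_rejected(self, tmp_path):
        bad = tmp_path / "r.yaml"
        bad.write_text(
            "t_size_thresholds_mm: [[null, T4]]\n"
            "feature_to_t: {T2: T2}\n"
            "node_size_cutoff_mm: 10\n"
            "station_to_n: {1: {ipsilateral: N3, contralateral: N3}}\n"
        )
        with pytest.raises(ValueError, match="missing station"):
            load_rules(bad)
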