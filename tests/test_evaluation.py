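import random

import pytest

from tnstager.corpus_io import LabeledReport
from tnstager.evaluation import (
    EvaluationError,
    error_report,
    error_report_frame,
    evaluate,
)
from tnstager.staging import N_LABELS, T_LABELS, TNResult


def _gold(i, t, n):
    return LabeledReport(f"r{i}", "text", gold_t=t, gold_n=n)


def _pred(i, t, n, trace=()):
    return TNResult(f"r{i}", t, n, trace=list(trace) or ["result"])


class TestEvaluate:
    def test_three_of_four_correct(self):
        gold = [_gold(0, "T1a", "N0"), _gold(1, "T1b", "N1"), _gold(2, "T3", "N2"), _gold(3, "T4", "N3")]
        preds = [_pred(0, "T1a", "N0"), _pred(1, "T1b", "N1"), _pred(2, "T3", "N2"), _pred(3, "T4", "N0")]
        metrics = evaluate(preds, gold)
        assert metrics.accuracy_tn == 0.75
        assert metrics.accuracy_t == 1.0
        assert metrics.accuracy_n == 0.75

    def test_all_correct_diagonal(self):
        gold = [_gold(i, "T2a", "N1") for i in range(3)]
        preds = [_pred(i, "T2a", "N1") for i in range(3)]
        metrics = evaluate(preds, gold)
        assert metrics.accuracy_t == metrics.accuracy_n == metrics.accuracy_tn == 1.0
        for df in (metrics.confusion_t, metrics.confusion_n, metrics.confusion_tn):
            off_diag = df.values.sum() - sum(
                df.loc[label, label] for label in df.index if label in df.columns
            )
            assert off_diag == 0

    def test_toy_weighted_f1(self):
        # gold [A, A, B], pred [A, B, B] with A=T1aN0, B=T1bN0; the
        # independent one-vs-rest oracle (and sklearn) gives:
        #   class A: p=1, r=1/2, f1=2/3; class B: p=1/2, r=1, f1=2/3
        #   weighted F1 = (2/3)*(2/3) + (1/3)*(2/3) = 2/3
        gold = [_gold(0, "T1a", "N0"), _gold(1, "T1a", "N0"), _gold(2, "T1b", "N0")]
        preds = [_pred(0, "T1a", "N0"), _pred(1, "T1b", "N0"), _pred(2, "T1b", "N0")]
        metrics = evaluate(preds, gold)
        assert metrics.weighted_f1 == pytest.approx(2 / 3, abs=1e-12)
        assert metrics.weighted_precision == pytest.approx(2 / 3 * 1 + 1 / 3 * 0.5, abs=1e-12)
        assert metrics.weighted_recall == pytest.approx(metrics.accuracy_tn, abs=1e-12)

    def test_id_mismatch_lists_ids(self):
        gold = [_gold(0, "T1a", "N0"), _gold(1, "T1a", "N0")]
        preds = [_pred(0, "T1a", "N0")]
        with pytest.raises(EvaluationError, match="r1"):
            evaluate(preds, gold)

    def test_confusion_sums_to_n(self):
        rng = random.Random(0)
        gold, preds = _random_pair(rng, 37)
        metrics = evaluate(preds, gold)
        assert metrics.confusion_t.values.sum() == 37
        assert metrics.confusion_n.values.sum() == 37
        assert metrics.confusion_tn.values.sum() == 37

    def test_permutation_invariant(self):
        rng = random.Random(4)
        gold, preds = _random_pair(rng, 25)
        base = evaluate(preds, gold)
        shuffled_preds = list(preds)
        rng.shuffle(shuffled_preds)
        shuffled_gold = list(gold)
        rng.shuffle(shuffled_gold)
        other = evaluate(shuffled_preds, shuffled_gold)
        assert other.accuracy_tn == base.accuracy_tn
        assert other.weighted_f1 == pytest.approx(base.weighted_f1, abs=1e-12)

    def test_accuracy_tn_bounded(self):
        rng = random.Random(8)
        for _ in range(50):
            gold, preds = _random_pair(rng, rng.randint(1, 40))
            metrics = evaluate(preds, gold)
            assert metrics.accuracy_tn <= min(metrics.accuracy_t, metrics.accuracy_n) + 1e-12


def _random_pair(rng, n):
    gold, preds = [], []
    for i in range(n):
        gt, gn = rng.choice(T_LABELS[1:]), rng.choice(N_LABELS)
        pt = gt if rng.random() < 0.7 else rng.choice(T_LABELS)
        pn = gn if rng.random() < 0.7 else rng.choice(N_LABELS)
        gold.append(_gold(i, gt, gn))
        preds.append(_pred(i, pt, pn))
    return gold, preds


class TestAgainstSklearn:
    def test_weighted_prf_matches_sklearn(self):
        from sklearn.metrics import precision_recall_fscore_support

        rng = random.Random(17)
        for _ in range(100):
            gold, preds = _random_pair(rng, rng.randint(2, 60))
            metrics = evaluate(preds, gold)
            y_true = [f"{g.gold_t}{g.gold_n}" for g in gold]
            y_pred = [f"{p.t}{p.n}" for p in preds]
            labels = sorted(set(y_true))
            p, r, f, _ = precision_recall_fscore_support(
                y_true, y_pred, labels=labels, average="weighted", zero_division=0
            )
            assert metrics.weighted_precision == pytest.approx(p, abs=1e-9)
            assert metrics.weighted_recall == pytest.approx(r, abs=1e-9)
            assert metrics.weighted_f1 == pytest.approx(f, abs=1e-9)

    def test_confusion_matches_sklearn(self):
        from sklearn.metrics import confusion_matrix

        rng = random.Random(23)
        gold, preds = _random_pair(rng, 80)
        metrics = evaluate(preds, gold)
        y_true = [g.gold_t for g in gold]
        y_pred = [p.t for p in preds]
        ours = metrics.confusion_t.values
        theirs = confusion_matrix(y_true, y_pred, labels=list(T_LABELS))
        assert (ours == theirs).all()


class TestErrorReport:
    def test_correct_predictions_no_records(self):
        gold = [_gold(0, "T1a", "N0")]
        preds = [_pred(0, "T1a", "N0")]
        assert error_report(preds, gold) == []

    def test_sectionizer_category(self):
        gold = [_gold(0, "T1a", "N0")]
        preds = [_pred(0, "T1b", "N0", trace=["sectionizer:unsectioned_fallback"])]
        (record,) = error_report(preds, gold)
        assert record.auto_category == "sectionizer"
        assert record.axis == "T"

    def test_pet_overruling_category_is_context(self):
        gold = [_gold(0, "T1a", "N0")]
        preds = [
            _pred(
                0,
                "T1a",
                "N2",
                trace=["modality:PETCT", "context:pet_overruling:sentence_3:size_verdict=True:avid=False"],
            )
        ]
        (record,) = error_report(preds, gold)
        assert record.auto_category == "context"
        assert record.axis == "N"

    def test_unclassified_bucket(self):
        gold = [_gold(0, "T1a", "N0")]
        preds = [_pred(0, "T1a", "N1", trace=["result:T1a:N1"])]
        (record,) = error_report(preds, gold)
        assert record.auto_category == "unclassified"

    def test_frame_columns(self):
        gold = [_gold(0, "T1a", "N0")]
        preds = [_pred(0, "T4", "N3", trace=["concept:nonthoracic_node_excluded:sentence_2"])]
        df = error_report_frame(error_report(preds, gold))
        assert list(df.columns) == [
            "report_id",
            "axis",
            "predicted",
            "gold",
            "auto_category",
            "trace_excerpt",
        ]
        assert df.iloc[0]["axis"] == "both"
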