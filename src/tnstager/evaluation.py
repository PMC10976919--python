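"""Scoring of predicted (T, N) against gold labels.

Accuracies per axis and combined, support-weighted one-vs-rest
precision/recall/F1 over the joint TN labels observed in gold (zero-support
classes are excluded), confusion matrices, and a best-effort categorized
error report derived from the prediction traces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .corpus_io import LabeledReport
from .staging import N_LABELS, T_LABELS, TNResult

__all__ = ["Metrics", "ErrorRecord", "EvaluationError", "evaluate", "error_report"]


class EvaluationError(ValueError):
    pass


@dataclass
class Metrics:
    accuracy_t: float
    accuracy_n: float
    accuracy_tn: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    confusion_t: pd.DataFrame
    confusion_n: pd.DataFrame
    confusion_tn: pd.DataFrame
    n_reports: int

    def to_dict(self) -> dict:
        return {
            "n_reports": self.n_reports,
            "accuracy_t": self.accuracy_t,
            "accuracy_n": self.accuracy_n,
            "accuracy_tn": self.accuracy_tn,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary_table(self) -> str:
        """Accuracy trio, rows T / N / TN."""
        lines = [
            "Accuracy T stage   {:.2f}".format(self.accuracy_t),
            "Accuracy N stage   {:.2f}".format(self.accuracy_n),
            "Accuracy TN stage  {:.2f}".format(self.accuracy_tn),
        ]
        return "\n".join(lines)


def _confusion(gold: list[str], pred: list[str], labels: list[str]) -> pd.DataFrame:
    df = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for g, p in zip(gold, pred):
        df.loc[g, p] += 1
    df.index.name = "gold"
    df.columns.name = "predicted"
    return df


def evaluate(predictions: list[TNResult], gold: list[LabeledReport]) -> Metrics:
    """Score predictions against gold labels (matched by report_id)."""
    pred_by_id = {p.report_id: p for p in predictions}
    gold_by_id = {g.report_id: g for g in gold}
    missing = sorted(set(gold_by_id) - set(pred_by_id))
    extra = sorted(set(pred_by_id) - set(gold_by_id))
    if missing or extra:
        raise EvaluationError(
            f"report id mismatch: missing predictions for {missing}, "
            f"unmatched predictions {extra}"
        )
    ids = [g.report_id for g in gold]
    gold_t = [gold_by_id[i].gold_t for i in ids]
    gold_n = [gold_by_id[i].gold_n for i in ids]
    pred_t = [pred_by_id[i].t for i in ids]
    pred_n = [pred_by_id[i].n for i in ids]
    n = len(ids)
    if n == 0:
        raise EvaluationError("empty corpus")

    acc_t = sum(g == p for g, p in zip(gold_t, pred_t)) / n
    acc_n = sum(g == p for g, p in zip(gold_n, pred_n)) / n
    acc_tn = (
        sum(gt == pt and gn == pn for gt, pt, gn, pn in zip(gold_t, pred_t, gold_n, pred_n))
        / n
    )

    gold_tn = [f"{t}{nn}" for t, nn in zip(gold_t, gold_n)]
    pred_tn = [f"{t}{nn}" for t, nn in zip(pred_t, pred_n)]
    precision, recall, f1 = _weighted_prf(gold_tn, pred_tn)

    joint_labels = sorted(set(gold_tn) | set(pred_tn))
    return Metrics(
        accuracy_t=acc_t,
        accuracy_n=acc_n,
        accuracy_tn=acc_tn,
        weighted_precision=precision,
        weighted_recall=recall,
        weighted_f1=f1,
        confusion_t=_confusion(gold_t, pred_t, list(T_LABELS)),
        confusion_n=_confusion(gold_n, pred_n, list(N_LABELS)),
        confusion_tn=_confusion(gold_tn, pred_tn, joint_labels),
        n_reports=n,
    )


def _weighted_prf(gold: list[str], pred: list[str]) -> tuple[float, float, float]:
    """Support-weighted one-vs-rest P/R/F1 over the labels observed in gold.

    Classes predicted but absent from gold get zero support and are excluded;
    an empty prediction set for a class yields precision 0 for that class.
    """
    n = len(gold)
    classes = sorted(set(gold))
    wp = wr = wf = 0.0
    for c in classes:
        support = sum(g == c for g in gold)
        tp = sum(g == c and p == c for g, p in zip(gold, pred))
        pred_c = sum(p == c for p in pred)
        precision = tp / pred_c if pred_c else 0.0
        recall = tp / support
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        weight = support / n
        wp += weight * precision
        wr += weight * recall
        wf += weight * f1
    return wp, wr, wf


ERROR_CATEGORIES = (
    "sectionizer",
    "measurement",
    "context",
    "concept",
    "reporter_input",
    "unclassified",
)


@dataclass(frozen=True)
class ErrorRecord:
    report_id: str
    axis: str  # "T" | "N" | "both"
    predicted: str
    gold: str
    auto_category: str
    trace_excerpt: str


def _categorize(trace: list[str]) -> tuple[str, str]:
    """Best-effort error category from trace tags; honest 'unclassified'
    bucket when nothing matches."""
    priorities = (
        ("sectionizer:unsectioned_fallback", "sectionizer"),
        ("context:pet_overruling", "context"),
        ("context:", "context"),
        ("measurement:blacklist_tie", "measurement"),
        ("measurement:no_tumor_size", "measurement"),
        ("measurement:adjacent_sentence_fallback", "measurement"),
        ("concept:", "concept"),
        ("staging:unknown_station", "concept"),
        ("staging:unknown_tumor_side", "concept"),
    )
    for prefix, category in priorities:
        for line in trace:
            if line.startswith(prefix):
                return category, line
    return "unclassified", trace[-1] if trace else ""


def error_report(
    predictions: list[TNResult],
    gold: list[LabeledReport],
    traces: Optional[dict[str, list[str]]] = None,
) -> list[ErrorRecord]:
    """One record per mismatched report, auto-tagged from its trace."""
    pred_by_id = {p.report_id: p for p in predictions}
    records: list[ErrorRecord] = []
    for g in gold:
        p = pred_by_id.get(g.report_id)
        if p is None:
            raise EvaluationError(f"missing prediction for {g.report_id!r}")
        t_wrong = p.t != g.gold_t
        n_wrong = p.n != g.gold_n
        if not (t_wrong or n_wrong):
            continue
        axis = "both" if (t_wrong and n_wrong) else ("T" if t_wrong else "N")
        trace = traces.get(g.report_id, p.trace) if traces else p.trace
        category, excerpt = _categorize(trace)
        records.append(
            ErrorRecord(
                report_id=g.report_id,
                axis=axis,
                predicted=f"{p.t}{p.n}",
                gold=f"{g.gold_t}{g.gold_n}",
                auto_category=category,
                trace_excerpt=excerpt,
            )
        )
    return records


def error_report_frame(records: list[ErrorRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "report_id": r.report_id,
                "axis": r.axis,
                "predicted": r.predicted,
                "gold": r.gold,
                "auto_category": r.auto_category,
                "trace_excerpt": r.trace_excerpt,
            }
            for r in records
        ],
        columns=["report_id", "axis", "predicted", "gold", "auto_category", "trace_excerpt"],
    )
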