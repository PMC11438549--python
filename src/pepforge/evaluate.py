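"""Threshold-based binary evaluation with MCC as the headline metric.

The Matthews correlation coefficient is the primary score because it stays
informative under class imbalance: it is the Pearson correlation between
the predicted and true 0/1 label vectors, ranges over [-1, 1], and is 0 for
any trivial constant predictor. Probability scores are binarized with a
strict rule — a score must *exceed* the threshold (0.5 by default) to be
called positive; a score exactly at the threshold is negative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np


class EvaluationLeakageError(RuntimeError):
    """Raised when a test peptide appears in the model's training set."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("label vectors differ in length")
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty.

    (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)). The zero-
    denominator convention (any empty row or column of the confusion
    matrix gives 0) is the standard one and matches the metric's reading
    as a correlation: a constant predictor carries no information.
    """
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def threshold_predictions(
    scores: dict[str, float], threshold: float = 0.5
) -> dict[str, int]:
    """Binarize scores: positive iff score strictly exceeds the threshold."""
    for pid, s in scores.items():
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"score for {pid!r} outside [0,1]: {s}")
    return {pid: int(s > threshold) for pid, s in scores.items()}


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def _auroc(y_true: np.ndarray, scores: np.ndarray) -> float | None:
    if len(set(y_true.tolist())) < 2:
        return None
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y_true, scores))


@dataclass
class EvaluationReport:
    """All evaluation outputs plus provenance needed to reproduce them."""

    metrics: dict[str, float | None]
    threshold: float
    counts: ConfusionCounts
    n_test: int
    interdependence: float | None
    split_method: str
    split_params: dict
    backend: str
    guidance: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_markdown(self, path: str | Path | None = None) -> str:
        lines = [
            "# Model evaluation report",
            "",
            f"- Split method: **{self.split_method}** "
            f"(params: `{json.dumps(self.split_params)}`)",
            f"- Representation backend: `{self.backend}`",
            f"- Decision threshold: {self.threshold} "
            "(score must strictly exceed it to be called positive)",
            f"- Test peptides: {self.n_test}",
        ]
        if self.interdependence is not None:
            lines.append(
                f"- Train/test interdependence: {self.interdependence:.1%}"
            )
        lines += ["", "| Metric | Value |", "|---|---|"]
        for name, value in self.metrics.items():
            shown = "n/a" if value is None else f"{value:.4f}"
            lines.append(f"| {name.upper() if name == 'mcc' else name} | {shown} |")
        c = self.counts
        lines += [
            "",
            f"Confusion counts: TP={c.tp}, TN={c.tn}, FP={c.fp}, FN={c.fn}",
            "",
            "## Guidance",
            "",
        ]
        lines += [f"- {g}" for g in self.guidance]
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def _guidance(report_metrics: dict, interdep: float | None, method: str) -> list[str]:
    out = []
    m = report_metrics.get("mcc") or 0.0
    if m >= 0.7:
        out.append(
            "MCC >= 0.7: strong agreement between predictions and labels on "
            "held-out data."
        )
    elif m >= 0.3:
        out.append(
            "MCC between 0.3 and 0.7: the model captures real signal but "
            "errors are frequent; treat ranked predictions as enrichment, "
            "not classification."
        )
    else:
        out.append(
            "MCC below 0.3: predictions are close to uninformative on "
            "held-out data; collect more positives or revisit the "
            "representation before use."
        )
    if method == "ccpart" and (interdep == 0.0):
        out.append(
            "The test set shares no similar sequence (identity above the "
            "threshold) with training, so this estimate reflects "
            "generalization to novel peptides."
        )
    else:
        out.append(
            "No homology correction was applied to this split: test peptides "
            "may resemble training peptides, so performance on genuinely "
            "novel sequences is likely lower than reported."
        )
    return out


def evaluate_split(
    ensemble,
    test_vectors: dict[str, np.ndarray],
    test_labels: dict[str, int],
    threshold: float = 0.5,
    graph=None,
    split=None,
) -> EvaluationReport:
    """Score an ensemble on a held-out test set it was never trained on.

    Hard-fails if any test id occurs in the ensemble's recorded training
    ids — that would make the evaluation an in-sample measurement.
    When the similarity graph and split are supplied, the report embeds the
    train/test interdependence of the actual split.
    """
    overlap = set(test_vectors) & set(ensemble.train_ids)
    if overlap:
        raise EvaluationLeakageError(
            f"evaluation leakage: {len(overlap)} test ids occur in the "
            f"training set (e.g. {sorted(overlap)[:3]})"
        )
    scores = ensemble.predict(test_vectors)
    preds = threshold_predictions(scores, threshold)
    ids = sorted(scores)
    y_true = np.array([test_labels[i] for i in ids])
    y_pred = np.array([preds[i] for i in ids])
    y_score = np.array([scores[i] for i in ids])
    c = ConfusionCounts.from_labels(y_true, y_pred)
    metrics = {
        "mcc": mcc(c),
        "accuracy": _safe_div(c.tp + c.tn, c.total),
        "precision": _safe_div(c.tp, c.tp + c.fp),
        "recall": _safe_div(c.tp, c.tp + c.fn),
        "specificity": _safe_div(c.tn, c.tn + c.fp),
        "auroc": _auroc(y_true, y_score),
    }
    interdep = None
    split_method, split_params = "unknown", {}
    if graph is not None and split is not None:
        from .partition import interdependence as _interdep

        interdep = _interdep(split, graph)
        split_method = split.method
        split_params = dict(split.params)
    return EvaluationReport(
        metrics=metrics,
        threshold=threshold,
        counts=c,
        n_test=len(ids),
        interdependence=interdep,
        split_method=split_method,
        split_params=split_params,
        backend=ensemble.backend_name,
        guidance=_guidance(metrics, interdep, split_method),
    )


def render_report(
    report: EvaluationReport, path: str | Path, format: str = "json"
) -> Path:
    path = Path(path)
    if format == "json":
        report.to_json(path)
    elif format == "markdown":
        report.to_markdown(path)
    else:
        raise ValueError(f"unknown report format: {format!r}")
    return path
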