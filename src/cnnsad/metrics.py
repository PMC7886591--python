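"""Confusion-matrix metrics, AUC, stratified cross-validation, and
adjacent-stage confusion analysis.

Staging is evaluated one-vs-rest per stage: precision TP/(TP+FP), recall
TP/(TP+FN), accuracy (TP+TN)/(TP+TN+FP+FN), and rank-based AUC, macro-
averaged over the four stages. Undefined metrics (zero denominators) are
reported as NaN with a warning, never as 0. An alternative accuracy mode
``"as-printed"`` computes (TP+FN)/total instead — a formula that circulates
in some write-ups of these metrics but is not the standard definition; the
default is the standard one.

Because clinical stages are ordered, the interesting error structure is how
far a misclassified record lands from its true stage; ``adjacency_analysis``
splits each stage's errors into adjacent (distance 1) and distant ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .records import STAGES


@dataclass
class Confusion:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_predictions(
    truth: Sequence, predicted: Sequence, positive_label
) -> Confusion:
    """Count TP/FP/TN/FN for one positive label by exhaustive comparison."""
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    tp = fp = tn = fn = 0
    for t, p in zip(truth, predicted):
        t_pos, p_pos = t == positive_label, p == positive_label
        if t_pos and p_pos:
            tp += 1
        elif not t_pos and p_pos:
            fp += 1
        elif t_pos and not p_pos:
            fn += 1
        else:
            tn += 1
    return Confusion(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def metrics(conf: Confusion, mode: str = "standard") -> tuple[float, float, float]:
    """(precision, recall, accuracy) of a binary confusion matrix."""
    if conf.total == 0:
        raise ValueError("empty confusion matrix")
    pre = _safe_div(conf.tp, conf.tp + conf.fp, "precision")
    rec = _safe_div(conf.tp, conf.tp + conf.fn, "recall")
    if mode == "standard":
        acc = (conf.tp + conf.tn) / conf.total
    elif mode == "as-printed":
        acc = (conf.tp + conf.fn) / conf.total
    else:
        raise ValueError(f"unknown accuracy mode {mode!r}")
    return pre, rec, acc


def auc(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """Rank-based AUC: P(random positive outscores random negative), ties half."""
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


@dataclass
class MetricReport:
    """Cross-validated staging metrics, macro-averaged one-vs-rest."""

    precision: float
    recall: float
    accuracy: float
    auc: float
    multiclass_accuracy: float
    per_stage: dict[str, dict[str, float]]
    fold_assignments: np.ndarray
    seed: int
    per_fold: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = {s: self.per_stage[s] for s in self.per_stage}
        df = pd.DataFrame(rows).T
        df.loc["macro"] = [self.precision, self.recall, self.accuracy, self.auc]
        return df

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        obj = {
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "multiclass_accuracy": self.multiclass_accuracy,
            "per_stage": self.per_stage,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(obj, indent=2), encoding="utf-8")


def cross_validate(
    stages: Sequence[str],
    trainer: Callable[[np.ndarray, np.ndarray], tuple[Sequence[str], np.ndarray | None]],
    k: int = 10,
    seed: int = 0,
    stage_order: Sequence[str] = STAGES,
) -> MetricReport:
    """Stratified k-fold evaluation of a staging trainer.

    ``trainer(train_idx, test_idx)`` fits on the training indices and returns
    ``(predicted_stages, score_matrix)`` for the test indices, where
    ``score_matrix`` is an optional (n_test, n_stages) array of per-stage
    scores used for AUC. Metrics are computed one-vs-rest per stage within
    each fold, macro-averaged over stages, then averaged over folds.
    """
    stages = np.asarray(stages)
    n = len(stages)
    if n < k:
        raise ValueError("corpus smaller than the number of folds")
    if k == n:
        # leave-one-out: singleton folds, stratification is vacuous
        from sklearn.model_selection import KFold

        splits = KFold(n_splits=n).split(np.zeros(n))
    else:
        present, counts = np.unique(stages, return_counts=True)
        if counts.min() < k:
            lacking = present[counts.argmin()]
            raise ValueError(
                f"stage {lacking!r} has only {counts.min()} records; use k <= "
                f"{counts.min()} to stratify"
            )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = skf.split(np.zeros(n), stages)
    fold_assignments = np.full(n, -1, dtype=int)
    fold_rows = []
    per_stage_acc: dict[str, list[dict[str, float]]] = {s: [] for s in stage_order}
    for fold, (train_idx, test_idx) in enumerate(splits):
        fold_assignments[test_idx] = fold
        pred, score_matrix = trainer(train_idx, test_idx)
        pred = np.asarray(pred)
        truth = stages[test_idx]
        stage_metrics = {}
        for j, s in enumerate(stage_order):
            conf = confusion_from_predictions(truth, pred, s)
            pre, rec, acc = metrics(conf)
            row = {"precision": pre, "recall": rec, "accuracy": acc, "auc": float("nan")}
            if score_matrix is not None and 0 < (truth == s).sum() < len(truth):
                row["auc"] = auc(score_matrix[:, j], truth == s)
            per_stage_acc[s].append(row)
            stage_metrics[s] = row
        fold_rows.append(
            {
                "fold": fold,
                "multiclass_accuracy": float((pred == truth).mean()),
                **{
                    f"{m}_macro": float(
                        np.nanmean([stage_metrics[s][m] for s in stage_order])
                    )
                    for m in ("precision", "recall", "accuracy", "auc")
                },
            }
        )
    per_fold = pd.DataFrame(fold_rows)
    per_stage = {
        s: {
            m: float(np.nanmean([r[m] for r in rows]))
            for m in ("precision", "recall", "accuracy", "auc")
        }
        for s, rows in per_stage_acc.items()
    }
    return MetricReport(
        precision=float(per_fold["precision_macro"].mean()),
        recall=float(per_fold["recall_macro"].mean()),
        accuracy=float(per_fold["accuracy_macro"].mean()),
        auc=float(per_fold["auc_macro"].mean()),
        multiclass_accuracy=float(per_fold["multiclass_accuracy"].mean()),
        per_stage=per_stage,
        fold_assignments=fold_assignments,
        seed=seed,
        per_fold=per_fold,
    )


def adjacency_analysis(
    truth: Sequence[str], predicted: Sequence[str], stage_order: Sequence[str] = STAGES
) -> pd.DataFrame:
    """Split each true stage's errors by predicted-stage distance.

    Returns one row per true stage with the error count at distance 1
    (adjacent stage) and at distance >= 2, plus the adjacent fraction of all
    errors for that stage (NaN when the stage has no errors).
    """
    order = {s: i for i, s in enumerate(stage_order)}
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    for s in set(truth) | set(predicted):
        if s not in order:
            raise ValueError(f"unknown stage symbol {s!r}")
    rows = []
    for s in stage_order:
        adjacent = distant = 0
        for t, p in zip(truth, predicted):
            if t != s or p == s:
                continue
            if abs(order[p] - order[t]) == 1:
                adjacent += 1
            else:
                distant += 1
        errors = adjacent + distant
        rows.append(
            {
                "stage": s,
                "errors": errors,
                "adjacent": adjacent,
                "distant": distant,
                "adjacent_fraction": adjacent / errors if errors else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("stage")
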