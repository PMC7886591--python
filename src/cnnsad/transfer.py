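"""Label co-occurrence counting, one-vs-rest splits, and parameter transfer.

Small-sample stages cannot support training a classifier from scratch, so
their heads are initialized from the trained head of a related task. The
relatedness signal is the label co-occurrence table
``T(d_i, d_j) = sum_n E({d_i, d_j} subset y_n)`` counted over the corpus's
label sets: the source task for a target label is the label it co-occurs with
most. All transferred parameters are deep copies — fine-tuning the target
never mutates the source — and every layer is fine-tuned by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cnn
from .records import Record

logger = logging.getLogger(__name__)


@dataclass
class CooccurrenceTable:
    """Symmetric label-pair counts; the diagonal counts records per label."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts must be square over labels")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def count(self, a: str, b: str) -> int:
        return int(self.counts[self._index[a], self._index[b]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def cooccurrence(
    records: Sequence[Record], labels: Sequence[str] | None = None
) -> CooccurrenceTable:
    """Count, for every label pair, the records whose label set holds both.

    The indicator is 1 iff both labels are in the record's label set, so the
    table is symmetric, entries never exceed the corpus size, and the
    diagonal equals each label's record count. An empty corpus yields a zero
    table.
    """
    if labels is None:
        labels = sorted(set().union(*(r.labels for r in records)) if records else [])
    labels = list(labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    index = {lab: i for i, lab in enumerate(labels)}
    M = np.zeros((len(records), len(labels)), dtype=np.int64)
    for n, rec in enumerate(records):
        for lab in rec.labels:
            if lab in index:
                M[n, index[lab]] = 1
    return CooccurrenceTable(labels=labels, counts=M.T @ M)


@dataclass
class OvrSplit:
    """One-vs-rest partition of a corpus for one target label."""

    label: str
    positives: list[Record]
    negatives: list[Record]
    pos_indices: np.ndarray
    neg_indices: np.ndarray

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)


def ovr_split(records: Sequence[Record], label: str) -> OvrSplit:
    """Partition records into those carrying ``label`` and the rest."""
    pos_idx = np.array([i for i, r in enumerate(records) if label in r.labels], dtype=int)
    neg_idx = np.array([i for i, r in enumerate(records) if label not in r.labels], dtype=int)
    if len(pos_idx) == 0:
        warnings.warn(f"label {label!r} absent from every record", stacklevel=2)
    if len(neg_idx) == 0:
        warnings.warn(f"label {label!r} present in every record", stacklevel=2)
    return OvrSplit(
        label=label,
        positives=[records[i] for i in pos_idx],
        negatives=[records[i] for i in neg_idx],
        pos_indices=pos_idx,
        neg_indices=neg_idx,
    )


def select_source_label(table: CooccurrenceTable, target: str) -> str:
    """The label co-occurring most with ``target``; the transfer source.

    Ties are broken by larger positive-set size (the diagonal), then lexical
    order. If the target co-occurs with nothing, fall back to the label with
    the largest positive set (logged).
    """
    t = table._index[target]
    candidates = [lab for lab in table.labels if lab != target]
    if not candidates:
        raise ValueError("no candidate source labels")
    diag = {lab: int(table.counts[table._index[lab], table._index[lab]]) for lab in candidates}
    row = {lab: int(table.counts[t, table._index[lab]]) for lab in candidates}
    if all(v == 0 for v in row.values()):
        fallback = min(candidates, key=lambda lab: (-diag[lab], lab))
        warnings.warn(
            f"label {target!r} co-occurs with nothing; falling back to the "
            f"largest-support label {fallback!r}",
            stacklevel=2,
        )
        return fallback
    return min(candidates, key=lambda lab: (-row[lab], -diag[lab], lab))


def train_source_model(
    X: np.ndarray,
    is_positive: np.ndarray,
    *,
    dim_k: int | None = None,
    windows: Sequence[int] = (2, 3, 4),
    kernels_per_window: int = 8,
    learning_rate: float = 0.2,
    epochs: int = 15,
    batch_size: int = 32,
    seed: int = 0,
    min_positives: int = 10,
    loss_tol: float = 0.05,
    source_label: str = "source",
) -> cnn.CnnParams:
    """Train a binary one-vs-rest head on the source task.

    ``X`` is the encoded (n, L, k) corpus; ``is_positive`` marks records that
    carry the source label (class index 0 = positive). Training runs minibatch
    SGD until the epoch loss drops below ``loss_tol`` or ``epochs`` is reached.
    """
    is_positive = np.asarray(is_positive, dtype=bool)
    n_pos = int(is_positive.sum())
    if n_pos < min_positives:
        raise ValueError(
            f"source task needs >= {min_positives} positives, got {n_pos}"
        )
    params = cnn.init_params(
        dim_k=dim_k or X.shape[2],
        classes=(source_label, "rest"),
        windows=windows,
        kernels_per_window=kernels_per_window,
        seed=seed,
    )
    y = np.where(is_positive, 0, 1)
    rng = np.random.default_rng(seed)
    for _ in range(epochs):
        order = rng.permutation(len(y))
        epoch_losses = []
        for start in range(0, len(y), batch_size):
            sl = order[start : start + batch_size]
            params, loss = cnn.train_step(X[sl], y[sl], params, learning_rate)
            epoch_losses.append(loss)
        if float(np.mean(epoch_losses)) < loss_tol:
            break
    return params


def transfer_init(source: cnn.CnnParams, target_classes: Sequence[str] | None = None) -> cnn.CnnParams:
    """Deep-copy the source parameters as the target's initialization.

    The copy is isolated: fine-tuning the returned parameters never touches
    the source. Architectures must match; only the class names may be
    relabelled (same arity).
    """
    target = source.copy()
    if target_classes is not None:
        if len(target_classes) != len(source.classes):
            raise ValueError(
                f"architecture mismatch: source has {len(source.classes)} "
                f"classes, target wants {len(target_classes)}"
            )
        target.classes = tuple(target_classes)
    return target
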