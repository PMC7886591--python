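"""Skip-Gram word embeddings and record-matrix encoding.

A record is classified from its text alone, so the first stage of the model
turns each token into a k-dimensional vector and each record into the n x k
matrix X_1:n obtained by stacking the token vectors in order.

Vectors are pretrained with the Skip-Gram objective: each token w_t predicts
the tokens in its context window of radius n, maximizing
``L = sum_{d in CW(w_t)} log p(d | w_t)``. The context softmax is
approximated with negative sampling (the exact softmax is quadratic in
vocabulary size), trained by minibatch stochastic gradient ascent over
(center, context) pairs. Training is deterministic given the seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .records import Record

logger = logging.getLogger(__name__)

PAD = "<pad>"
UNK = "<unk>"


@dataclass
class SkipGramConfig:
    window_n: int = 2          # context radius
    dim_k: int = 100           # embedding dimension (8 in test fixtures)
    epochs: int = 5
    negative_samples: int = 5
    learning_rate: float = 0.05
    min_count: int = 1
    seed: int = 0
    batch_size: int = 512

    def __post_init__(self) -> None:
        if self.window_n < 1:
            raise ValueError("window_n must be >= 1")
        if self.dim_k < 2:
            raise ValueError("dim_k must be >= 2")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class EmbeddingModel:
    """Vocabulary plus one k-vector per token.

    Index 0 is the PAD symbol (all-zero vector, used for length padding and
    never trained); index 1 is the shared UNK vector, trained as an ordinary
    token and used for every out-of-vocabulary lookup.
    """

    vocabulary: list[str]
    vectors: np.ndarray
    unk_policy: str = "shared-unk"
    training_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.vocabulary) != self.vectors.shape[0]:
            raise ValueError("one vector per vocabulary token required")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors must be finite")
        self._index = {tok: i for i, tok in enumerate(self.vocabulary)}

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def token_id(self, token: str) -> int:
        return self._index.get(token, self._index[UNK])

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self.token_id(token)]


def build_vocab(
    records: Sequence[Record] | Sequence[Sequence[str]], min_count: int = 1
) -> list[str]:
    """Frequency-filtered vocabulary with reserved PAD and UNK symbols.

    Order is deterministic: PAD, UNK, then tokens by descending frequency and
    lexical order within ties.
    """
    if not records:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    freq: dict[str, int] = {}
    for rec in records:
        tokens = rec.tokens if isinstance(rec, Record) else rec
        for tok in tokens:
            freq[tok] = freq.get(tok, 0) + 1
    kept = sorted(
        (tok for tok, c in freq.items() if c >= min_count),
        key=lambda tok: (-freq[tok], tok),
    )
    if not kept:
        warnings.warn(
            f"min_count={min_count} removed every token; vocabulary holds only "
            "reserved symbols",
            stacklevel=2,
        )
    return [PAD, UNK] + kept


def _pair_arrays(
    sequences: list[np.ndarray], window_n: int
) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for seq in sequences:
        n = len(seq)
        for off in range(1, window_n + 1):
            if n <= off:
                continue
            centers.append(seq[:-off])
            contexts.append(seq[off:])
            centers.append(seq[off:])
            contexts.append(seq[:-off])
    if not centers:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def train_skipgram(
    records: Sequence[Record] | Sequence[Sequence[str]],
    config: SkipGramConfig,
) -> EmbeddingModel:
    """Pretrain Skip-Gram vectors with negative sampling on a corpus.

    Returns an :class:`EmbeddingModel` whose ``training_history`` holds the
    mean per-pair negative-sampling objective (higher is better) evaluated on
    a fixed pair sample after each epoch.
    """
    vocab = build_vocab(records, min_count=config.min_count)
    if len(vocab) < 3:  # PAD + UNK + at least one real token
        raise ValueError("vocabulary must contain at least 2 trainable tokens")
    index = {tok: i for i, tok in enumerate(vocab)}
    sequences = [
        np.array(
            [index.get(t, 1) for t in (r.tokens if isinstance(r, Record) else r)],
            dtype=np.int64,
        )
        for r in records
    ]
    centers, contexts = _pair_arrays(sequences, config.window_n)
    if centers.size == 0:
        raise ValueError("corpus has no context pairs at this window size")

    V, k = len(vocab), config.dim_k
    rng = np.random.default_rng(config.seed)
    W = rng.uniform(-0.5 / k, 0.5 / k, size=(V, k))  # input vectors
    # random (not zero) context init: avoids the early shared-drift
    # direction that negative sampling otherwise imprints on every vector
    C = rng.uniform(-0.5 / k, 0.5 / k, size=(V, k))
    W[0] = 0.0
    C[0] = 0.0

    # unigram^0.75 noise distribution over trainable tokens (skip PAD)
    counts = np.bincount(np.concatenate(sequences), minlength=V).astype(float)
    counts[0] = 0.0
    noise = counts**0.75
    noise /= noise.sum()

    n_eval = min(2000, centers.size)
    eval_idx = rng.choice(centers.size, size=n_eval, replace=False)
    eval_neg = rng.choice(V, size=(n_eval, config.negative_samples), p=noise)

    def objective() -> float:
        w = W[centers[eval_idx]]
        pos = np.log(_sigmoid(np.sum(w * C[contexts[eval_idx]], axis=1)) + 1e-12)
        neg = np.log(
            _sigmoid(-np.einsum("bk,bjk->bj", w, C[eval_neg])) + 1e-12
        ).sum(axis=1)
        return float(np.mean(pos + neg))

    history: list[float] = []
    B = config.batch_size
    K = config.negative_samples
    n_batches_total = config.epochs * int(np.ceil(centers.size / B))
    batch_no = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(centers.size)
        for start in range(0, centers.size, B):
            # linear learning-rate decay stabilizes high-frequency tokens
            lr = config.learning_rate * max(
                1.0 - batch_no / n_batches_total, 1e-4
            )
            batch_no += 1
            sl = order[start : start + B]
            ctr, ctx = centers[sl], contexts[sl]
            negs = rng.choice(V, size=(len(sl), K), p=noise)
            w = W[ctr]                                    # (B, k)
            c_pos = C[ctx]                                # (B, k)
            c_neg = C[negs]                               # (B, K, k)
            # clip scores to +-6: bounds gradients when high-frequency
            # pairs repeat many times within one accumulated batch
            s_pos = np.clip(np.sum(w * c_pos, axis=1), -6.0, 6.0)
            s_neg = np.clip(np.einsum("bk,bjk->bj", w, c_neg), -6.0, 6.0)
            g_pos = _sigmoid(s_pos) - 1.0                 # (B,)
            g_neg = _sigmoid(s_neg)                       # (B, K)
            grad_w = g_pos[:, None] * c_pos + np.einsum("bj,bjk->bk", g_neg, c_neg)
            np.add.at(W, ctr, -lr * grad_w)
            np.add.at(C, ctx, -lr * g_pos[:, None] * w)
            np.add.at(
                C,
                negs.ravel(),
                (-lr * g_neg[:, :, None] * w[:, None, :]).reshape(-1, k),
            )
            W[0] = 0.0
            C[0] = 0.0
        history.append(objective())

    return EmbeddingModel(vocabulary=vocab, vectors=W, training_history=history)


@dataclass
class RecordMatrix:
    """The n x k word-vector matrix of one record, rows in token order."""

    rows: np.ndarray
    record_id: str

    def __post_init__(self) -> None:
        if self.rows.ndim != 2:
            raise ValueError("rows must be a 2-d matrix")


def encode_record(
    record: Record, model: EmbeddingModel, max_len: int | None = None
) -> RecordMatrix:
    """Look up token vectors row by row; OOV tokens map to the UNK vector.

    Records longer than ``max_len`` are truncated (logged); shorter ones are
    padded with all-zero PAD rows so every matrix has ``max_len`` rows.
    """
    if not record.tokens:
        raise ValueError(f"record {record.record_id} has no tokens")
    ids = [model.token_id(t) for t in record.tokens]
    if max_len is not None:
        if len(ids) > max_len:
            logger.debug(
                "record %s truncated from %d to %d tokens",
                record.record_id,
                len(ids),
                max_len,
            )
            ids = ids[:max_len]
        elif len(ids) < max_len:
            ids = ids + [0] * (max_len - len(ids))
    return RecordMatrix(rows=model.vectors[np.array(ids)], record_id=record.record_id)


def encode_corpus(
    records: Sequence[Record], model: EmbeddingModel, max_len: int
) -> np.ndarray:
    """Encode many records into one (n_records, max_len, k) tensor."""
    ids = np.zeros((len(records), max_len), dtype=np.int64)
    for i, rec in enumerate(records):
        row = [model.token_id(t) for t in rec.tokens[:max_len]]
        ids[i, : len(row)] = row
    return model.vectors[ids]


# ---------------------------------------------------------------------------
# word2vec text format

def save_word2vec(model: EmbeddingModel, path: str | Path) -> None:
    """Write ``|V| k`` header then one ``token v1 .. vk`` line per token."""
    path = Path(path)
    V, k = model.vectors.shape
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{V} {k}\n")
        for tok, vec in zip(model.vocabulary, model.vectors):
            fh.write(tok + " " + " ".join(f"{v:.8g}" for v in vec) + "\n")


def load_word2vec(path: str | Path) -> EmbeddingModel:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header")
        V, k = int(header[0]), int(header[1])
        vocab: list[str] = []
        vectors = np.zeros((V, k))
        for i in range(V):
            parts = fh.readline().rstrip("\n").split(" ")
            if len(parts) != k + 1:
                raise ValueError(f"{path}, line {i + 2}: expected {k} components")
            vocab.append(parts[0])
            vectors[i] = [float(x) for x in parts[1:]]
    return EmbeddingModel(vocabulary=vocab, vectors=vectors)
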