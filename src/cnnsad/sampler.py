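"""Dynamic-sampling training loop for imbalanced one-vs-rest staging heads.

The corpus is split one-vs-rest for a target label; each record j carries a
sampling probability rho_t(j). Probabilities start per-class uniform,

    rho_1(j) = size / (2 N_pos)   for positives,
    rho_1(j) = size / (2 N_neg)   for negatives,

so each class's probabilities sum to size/2 and a draw yields, in
expectation, a balanced block of ``size`` records. Every iteration draws a
block, takes gradient steps on it, scores the whole training corpus with the
current head, and reweights:

    rho_{t+1}(j) = rho_t(j) * exp(1 - P_t(j))   for positives,
    rho_{t+1}(j) = rho_t(j) * exp(P_t(j))       for negatives,

where P_t(j) is the positive-class posterior — misclassified and
low-confidence records gain sampling mass. Each class is then renormalized
back to sum size/2 (rho <- size * rho / (2 H_class)), which keeps drawn
blocks balanced for the whole run.

When a class is smaller than size/2 its probabilities exceed 1; such a
record contributes floor(rho) deterministic copies plus one more with
probability rho - floor(rho), so the expected copy count is exactly rho and
the size/2 class balance survives. Strict Bernoulli inclusion could not
preserve it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cnn
from .transfer import OvrSplit


@dataclass
class LoopConfig:
    size: int = 64            # drawn-block size (sum of both class budgets)
    iterations: int = 30
    seed: int = 0
    learning_rate: float = 0.2
    epochs_per_iteration: int = 1
    batch_size: int = 16

    def __post_init__(self) -> None:
        if self.size < 2 or self.size % 2 != 0:
            raise ValueError("size must be an even integer >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class SamplingState:
    """Per-record sampling probabilities with their class partition."""

    rho: np.ndarray
    pos_index: np.ndarray
    neg_index: np.ndarray
    size: int
    t: int = 1
    h_pos: float = float("nan")   # pre-renormalization class sums
    h_neg: float = float("nan")

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.rho)) or np.any(self.rho < 0):
            raise ValueError("sampling probabilities must be finite and >= 0")

    @property
    def pos_sum(self) -> float:
        return float(self.rho[self.pos_index].sum())

    @property
    def neg_sum(self) -> float:
        return float(self.rho[self.neg_index].sum())


def init_probs(split: OvrSplit | tuple[np.ndarray, np.ndarray], size: int) -> SamplingState:
    """Per-class uniform initialization; each class sums to size/2 exactly."""
    if isinstance(split, OvrSplit):
        pos_idx, neg_idx = split.pos_indices, split.neg_indices
    else:
        pos_idx, neg_idx = (np.asarray(a, dtype=int) for a in split)
    n_pos, n_neg = len(pos_idx), len(neg_idx)
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both classes must be non-empty")
    merged = np.sort(np.concatenate([pos_idx, neg_idx]))
    if not np.array_equal(merged, np.arange(n_pos + n_neg)):
        raise ValueError("pos/neg indices must partition 0..N-1")
    rho = np.empty(n_pos + n_neg)
    rho[pos_idx] = size / (2.0 * n_pos)
    rho[neg_idx] = size / (2.0 * n_neg)
    return SamplingState(rho=rho, pos_index=pos_idx, neg_index=neg_idx, size=size)


def draw_balanced(state: SamplingState, rng: np.random.Generator) -> np.ndarray:
    """Draw a training block; returns record indices (with repeats).

    Classes are sampled independently. rho <= 1: Bernoulli inclusion
    (uniform draw < rho). rho > 1: floor(rho) copies plus a Bernoulli
    remainder, so the expected copy count equals rho and the expected block
    size equals ``size`` with size/2 per class.
    """
    if rng is None:
        raise ValueError("an explicit random generator is required")
    floor = np.floor(state.rho)
    extra = (rng.random(len(state.rho)) < (state.rho - floor)).astype(np.int64)
    counts = floor.astype(np.int64) + extra
    return np.repeat(np.arange(len(state.rho)), counts)


def update_probs(state: SamplingState, posteriors: np.ndarray) -> SamplingState:
    """Confidence-driven reweighting followed by class renormalization.

    ``posteriors`` holds each record's positive-class probability P in
    [0, 1]. Positives are multiplied by exp(1 - P), negatives by exp(P), then
    each class is rescaled to sum size/2. Among positives, lower P (worse
    classification) yields weakly larger updated rho.
    """
    P = np.asarray(posteriors, dtype=float)
    if P.shape != state.rho.shape:
        raise ValueError("one posterior per record required")
    if np.any(P < 0) or np.any(P > 1):
        raise ValueError("posteriors must lie in [0, 1]")
    rho = state.rho.copy()
    rho[state.pos_index] *= np.exp(1.0 - P[state.pos_index])
    rho[state.neg_index] *= np.exp(P[state.neg_index])
    h_pos = float(rho[state.pos_index].sum())
    h_neg = float(rho[state.neg_index].sum())
    rho[state.pos_index] *= state.size / (2.0 * h_pos)
    rho[state.neg_index] *= state.size / (2.0 * h_neg)
    if np.any(~np.isfinite(rho)):
        raise RuntimeError(
            f"non-finite sampling probabilities at t={state.t}; "
            f"h_pos={h_pos}, h_neg={h_neg}"
        )
    return replace(state, rho=rho, t=state.t + 1, h_pos=h_pos, h_neg=h_neg)


def run_loop(
    X: np.ndarray,
    is_positive: np.ndarray,
    config: LoopConfig,
    params: cnn.CnnParams,
) -> tuple[cnn.CnnParams, list[dict], SamplingState]:
    """Full dynamic-sampling training of one binary head.

    ``X`` is the encoded (n, L, k) training corpus; ``is_positive`` marks the
    one-vs-rest positives. Each iteration: draw a block, take
    ``epochs_per_iteration`` shuffled passes of SGD over it, score every
    record, reweight, renormalize. Returns the trained head, per-iteration
    diagnostics, and the final sampling state. Fully reproducible per seed.
    """
    is_positive = np.asarray(is_positive, dtype=bool)
    if len(params.classes) != 2:
        raise ValueError("run_loop trains binary one-vs-rest heads")
    pos_idx = np.flatnonzero(is_positive)
    neg_idx = np.flatnonzero(~is_positive)
    state = init_probs((pos_idx, neg_idx), config.size)
    rng = np.random.default_rng(config.seed)
    y = np.where(is_positive, 0, 1)
    # the scoring corpus is fixed: build its window tensors once
    wins = cnn.precompute_windows(X, params.window_sizes)
    history: list[dict] = []
    for it in range(1, config.iterations + 1):
        drawn = draw_balanced(state, rng)
        if len(drawn) == 0:  # vanishingly unlikely; redraw once
            drawn = draw_balanced(state, rng)
        for _ in range(config.epochs_per_iteration):
            order = rng.permutation(len(drawn))
            for start in range(0, len(drawn), config.batch_size):
                sl = drawn[order[start : start + config.batch_size]]
                params, _ = cnn.train_step(X[sl], y[sl], params, config.learning_rate)
        P = cnn.batch_positive_prob(X, params, wins)
        state = update_probs(state, P)
        history.append(
            {
                "iteration": it,
                "pos_rho_sum": state.pos_sum,
                "neg_rho_sum": state.neg_sum,
                "mean_P_pos": float(P[pos_idx].mean()),
                "mean_P_neg": float(P[neg_idx].mean()),
                "drawn_total": int(len(drawn)),
                "drawn_pos": int(is_positive[drawn].sum()),
            }
        )
    return params, history, state


def history_to_tsv(history: Sequence[dict], path: str | Path) -> None:
    """Export per-iteration loop diagnostics as TSV."""
    pd.DataFrame(list(history)).to_csv(path, sep="\t", index=False)
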