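"""End-to-end composition: generate -> embed -> (transfer) -> train -> evaluate.

The staging model is an ensemble of four one-vs-rest convolutional heads,
each trained with the dynamic-sampling loop; records are encoded once with
Skip-Gram vectors pretrained on the corpus text (unsupervised, so no label
leakage into cross-validation folds). ``cross_validate_staging`` is the
package's headline evaluation: stratified k-fold cross-validation of the
full train-and-ensemble procedure.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import cnn, embedding, metrics, sampler, transfer
from .records import (
    STAGES,
    GeneratorConfig,
    Record,
    generate_corpus,
    read_jsonl,
    write_jsonl,
)

logger = logging.getLogger(__name__)

#: generous cap: default records carry at most ~53 tokens
DEFAULT_MAX_LEN = 56


@dataclass
class CnnConfig:
    windows: tuple[int, ...] = (2, 3, 4)
    kernels_per_window: int = 8
    max_len: int = DEFAULT_MAX_LEN


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; the seed is mandatory."""

    seed: int
    out_dir: str = "cnnsad_run"
    generator: GeneratorConfig = field(default_factory=lambda: GeneratorConfig(n_records=1000))
    skipgram: embedding.SkipGramConfig = field(
        default_factory=lambda: embedding.SkipGramConfig(dim_k=8, window_n=2)
    )
    cnn: CnnConfig = field(default_factory=CnnConfig)
    loop: sampler.LoopConfig = field(default_factory=sampler.LoopConfig)
    use_transfer: bool = False
    cv_folds: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        kwargs = dict(raw)
        if "generator" in kwargs:
            g = dict(kwargs["generator"])
            for key in ("stage_weights", "tokens_per_record"):
                if key in g:
                    g[key] = tuple(g[key])
            kwargs["generator"] = GeneratorConfig(**g)
        if "skipgram" in kwargs:
            kwargs["skipgram"] = embedding.SkipGramConfig(**kwargs["skipgram"])
        if "cnn" in kwargs:
            c = dict(kwargs["cnn"])
            if "windows" in c:
                c["windows"] = tuple(c["windows"])
            kwargs["cnn"] = CnnConfig(**c)
        if "loop" in kwargs:
            kwargs["loop"] = sampler.LoopConfig(**kwargs["loop"])
        return cls(**kwargs)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def pretrain_embeddings(
    records: Sequence[Record], config: embedding.SkipGramConfig
) -> embedding.EmbeddingModel:
    return embedding.train_skipgram(records, config)


def train_stage_head(
    X: np.ndarray,
    is_positive: np.ndarray,
    loop: sampler.LoopConfig,
    *,
    stage_label: str,
    init: cnn.CnnParams | None = None,
    cnn_config: CnnConfig | None = None,
    seed: int | None = None,
) -> tuple[cnn.CnnParams, list[dict]]:
    """Train one one-vs-rest head with the dynamic-sampling loop."""
    cfg = cnn_config or CnnConfig()
    if init is None:
        init = cnn.init_params(
            dim_k=X.shape[2],
            classes=(stage_label, "rest"),
            windows=cfg.windows,
            kernels_per_window=cfg.kernels_per_window,
            seed=loop.seed if seed is None else seed,
        )
    loop_cfg = sampler.LoopConfig(**{**asdict(loop), "seed": loop.seed if seed is None else seed})
    params, history, _state = sampler.run_loop(X, is_positive, loop_cfg, init)
    return params, history


def train_staging_ensemble(
    records: Sequence[Record],
    X: np.ndarray,
    loop: sampler.LoopConfig,
    cnn_config: CnnConfig | None = None,
    use_transfer: bool = False,
    seed: int = 0,
) -> dict[str, cnn.CnnParams]:
    """Train all four one-vs-rest stage heads on an encoded corpus.

    With ``use_transfer``, each stage head is initialized from a head trained
    on the label it co-occurs with most (auxiliary findings included),
    instead of random initialization.
    """
    stages = np.array([r.stage for r in records])
    heads: dict[str, cnn.CnnParams] = {}
    table = transfer.cooccurrence(records) if use_transfer else None
    source_cache: dict[str, cnn.CnnParams] = {}
    for j, s in enumerate(STAGES):
        head_seed = seed * 16 + j
        init = None
        if use_transfer:
            source = transfer.select_source_label(table, s)
            if source not in source_cache:
                is_src = np.array([source in r.labels for r in records])
                source_cache[source] = transfer.train_source_model(
                    X,
                    is_src,
                    windows=(cnn_config or CnnConfig()).windows,
                    kernels_per_window=(cnn_config or CnnConfig()).kernels_per_window,
                    seed=head_seed,
                    source_label=source,
                )
            init = transfer.transfer_init(source_cache[source], (s, "rest"))
            logger.info("stage %s head initialized from source label %r", s, source)
        heads[s], _ = train_stage_head(
            X,
            stages == s,
            loop,
            stage_label=s,
            init=init,
            cnn_config=cnn_config,
            seed=head_seed,
        )
    return heads


def predict_stages(
    X: np.ndarray, heads: dict[str, cnn.CnnParams]
) -> tuple[np.ndarray, np.ndarray]:
    """(predicted stage labels, per-stage normalized posterior matrix)."""
    probs = np.column_stack(
        [cnn.batch_positive_prob(X, heads[s]) for s in STAGES]
    )
    probs = probs / probs.sum(axis=1, keepdims=True)
    pred = np.array([STAGES[i] for i in probs.argmax(axis=1)])
    return pred, probs


def cross_validate_staging(
    records: Sequence[Record],
    emb: embedding.EmbeddingModel,
    loop: sampler.LoopConfig,
    cnn_config: CnnConfig | None = None,
    k: int = 10,
    seed: int = 0,
    use_transfer: bool = False,
) -> metrics.MetricReport:
    """Stratified k-fold cross-validation of the full staging procedure."""
    cfg = cnn_config or CnnConfig()
    X = embedding.encode_corpus(records, emb, cfg.max_len).astype(np.float32)
    stages = [r.stage for r in records]

    def trainer(train_idx: np.ndarray, test_idx: np.ndarray):
        heads = train_staging_ensemble(
            [records[i] for i in train_idx],
            X[train_idx],
            loop,
            cnn_config=cfg,
            use_transfer=use_transfer,
            seed=seed,
        )
        pred, probs = predict_stages(X[test_idx], heads)
        return pred, probs

    return metrics.cross_validate(stages, trainer, k=k, seed=seed)


def run_end_to_end(config: RunConfig) -> dict:
    """The five-phase flow: generate, embed, train per stage, evaluate.

    Writes every artifact (corpus, embeddings, four head checkpoints,
    co-occurrence table, metric report, provenance) under ``config.out_dir``
    and returns a bundle of paths plus the metric report. Deterministic for
    a fixed config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(
        logging.Formatter("%(asctime)s [%(name)s] %(levelname)s %(message)s")
    )
    root = logging.getLogger("cnnsad")
    root.addHandler(handler)
    t0 = time.time()
    try:
        stage = "generate"
        logger.info("[%s] n=%d seed=%d", stage, config.generator.n_records, config.seed)
        gen = GeneratorConfig(**{**asdict(config.generator), "seed": config.seed})
        records = generate_corpus(gen)
        corpus_path = out / "corpus.jsonl"
        write_jsonl(records, corpus_path)

        stage = "embed"
        logger.info("[%s] dim_k=%d", stage, config.skipgram.dim_k)
        sg = embedding.SkipGramConfig(
            **{**asdict(config.skipgram), "seed": config.seed}
        )
        emb = pretrain_embeddings(records, sg)
        emb_path = out / "embeddings.txt"
        embedding.save_word2vec(emb, emb_path)

        stage = "cooccurrence"
        table = transfer.cooccurrence(records)
        table.to_tsv(out / "cooccurrence.tsv")

        stage = "train"
        X = embedding.encode_corpus(records, emb, config.cnn.max_len).astype(np.float32)
        heads = train_staging_ensemble(
            records,
            X,
            config.loop,
            cnn_config=config.cnn,
            use_transfer=config.use_transfer,
            seed=config.seed,
        )
        ckpt_paths = {}
        for s, params in heads.items():
            p = out / f"head_{s}.json"
            cnn.save_checkpoint(
                params, p, embedding_path=str(emb_path), seed=config.seed
            )
            ckpt_paths[s] = str(p)

        stage = "evaluate"
        report = cross_validate_staging(
            records,
            emb,
            config.loop,
            cnn_config=config.cnn,
            k=config.cv_folds,
            seed=config.seed,
            use_transfer=config.use_transfer,
        )
        report.to_json(out / "metrics.json")
        report.to_frame().to_csv(out / "metrics.tsv", sep="\t")

        provenance = {
            "config_digest": config.digest(),
            "seed": config.seed,
            "format_version": cnn.CHECKPOINT_FORMAT_VERSION,
            "elapsed_s": round(time.time() - t0, 2),
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    except Exception as exc:
        logger.error("pipeline failed in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed in stage {stage!r}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return {
        "corpus": str(corpus_path),
        "embeddings": str(emb_path),
        "checkpoints": ckpt_paths,
        "report": report,
        "provenance": provenance,
    }


def diagnose(
    records: Sequence[Record],
    emb: embedding.EmbeddingModel,
    heads: dict[str, cnn.CnnParams],
    max_len: int = DEFAULT_MAX_LEN,
):
    """Per-record staging decisions (posterior, F(x), stage) as a DataFrame."""
    import pandas as pd

    X = embedding.encode_corpus(records, emb, max_len).astype(np.float32)
    decisions = cnn.ensemble_decisions(X, heads)
    rows = []
    for rec, d in zip(records, decisions):
        row = {"record_id": rec.record_id, "f_value": d.f_value, "stage": d.stage}
        row.update({f"p_{s}": float(p) for s, p in zip(STAGES, d.posterior)})
        rows.append(row)
    return pd.DataFrame(rows)
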