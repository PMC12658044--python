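"""Shared fixtures: a small synthetic study and fully trained decoder runs.

The trained runs are expensive (minutes), so they are session-scoped and
shared by the parameter-recovery, repetition-averaging and
transformer-ablation tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from neuroword import (
    SyntheticConfig, TrainConfig, epoch_events, preprocess_recording,
    simulate_study, split_sentences, train,
)
from neuroword.containers import concat_epochs
from neuroword.evaluation import (balanced_topk, build_vocabulary,
                                  evaluate_predictions)
from neuroword.model import BrainDecoder, ModelConfig, sort_by_sentence


def make_study(seed: int = 7, **overrides):
    """Small but decodable synthetic study; returns everything downstream."""
    params = dict(vocab_size=60, n_sentences=60, sentence_length_range=(4, 8),
                  n_subjects=2, n_sensors=16, embedding_dim=24, snr=5.0,
                  seed=seed)
    params.update(overrides)
    cfg = SyntheticConfig(**params)
    lexicon, corpus, fm, table, recordings = simulate_study(cfg)
    return cfg, lexicon, corpus, fm, table, recordings


def epochs_and_splits(corpus, recordings):
    """Preprocess + epoch all subjects and label epochs by sentence split."""
    sets = [epoch_events(preprocess_recording(rec), ev)
            for rec, ev in recordings]
    epochs = sort_by_sentence(concat_epochs(sets))
    texts = dict(zip(corpus.sentence_ids, corpus.texts()))
    assignment = split_sentences(list(texts.values()))
    labels = np.array([assignment[texts[s]] for s in epochs.sentence_ids])
    return epochs, labels


@pytest.fixture(scope="session")
def small_study():
    cfg, lexicon, corpus, fm, table, recordings = make_study()
    epochs, labels = epochs_and_splits(corpus, recordings)
    return {"config": cfg, "lexicon": lexicon, "corpus": corpus,
            "forward_model": fm, "embeddings": table,
            "recordings": recordings, "epochs": epochs, "labels": labels}


# -- full training runs (parameter recovery conditions) -----------------------

RECOVERY_SEEDS = (1, 2, 3)


@dataclass
class TrainedRun:
    seed: int
    accuracy: float              # balanced top-10 on test, 2 transformer layers
    chance: float
    vocab_size: int
    history_loss: list
    test_batch: object           # PredictionBatch on held-out sentences
    vocab: object
    embeddings: object


def _train_one(seed: int, transformer_layers: int):
    cfg = SyntheticConfig(vocab_size=100, n_sentences=210,
                          sentence_length_range=(5, 10), n_subjects=2,
                          n_sensors=32, embedding_dim=64, snr=5.0, seed=seed)
    _, corpus, _, table, recordings = simulate_study(cfg)
    epochs, labels = epochs_and_splits(corpus, recordings)
    tr = epochs.select(labels == "train")
    va = epochs.select(labels == "val")
    te = epochs.select(labels == "test")
    mc = ModelConfig(n_sensors=32, n_subjects=2, model_dim=64,
                     latent_channels=64, conv_blocks=2,
                     transformer_layers=transformer_layers,
                     transformer_heads=8, spatial_harmonics=6)
    model = BrainDecoder(mc, recordings[0][0].sensor_positions,
                         ["sub-01", "sub-02"], seed=seed)
    tc = TrainConfig(lr=3e-3, batch_sentences=32, max_epochs=12,
                     cosine_decay_epochs=12, patience=6, seed=seed)
    history = train(model, tr, va, table, tc)
    vocab = build_vocabulary(tr.words, table, size=250)
    batch = model.predict(te)
    acc = balanced_topk(evaluate_predictions(batch, vocab, k=10))
    return acc, vocab, batch, table, history


@pytest.fixture(scope="session")
def trained_runs() -> list[TrainedRun]:
    """Three independent simulate+train+evaluate runs (and their ablations)."""
    runs = []
    for seed in RECOVERY_SEEDS:
        acc, vocab, batch, table, history = _train_one(seed, transformer_layers=2)
        runs.append(TrainedRun(
            seed=seed, accuracy=acc, chance=10.0 / len(vocab),
            vocab_size=len(vocab), history_loss=history.epoch_loss,
            test_batch=batch, vocab=vocab, embeddings=table))
    return runs
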