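"""Optimization loop: AdamW, half-cosine learning-rate decay, early stopping.

A batch is a set of sentences (the transformer consumes whole sentences);
the contrastive loss is computed jointly over all words of the batch.
After every epoch the balanced top-10 accuracy on the validation split is
evaluated (against the most-frequent-words vocabulary built from the train
split); the best checkpoint is kept and training stops after ``patience``
epochs without improvement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Parameter, no_grad
from .containers import EpochSet
from .embeddings import EmbeddingTable
from .evaluation import balanced_topk, build_vocabulary, evaluate_predictions
from .losses import ContrastiveParams, contrastive_loss
from .model import BrainDecoder, sentence_groups, sort_by_sentence

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    lr: float = 1e-4
    batch_sentences: int = 64
    max_epochs: int = 50
    cosine_decay_epochs: int = 50
    patience: int = 10
    loss: str = "dsiglip"
    grad_clip: float = 1.0
    weight_decay: float = 0.01
    eval_vocab_size: int = 250
    eval_topk: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def cosine_lr(base_lr: float, epoch: int, decay_epochs: int) -> float:
    """Half-cosine decay from base_lr to 0 over ``decay_epochs``, then floor."""
    if epoch >= decay_epochs:
        return 0.0
    return 0.5 * (1.0 + np.cos(np.pi * epoch / decay_epochs)) * base_lr


class AdamW:
    """Decoupled weight-decay Adam over a list of Parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            update = (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def clip_global_norm(params: list[Parameter], max_norm: float) -> float:
    total = np.sqrt(sum(float((p.grad**2).sum())
                        for p in params if p.grad is not None))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale  # no in-place: grads may be shared
    return float(total)


@dataclass
class TrainHistory:
    epoch_loss: list[float] = field(default_factory=list)
    val_metric: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val: float = -np.inf


def _snapshot(params: list[Parameter]) -> list[np.ndarray]:
    return [p.data.copy() for p in params]


def _restore(params: list[Parameter], snap: list[np.ndarray]) -> None:
    for p, s in zip(params, snap):
        p.data = s.copy()


def validation_metric(model: BrainDecoder, val_epochs: EpochSet, vocab,
                      k: int = 10) -> float:
    with no_grad():
        batch = model.forward(val_epochs, train=False)
    return balanced_topk(evaluate_predictions(batch, vocab, k=k))


def train(model: BrainDecoder, train_epochs: EpochSet, val_epochs: EpochSet,
          embeddings: EmbeddingTable, cfg: TrainConfig,
          loss_params: ContrastiveParams | None = None,
          check_disjoint: bool = True) -> TrainHistory:
    """Fit the decoder with a contrastive objective; returns the history.

    The model is left holding the *best* validation checkpoint.  Splits must
    be sentence-disjoint: this is asserted up front.
    """
    if not len(val_epochs):
        raise ValueError("empty validation split: early stopping undefined")
    if check_disjoint:
        tr = set(map(str, train_epochs.sentence_ids))
        va = set(map(str, val_epochs.sentence_ids))
        if tr & va:
            raise ValueError(f"train/val share {len(tr & va)} sentences")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7e]))
    train_epochs = sort_by_sentence(train_epochs)
    val_epochs = sort_by_sentence(val_epochs)
    slices = sentence_groups(train_epochs)
    loss_params = loss_params or ContrastiveParams.init()
    params = model.parameters() + loss_params.parameters()
    opt = AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    vocab = build_vocabulary(train_epochs.words, embeddings,
                             size=cfg.eval_vocab_size)

    history = TrainHistory()
    best_snap = _snapshot(params)
    bad_epochs = 0
    for epoch in range(cfg.max_epochs):
        opt.lr = cosine_lr(cfg.lr, epoch, cfg.cosine_decay_epochs)
        order = rng.permutation(len(slices))
        losses = []
        for start in range(0, len(order), cfg.batch_sentences):
            batch_slices = [slices[i] for i in order[start:start + cfg.batch_sentences]]
            # group sentences of one subject contiguously within the batch
            # (lets the subject layer run one GEMM per subject)
            batch_slices.sort(key=lambda se: train_epochs.subject_ids[se[0]])
            idx = np.concatenate([np.arange(s, e) for s, e in batch_slices])
            sub = train_epochs.select(idx)
            targets = np.stack([embeddings[w] for w in sub.words]).astype(
                model._np_dtype)
            opt.zero_grad()
            preds = model.forward(sub, train=True, rng=rng, return_tensor=True)
            loss = contrastive_loss(cfg.loss, preds, targets, loss_params,
                                    sub.words)
            loss.backward()
            clip_global_norm(params, cfg.grad_clip)
            opt.step()
            losses.append(loss.item())
        val = validation_metric(model, val_epochs, vocab, k=cfg.eval_topk)
        history.epoch_loss.append(float(np.mean(losses)))
        history.val_metric.append(val)
        history.lr.append(opt.lr)
        logger.info("epoch=%d loss=%.4f val_top%d=%.4f lr=%.2e",
                    epoch, history.epoch_loss[-1], cfg.eval_topk, val, opt.lr)
        if val > history.best_val:
            history.best_val = val
            history.best_epoch = epoch
            best_snap = _snapshot(params)
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                logger.info("early stop at epoch %d (best %d)", epoch,
                            history.best_epoch)
                break
    _restore(params, best_snap)
    return history
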