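"""Contrastive objectives mapping predicted embeddings onto targets.

Given a batch of N predictions and their N target word embeddings, the
similarity matrix holds the cosine between every (prediction, target) pair.
Three losses are provided:

* ``clip_loss`` — softmax over targets for each prediction (one-directional
  multiclass form), scaled by a learnable temperature t = exp(t').
* ``siglip_loss`` — N^2 independent binary problems through a sigmoid with
  learnable temperature and bias, so no batch-wide normalization is needed.
* D-SigLIP — the deduplicated variant: when a word repeats inside a batch,
  only its first occurrence is kept in the loss (rows and columns of the
  repeats are excluded), so genuine (brain, word) matches are never pushed
  apart as false negatives.

All functions accept numpy arrays or autodiff Tensors and return a scalar
Tensor, so the same code path serves training and testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Parameter, Tensor

__all__ = ["ContrastiveParams", "LabelMatrix", "cosine_matrix", "clip_loss",
           "siglip_loss", "dsiglip_labels", "dsiglip_loss", "contrastive_loss",
           "LOSS_CHOICES"]

LOSS_CHOICES = ("clip", "siglip", "dsiglip")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


@dataclass
class ContrastiveParams:
    """Learnable temperature (t = exp(t')) and bias of the contrastive head.

    Defaults follow the sigmoid-contrastive convention: t' = log 10, and a
    bias such that negative pairs start near-satisfied (their initial logit
    z(t*0 - b) = +10, i.e. almost zero loss), which prevents the wall of
    negatives from swamping the positives early in training.  In this loss's
    sign parameterization, logit = z(t*sim - b), that means b = +10.
    """

    t_raw: Parameter
    b: Parameter

    @classmethod
    def init(cls, t_raw: float = float(np.log(10.0)), b: float = 10.0):
        return cls(t_raw=Parameter(t_raw, name="loss.t_raw"),
                   b=Parameter(b, name="loss.b"))

    @property
    def temperature(self) -> float:
        return float(np.exp(self.t_raw.data))

    def parameters(self) -> list[Parameter]:
        return [self.t_raw, self.b]


@dataclass
class LabelMatrix:
    """Pair labels z in {+1,-1} plus the kept-item mask for deduplication.

    ``drop`` controls how discarded repeats leave the loss: with
    ``rows_and_columns`` (default) a repeat contributes neither as a
    prediction nor as a target; with ``rows`` its column still serves as a
    negative target for the kept items.
    """

    z: np.ndarray           # (N, N)
    keep_mask: np.ndarray   # (N,) bool
    drop: str = "rows_and_columns"

    @property
    def n_kept(self) -> int:
        return int(self.keep_mask.sum())

    def pair_mask(self) -> np.ndarray:
        if self.drop == "rows":
            return np.broadcast_to(self.keep_mask[:, None],
                                   self.z.shape).astype(float)
        if self.drop == "rows_and_columns":
            return np.outer(self.keep_mask, self.keep_mask).astype(float)
        raise ValueError("drop must be 'rows' or 'rows_and_columns'")


def cosine_matrix(preds, targets) -> Tensor:
    """Pairwise cosine similarities: sim[i, j] = cos(pred_i, target_j)."""
    preds = _as_tensor(preds)
    targets = _as_tensor(targets)
    pn = (preds * preds).sum(axis=1, keepdims=True) ** 0.5
    tn = (targets * targets).sum(axis=1, keepdims=True) ** 0.5
    if np.any(pn.data <= 0) or np.any(tn.data <= 0):
        raise ValueError("zero-norm row in cosine_matrix input")
    return (preds / pn) @ (targets / tn).transpose(1, 0)


def clip_loss(sim, params: ContrastiveParams) -> Tensor:
    """One-directional InfoNCE: softmax over target columns for each row.

    L = -(1/N) sum_i log( exp(t sim_ii) / sum_j exp(t sim_ij) ).
    """
    sim = _as_tensor(sim)
    n = sim.shape[0]
    t = params.t_raw.exp()
    logits = sim * t
    logp = logits.log_softmax(axis=1)
    diag = logp[np.arange(n), np.arange(n)]
    return -diag.mean()


def siglip_loss(sim, params: ContrastiveParams,
                labels: LabelMatrix | None = None) -> Tensor:
    """Sigmoid contrastive loss over N^2 binary pair-classification problems.

    L = -(1/N_kept) sum_{i,j kept} log sigma( z_ij (t sim_ij - b) ).
    Without labels, z is +1 on the diagonal and -1 elsewhere and all items
    are kept.
    """
    sim = _as_tensor(sim)
    n = sim.shape[0]
    if labels is None:
        z = -np.ones((n, n))
        np.fill_diagonal(z, 1.0)
        keep = np.ones(n, dtype=bool)
    else:
        if labels.z.shape != (n, n):
            raise ValueError("label matrix shape mismatch")
        z, keep = labels.z, labels.keep_mask
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise ValueError("all batch items masked out: loss undefined")
    t = params.t_raw.exp()
    if labels is None:
        pair_mask = np.ones((n, n), dtype=sim.data.dtype)
    else:
        pair_mask = labels.pair_mask().astype(sim.data.dtype)
    logits = (sim * t - params.b) * Tensor(z.astype(sim.data.dtype))
    return -(logits.log_sigmoid() * Tensor(pair_mask)).sum() / n_kept


def dsiglip_labels(batch_words: list[str],
                   drop: str = "rows_and_columns") -> LabelMatrix:
    """Deduplicated labels: keep only the first occurrence of each word.

    By default rows *and* columns of discarded repeats are excluded from the
    loss (``drop="rows"`` keeps their columns as negative targets); on kept
    items z is +1 on the diagonal and -1 off it.
    """
    n = len(batch_words)
    seen: set[str] = set()
    keep = np.zeros(n, dtype=bool)
    for i, w in enumerate(batch_words):
        if w not in seen:
            seen.add(w)
            keep[i] = True
    z = -np.ones((n, n))
    np.fill_diagonal(z, 1.0)
    return LabelMatrix(z=z, keep_mask=keep, drop=drop)


def dsiglip_loss(sim, params: ContrastiveParams, batch_words: list[str],
                 drop: str = "rows_and_columns") -> Tensor:
    """SigLIP with in-batch word repeats dropped from the loss."""
    return siglip_loss(sim, params, dsiglip_labels(batch_words, drop=drop))


def contrastive_loss(choice: str, preds, targets, params: ContrastiveParams,
                     batch_words: list[str]) -> Tensor:
    """Dispatch on the configured loss name ('clip'|'siglip'|'dsiglip')."""
    sim = cosine_matrix(preds, targets)
    if choice == "clip":
        return clip_loss(sim, params)
    if choice == "siglip":
        return siglip_loss(sim, params)
    if choice == "dsiglip":
        return dsiglip_loss(sim, params, batch_words)
    raise ValueError(f"unknown loss {choice!r}; choose from {LOSS_CHOICES}")
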