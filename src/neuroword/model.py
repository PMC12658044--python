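"""Brain-to-embedding decoding architectures.

The deep decoder maps a 3-s multi-sensor window of one word to a predicted
word embedding, then lets a sentence-level transformer refine every word of
the sentence jointly:

    spatial attention over sensors -> subject-specific linear layer ->
    dilated residual conv stack -> attention pooling over time  (per word)
    -> pre-norm transformer with rotary position encoding       (per sentence)

The documented default configuration is the full-scale one (model dim 1024,
16 transformer layers, 16 heads); compact configurations expose the same
architecture at desk scale.

A per-time-point ridge regression baseline (scikit-learn RidgeCV, one
regularization per embedding dimension) is included for sanity checks and
latency profiles.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._autodiff import Parameter, Tensor, concat, no_grad, stack
from .containers import EpochSet

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``model_dim`` must equal the target embedding dimension; heads must
    divide it.  Defaults document the full-scale network; tests and the
    bundled examples use compact values.
    """

    n_sensors: int
    n_subjects: int
    model_dim: int = 1024
    latent_channels: int = 256
    conv_blocks: int = 5
    transformer_layers: int = 16
    transformer_heads: int = 16
    attention_dropout: float = 0.1
    spatial_harmonics: int = 8
    dtype: str = "float32"  # compute precision of the network

    def __post_init__(self) -> None:
        if self.transformer_layers > 0 and self.model_dim % self.transformer_heads:
            raise ValueError("heads must divide model_dim")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class PredictionBatch:
    """Predicted embeddings with per-trial metadata, row-aligned to inputs."""

    y_hat: np.ndarray
    meta: pd.DataFrame  # columns: word, sentence_id, subject, position

    def __len__(self) -> int:
        return self.y_hat.shape[0]


def _fourier_features(positions: np.ndarray, k: int) -> np.ndarray:
    """2-D harmonic basis evaluated at sensor positions: (n, 2*k*k)."""
    kx, ky = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    freqs = np.stack([kx.ravel(), ky.ravel()], axis=1)  # (k*k, 2)
    phase = 2.0 * np.pi * positions @ freqs.T  # (n, k*k)
    return np.concatenate([np.cos(phase), np.sin(phase)], axis=1)


class SpatialAttention:
    """Softmax-over-sensors mixing with logits smooth in sensor position.

    Each latent channel carries a learned function of 2-D position (harmonic
    basis); its softmax across sensors gives time-independent mixing weights,
    so sensors at identical positions with identical series are
    interchangeable.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        f = 2 * cfg.spatial_harmonics**2
        self.W = Parameter(rng.standard_normal((f, cfg.latent_channels)) / np.sqrt(f),
                           name="spatial.W")

    def __call__(self, x: Tensor, positions: np.ndarray, k: int) -> Tensor:
        feats = _fourier_features(positions, k).astype(self.W.data.dtype)  # (n, f)
        logits = Tensor(feats) @ self.W  # (n, D)
        weights = logits.softmax(axis=0)  # softmax across sensors
        return x @ weights  # (B, t, n) @ (n, D)

    def parameters(self):
        return [self.W]


class SubjectLayer:
    """Per-subject D x D linear map, identity at initialization."""

    def __init__(self, cfg: ModelConfig):
        eye = np.broadcast_to(np.eye(cfg.latent_channels),
                              (cfg.n_subjects,) + (cfg.latent_channels,) * 2)
        self.M = Parameter(eye.copy(), name="subject.M")
        self.n_subjects = cfg.n_subjects

    def __call__(self, h: Tensor, subject_idx: np.ndarray) -> Tensor:
        if subject_idx.min() < 0 or subject_idx.max() >= self.n_subjects:
            raise KeyError(f"unknown subject index in {np.unique(subject_idx)}; "
                           "new subjects require fine-tuning a fresh row")
        runs = _runs(subject_idx)
        if len(runs) == len(np.unique(subject_idx)):
            # subject-contiguous batch: one flattened GEMM per subject
            parts = [h[s:e] @ self.M[int(sub)] for s, e, sub in runs]
            return parts[0] if len(parts) == 1 else concat(parts, axis=0)
        return h @ self.M[subject_idx]  # (B,t,D) @ (B,D,D) gather fallback

    def parameters(self):
        return [self.M]


def _runs(values: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous (start, end, value) runs of a 1-D array."""
    runs = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            runs.append((start, i, values[start]))
            start = i
    return runs


def _shift(x: Tensor, offset: int) -> Tensor:
    """Shift along the time axis with zero padding (for dilated convs)."""
    if offset == 0:
        return x
    b, t, c = x.shape
    zeros = Tensor(np.zeros((b, abs(offset), c), dtype=x.data.dtype))
    if offset > 0:  # past samples
        return concat([zeros, x[:, : t - offset]], axis=1)
    return concat([x[:, -offset:], zeros], axis=1)


class ConvBlock:
    """Residual kernel-3 dilated conv followed by GELU."""

    def __init__(self, d: int, dilation: int, rng: np.random.Generator, idx: int):
        scale = 1.0 / np.sqrt(3 * d)
        self.taps = [Parameter(rng.standard_normal((d, d)) * scale,
                               name=f"conv{idx}.tap{j}") for j in range(3)]
        self.bias = Parameter(np.zeros(d), name=f"conv{idx}.bias")
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        dil = self.dilation
        y = (_shift(x, dil) @ self.taps[0] + x @ self.taps[1]
             + _shift(x, -dil) @ self.taps[2] + self.bias)
        return x + y.gelu()

    def parameters(self):
        return [*self.taps, self.bias]


class ConvStack:
    """Length-preserving dilated residual blocks, then pointwise map to d."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        dils = [1, 2, 4]
        self.blocks = [ConvBlock(cfg.latent_channels, dils[i % 3], rng, i)
                       for i in range(cfg.conv_blocks)]
        scale = 1.0 / np.sqrt(cfg.latent_channels)
        self.proj = Parameter(
            rng.standard_normal((cfg.latent_channels, cfg.model_dim)) * scale,
            name="conv.proj")
        self.proj_bias = Parameter(np.zeros(cfg.model_dim), name="conv.proj_bias")

    def __call__(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x @ self.proj + self.proj_bias

    def parameters(self):
        return [p for b in self.blocks for p in b.parameters()] + [
            self.proj, self.proj_bias]


class TemporalPool:
    """Single-head attention over time collapsing (t, d) to one d-vector.

    A learned query scores the key projection of every time step; the output
    is the softmax-weighted average of the value projections (value map is
    identity-initialized, so at init the pool is a convex combination of the
    input steps).
    """

    def __init__(self, d: int, rng: np.random.Generator):
        self.query = Parameter(rng.standard_normal(d) / np.sqrt(d), name="pool.q")
        self.Wk = Parameter(rng.standard_normal((d, d)) / np.sqrt(d), name="pool.Wk")
        self.Wv = Parameter(np.eye(d), name="pool.Wv")
        self.d = d

    def __call__(self, x: Tensor) -> Tensor:
        scores = (x @ self.Wk) @ self.query.reshape(self.d, 1)  # (B,t,1)
        w = scores.swapaxes(1, 2).softmax(axis=-1)  # (B,1,t)
        return (w @ (x @ self.Wv)).reshape(x.shape[0], self.d)

    def attention_weights(self, x: Tensor) -> np.ndarray:
        scores = (x @ self.Wk) @ self.query.reshape(self.d, 1)
        return scores.swapaxes(1, 2).softmax(axis=-1).numpy()[:, 0, :]

    def parameters(self):
        return [self.query, self.Wk, self.Wv]


class LayerNorm:
    def __init__(self, d: int, name: str):
        self.gamma = Parameter(np.ones(d), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(d), name=f"{name}.beta")

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + 1e-5) ** 0.5) * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


def _rope_tables(length: int, head_dim: int) -> tuple[np.ndarray, np.ndarray]:
    half = head_dim // 2
    inv_freq = 1.0 / (10000.0 ** (np.arange(half) / half))
    ang = np.arange(length)[:, None] * inv_freq[None, :]  # (L, half)
    return np.cos(ang), np.sin(ang)


def _apply_rope(x: Tensor, cos: np.ndarray, sin: np.ndarray) -> Tensor:
    """Rotary position encoding on the last axis of (S, H, L, hd).

    The two halves of each head act as (real, imaginary) parts; rotation by
    a position-dependent angle preserves inner products between tokens at
    equal offsets.
    """
    hd = x.shape[-1]
    half = hd // 2
    xe, xo = x[..., :half], x[..., half:]
    c, s = Tensor(cos), Tensor(sin)
    return concat([xe * c - xo * s, xe * s + xo * c], axis=-1)


class TransformerLayer:
    """Pre-norm bidirectional block: RoPE attention + GELU MLP."""

    def __init__(self, d: int, heads: int, dropout: float,
                 rng: np.random.Generator, idx: int):
        s = 1.0 / np.sqrt(d)
        nm = f"tf{idx}"
        self.ln1 = LayerNorm(d, f"{nm}.ln1")
        self.ln2 = LayerNorm(d, f"{nm}.ln2")
        self.Wq = Parameter(rng.standard_normal((d, d)) * s, name=f"{nm}.Wq")
        self.Wk = Parameter(rng.standard_normal((d, d)) * s, name=f"{nm}.Wk")
        self.Wv = Parameter(rng.standard_normal((d, d)) * s, name=f"{nm}.Wv")
        self.Wo = Parameter(rng.standard_normal((d, d)) * s, name=f"{nm}.Wo")
        self.W1 = Parameter(rng.standard_normal((d, 4 * d)) * s, name=f"{nm}.W1")
        self.b1 = Parameter(np.zeros(4 * d), name=f"{nm}.b1")
        self.W2 = Parameter(rng.standard_normal((4 * d, d)) / np.sqrt(4 * d),
                            name=f"{nm}.W2")
        self.b2 = Parameter(np.zeros(d), name=f"{nm}.b2")
        self.heads = heads
        self.d = d
        self.dropout = dropout

    def _split_heads(self, x: Tensor, S: int, L: int) -> Tensor:
        return x.reshape(S, L, self.heads, self.d // self.heads).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor, pad_mask: np.ndarray, train: bool,
                 rng: np.random.Generator | None) -> Tensor:
        S, L, d = x.shape
        hd = d // self.heads
        h = self.ln1(x)
        q = self._split_heads(h @ self.Wq, S, L)
        k = self._split_heads(h @ self.Wk, S, L)
        v = self._split_heads(h @ self.Wv, S, L)
        cos, sin = _rope_tables(L, hd)
        cos = cos.astype(h.data.dtype)
        sin = sin.astype(h.data.dtype)
        q = _apply_rope(q, cos, sin)
        k = _apply_rope(k, cos, sin)
        logits = q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(hd))
        # padded keys are never attended to
        key_mask = pad_mask[:, None, None, :]  # (S,1,1,L)
        logits = logits + Tensor(np.where(key_mask, 0.0, -1e9).astype(h.data.dtype))
        attn = logits.softmax(axis=-1)
        if train and self.dropout > 0 and rng is not None:
            keep = (rng.random(attn.shape) >= self.dropout).astype(attn.data.dtype)
            attn = attn * Tensor(keep / np.asarray(1.0 - self.dropout,
                                                   dtype=attn.data.dtype))
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(S, L, d)
        x = x + ctx @ self.Wo
        h = self.ln2(x)
        x = x + ((h @ self.W1 + self.b1).gelu()) @ self.W2 + self.b2
        return x

    def parameters(self):
        return (self.ln1.parameters() + self.ln2.parameters()
                + [self.Wq, self.Wk, self.Wv, self.Wo,
                   self.W1, self.b1, self.W2, self.b2])


class BrainDecoder:
    """Full decoding network f: epoch windows -> predicted word embeddings."""

    def __init__(self, cfg: ModelConfig, sensor_positions: np.ndarray,
                 subject_ids: list[str], seed: int = 0):
        if len(subject_ids) != cfg.n_subjects:
            raise ValueError("subject_ids length must equal cfg.n_subjects")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xde]))
        self.cfg = cfg
        self.sensor_positions = np.asarray(sensor_positions, dtype=np.float64)
        if self.sensor_positions.shape != (cfg.n_sensors, 2):
            raise ValueError("sensor position count must match cfg.n_sensors")
        self.subject_index = {s: i for i, s in enumerate(subject_ids)}
        self.spatial = SpatialAttention(cfg, rng)
        self.subject = SubjectLayer(cfg)
        self.conv = ConvStack(cfg, rng)
        self.pool = TemporalPool(cfg.model_dim, rng)
        self.transformer = [
            TransformerLayer(cfg.model_dim, cfg.transformer_heads,
                             cfg.attention_dropout, rng, i)
            for i in range(cfg.transformer_layers)]
        self.final_ln = (LayerNorm(cfg.model_dim, "final_ln")
                         if cfg.transformer_layers else None)
        self._np_dtype = np.dtype(cfg.dtype)
        for p in self.parameters():
            p.data = p.data.astype(self._np_dtype)

    # -- plumbing -------------------------------------------------------------
    def parameters(self) -> list[Parameter]:
        ps = (self.spatial.parameters() + self.subject.parameters()
              + self.conv.parameters() + self.pool.parameters())
        for layer in self.transformer:
            ps += layer.parameters()
        if self.final_ln is not None:
            ps += self.final_ln.parameters()
        return ps

    def encode_words(self, X: np.ndarray, subject_idx: np.ndarray) -> Tensor:
        """Per-word CNN path: (B, t, n) -> (B, d)."""
        X = np.asarray(X).astype(self._np_dtype, copy=False)
        h = self.spatial(Tensor(X), self.sensor_positions,
                         self.cfg.spatial_harmonics)
        h = self.subject(h, subject_idx)
        h = self.conv(h)
        return self.pool(h)

    def forward_sentences(self, wv: Tensor, sentence_slices: list[tuple[int, int]],
                          train: bool = False,
                          rng: np.random.Generator | None = None) -> Tensor:
        """Sentence-level transformer over stacked word vectors."""
        if not self.transformer:
            return wv
        lens = [e - s for s, e in sentence_slices]
        if min(lens) < 1:
            raise ValueError("empty (all-padded) sentence group")
        L = max(lens)
        d = self.cfg.model_dim
        rows = []
        mask = np.zeros((len(lens), L), dtype=bool)
        for i, (s, e) in enumerate(sentence_slices):
            part = wv[s:e]
            if e - s < L:
                pad = np.zeros((L - (e - s), d), dtype=wv.data.dtype)
                part = concat([part, Tensor(pad)], axis=0)
            rows.append(part)
            mask[i, : e - s] = True
        x = stack(rows, axis=0)  # (S, L, d)
        for layer in self.transformer:
            x = layer(x, mask, train, rng)
        x = self.final_ln(x)
        out = [x[i, : lens[i]] for i in range(len(lens))]
        return concat(out, axis=0)

    def forward(self, epochs: EpochSet, train: bool = False,
                rng: np.random.Generator | None = None,
                return_tensor: bool = False):
        """Run the full pipeline on an epoch set grouped by sentence.

        Epochs of one sentence must be contiguous, single-subject and in
        presentation order (see :func:`sentence_groups`).  Returns a
        :class:`PredictionBatch` (or the raw Tensor when training needs
        gradients).
        """
        slices = sentence_groups(epochs)
        subject_idx = np.array([self.subject_index[s] for s in epochs.subject_ids])
        for s, e in slices:
            if len(set(epochs.subject_ids[s:e])) != 1:
                raise ValueError("mixed subjects inside one sentence group")
        wv = self.encode_words(epochs.X, subject_idx)
        out = self.forward_sentences(wv, slices, train=train, rng=rng)
        if return_tensor:
            return out
        meta = pd.DataFrame({
            "word": epochs.words,
            "sentence_id": epochs.sentence_ids,
            "subject": epochs.subject_ids,
            "position": _positions(slices, len(epochs)),
        })
        return PredictionBatch(y_hat=out.numpy(), meta=meta)

    def predict(self, epochs: EpochSet) -> PredictionBatch:
        """Inference without graph construction (eval mode, no dropout)."""
        with no_grad():
            return self.forward(epochs, train=False)

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path, subject_ids: list[str] | None = None) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "config": asdict(self.cfg),
            "sensor_positions": self.sensor_positions.tolist(),
            "subject_ids": [s for s, _ in sorted(self.subject_index.items(),
                                                 key=lambda kv: kv[1])],
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "BrainDecoder":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelConfig(**meta["config"]),
                    np.array(meta["sensor_positions"]), meta["subject_ids"])
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(model.parameters()):
            p.data = data[f"p{i}"].astype(np.float64)
        return model


def _positions(slices: list[tuple[int, int]], n: int) -> np.ndarray:
    pos = np.zeros(n, dtype=int)
    for s, e in slices:
        pos[s:e] = np.arange(e - s)
    return pos


def sentence_groups(epochs: EpochSet) -> list[tuple[int, int]]:
    """Contiguous (start, end) index ranges of (subject, sentence) runs."""
    keys = list(zip(epochs.subject_ids, epochs.sentence_ids))
    slices = []
    start = 0
    for i in range(1, len(keys) + 1):
        if i == len(keys) or keys[i] != keys[start]:
            slices.append((start, i))
            start = i
    if len({k for k in keys}) != len(slices):
        raise ValueError("epochs of one sentence must be contiguous; "
                         "sort by (subject, sentence) first")
    return slices


def sort_by_sentence(epochs: EpochSet) -> EpochSet:
    """Stable-sort epochs so each (subject, sentence) forms a contiguous run."""
    keys = list(zip(epochs.subject_ids, map(str, epochs.sentence_ids)))
    first_seen: dict = {}
    for i, k in enumerate(keys):
        first_seen.setdefault(k, i)
    order = sorted(range(len(keys)), key=lambda i: (first_seen[keys[i]], i))
    return epochs.select(np.array(order))


# -- ridge regression baseline -------------------------------------------------

@dataclass
class RidgeBaselineConfig:
    """Per-lag linear decoding setup.

    One ridge model per lag tau in ``lag_grid_s`` (relative to word onset)
    predicts the embedding from the single time sample at tau; regularization
    is selected per embedding dimension over ``alpha_grid``.
    """

    lag_grid_s: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(-0.5, 2.5 + 1e-9, 0.02), 4))
    alpha_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-2, 8, 11))


def ridge_baseline(train_epochs: EpochSet, test_epochs: EpochSet,
                   embeddings, cfg: RidgeBaselineConfig | None = None) -> pd.DataFrame:
    """Fit per-lag ridge models and report mean test Pearson r per lag.

    Epochs should be cut with ``tmin_s=-0.5`` so negative lags exist; lags
    outside the epoch window are skipped with a warning.  Returns a tidy
    DataFrame (lag_s, mean_r, mean_r_normalized) where the normalized column
    divides by the peak value.
    """
    from sklearn.linear_model import RidgeCV

    cfg = cfg or RidgeBaselineConfig()
    if len(train_epochs) < 50:
        raise ValueError("need at least 50 training epochs")
    fs = train_epochs.sampling_rate_hz
    tmin = train_epochs.tmin_s
    n_t = train_epochs.n_times
    Ytr = np.stack([embeddings[w] for w in train_epochs.words])
    Yte = np.stack([embeddings[w] for w in test_epochs.words])

    rows = []
    for lag in np.atleast_1d(cfg.lag_grid_s):
        idx = int(round((lag - tmin) * fs))
        if idx < 0 or idx >= n_t:
            warnings.warn(f"lag {lag:+.2f}s outside epoch window; skipped")
            continue
        Xtr = train_epochs.X[:, idx, :]
        Xte = test_epochs.X[:, idx, :]
        if np.allclose(Xtr.std(axis=0), 0):
            warnings.warn(f"constant features at lag {lag:+.2f}s; r set to 0")
            rows.append((float(lag), 0.0))
            continue
        model = RidgeCV(alphas=cfg.alpha_grid, alpha_per_target=True)
        model.fit(Xtr, Ytr)
        pred = model.predict(Xte)
        r = _mean_pearson(pred, Yte)
        rows.append((float(lag), r))
    df = pd.DataFrame(rows, columns=["lag_s", "mean_r"])
    if len(df):
        peak = df["mean_r"].abs().max()
        df["mean_r_normalized"] = df["mean_r"] / (peak if peak > 0 else 1.0)
    return df


def _mean_pearson(pred: np.ndarray, true: np.ndarray) -> float:
    """Pearson r per embedding dimension, averaged; degenerate dims count 0."""
    pc = pred - pred.mean(axis=0)
    tc = true - true.mean(axis=0)
    num = (pc * tc).sum(axis=0)
    den = np.sqrt((pc**2).sum(axis=0) * (tc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return float(np.mean(r))
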