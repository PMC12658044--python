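"""Word retrieval and its evaluation metrics.

A predicted embedding is turned into a word by ranking a candidate
vocabulary by cosine similarity.  The headline metric is the *balanced*
top-k accuracy: hit rates are averaged per word first, then across words,
so frequent words cannot dominate.  Additional analyses mirror standard
questions about such decoders: does averaging repeated presentations help,
what do the mistakes share with the true words (orthography, length,
part-of-speech), and how does accuracy depend on training-set frequency?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats

from .embeddings import EmbeddingTable, normalize_word
from .model import PredictionBatch

logger = logging.getLogger(__name__)

MISTAKE_FEATURES = ("first_letter", "last_letter", "length", "pos")


class UndefinedMetricError(ValueError):
    """No included trials: the metric has no value."""


@dataclass
class Vocabulary:
    """Ordered retrieval candidates with their embedding matrix."""

    words: list[str]
    embeddings: np.ndarray  # (len(words), d), row-aligned
    source: str = "custom"
    coverage: float | None = None  # fraction of test occurrences covered

    def __post_init__(self) -> None:
        if len(set(self.words)) != len(self.words):
            raise ValueError("vocabulary words must be unique")
        if self.embeddings.shape[0] != len(self.words):
            raise ValueError("embeddings row count must match words")
        self.index = {w: i for i, w in enumerate(self.words)}

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return normalize_word(word) in self.index


def build_vocabulary(train_words: list[str], embeddings: EmbeddingTable,
                     size: int = 250,
                     test_words: list[str] | None = None) -> Vocabulary:
    """Select the `size` most frequent training words (ties lexicographic).

    When fewer unique words exist, all are used (with a warning).  If
    ``test_words`` is given, the fraction of test occurrences covered by the
    vocabulary is recorded.
    """
    if not len(train_words):
        raise ValueError("train words must be non-empty")
    counts = Counter(normalize_word(w) for w in train_words)
    ranked = sorted(counts, key=lambda w: (-counts[w], w))
    if len(ranked) < size:
        logger.warning("only %d unique words < requested %d", len(ranked), size)
    chosen = ranked[:size]
    source = f"top{size}" if len(ranked) >= size else "full"
    coverage = None
    if test_words is not None:
        norm = [normalize_word(w) for w in test_words]
        coverage = float(np.mean([w in set(chosen) for w in norm])) if norm else 0.0
    return Vocabulary(words=chosen, embeddings=embeddings.matrix(chosen),
                      source=source, coverage=coverage)


def full_vocabulary(embeddings: EmbeddingTable) -> Vocabulary:
    words = sorted(embeddings.words)
    return Vocabulary(words=words, embeddings=embeddings.matrix(words),
                      source="full")


def retrieve(pred: np.ndarray, vocab: Vocabulary, k: int = 10) -> np.ndarray:
    """Rank candidates by cosine similarity; return top-k indices per row.

    Ties break toward earlier vocabulary order (frequency-descending), which
    makes the ranking deterministic.  ``k`` larger than the vocabulary is
    clamped with a warning.
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=np.float64))
    if not np.all(np.isfinite(pred)):
        raise ValueError("non-finite prediction")
    if k > len(vocab):
        logger.warning("k=%d > |V|=%d; clamping", k, len(vocab))
        k = len(vocab)
    sims = _cosine_to_vocab(pred, vocab)
    order = np.argsort(-sims, axis=1, kind="stable")
    return order[:, :k]


def rank_true_words(preds: np.ndarray, words: list[str],
                    vocab: Vocabulary) -> np.ndarray:
    """1-based rank of each true word among the candidates (0 = not in vocab)."""
    sims = _cosine_to_vocab(np.asarray(preds, dtype=np.float64), vocab)
    order = np.argsort(-sims, axis=1, kind="stable")
    ranks = np.zeros(len(words), dtype=int)
    inv = np.empty_like(order)
    rows = np.arange(order.shape[0])[:, None]
    inv[rows, order] = np.arange(order.shape[1])[None, :]
    for i, w in enumerate(words):
        j = vocab.index.get(normalize_word(w))
        ranks[i] = 0 if j is None else inv[i, j] + 1
    return ranks


def _cosine_to_vocab(pred: np.ndarray, vocab: Vocabulary) -> np.ndarray:
    pn = np.linalg.norm(pred, axis=1, keepdims=True)
    vn = np.linalg.norm(vocab.embeddings, axis=1, keepdims=True)
    return (pred / np.where(pn > 0, pn, 1.0)) @ (vocab.embeddings / vn).T


def evaluate_predictions(batch: PredictionBatch, vocab: Vocabulary,
                         k: int = 10,
                         train_counts: dict[str, int] | None = None,
                         pos_tags: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-trial retrieval table.

    Columns: subject, word, sentence_id, rank (0 when the true word is
    outside the vocabulary, flagged ``excluded``), hit (rank within k),
    pred_word (top-1 candidate), plus train_count / pos when provided.
    Excluded trials are discarded from all aggregate metrics downstream.
    """
    ranks = rank_true_words(batch.y_hat, list(batch.meta["word"]), vocab)
    top1 = retrieve(batch.y_hat, vocab, k=1)[:, 0]
    df = pd.DataFrame({
        "subject": batch.meta["subject"].to_numpy(),
        "word": [normalize_word(w) for w in batch.meta["word"]],
        "sentence_id": batch.meta["sentence_id"].to_numpy(),
        "rank": ranks,
        "excluded": ranks == 0,
        "hit": (ranks > 0) & (ranks <= k),
        "pred_word": [vocab.words[j] for j in top1],
    })
    if train_counts is not None:
        df["train_count"] = [train_counts.get(w, 0) for w in df["word"]]
    if pos_tags is not None:
        df["pos"] = [pos_tags.get(w, "FUNCTION") for w in df["word"]]
    return df


def balanced_topk(results: pd.DataFrame, k: int | None = None) -> float:
    """Per-word mean hit rate, then unweighted mean across words.

    Duplicating the trials of a word leaves the metric unchanged.  ``k``
    recomputes hits from ranks when given; otherwise the stored ``hit``
    column (computed at evaluation time) is used.
    """
    inc = results.loc[~results["excluded"]]
    if not len(inc):
        raise UndefinedMetricError("no included trials")
    hit = inc["hit"] if k is None else (inc["rank"] > 0) & (inc["rank"] <= k)
    return float(hit.groupby(inc["word"].to_numpy()).mean().mean())


def per_subject_balanced_topk(results: pd.DataFrame) -> pd.Series:
    inc = results.loc[~results["excluded"]]
    return inc.groupby("subject").apply(
        lambda g: g.groupby("word")["hit"].mean().mean(),
        include_groups=False)


# -- repetition averaging -------------------------------------------------------

AVERAGE_MODES = ("across_contexts", "across_subjects", "both")


def average_predictions(batch: PredictionBatch, mode: str, m: int,
                        rng: np.random.Generator) -> PredictionBatch:
    """Average m sampled predictions of each repetition group.

    Groups: ``across_contexts`` — same (subject, word) over different
    sentences; ``across_subjects`` — same (word, sentence, position) over
    subjects; ``both`` — all occurrences of a word.  Groups with fewer than
    m members are skipped; members are sampled without replacement.  Call
    repeatedly (fresh rng draws) to get resampling error bars.
    """
    if mode not in AVERAGE_MODES:
        raise ValueError(f"mode must be one of {AVERAGE_MODES}")
    meta = batch.meta
    if mode == "across_contexts":
        keys = list(zip(meta["subject"], meta["word"]))
    elif mode == "across_subjects":
        keys = list(zip(meta["word"], meta["sentence_id"], meta["position"]))
        if len(set(meta["subject"])) < 2:
            raise ValueError("across_subjects averaging needs shared contexts "
                             "from at least two subjects")
    else:
        keys = list(meta["word"])
    groups: dict = {}
    for i, key in enumerate(keys):
        groups.setdefault(key, []).append(i)

    rows_y, rows_meta = [], []
    for key, idxs in groups.items():
        if len(idxs) < m:
            continue
        pick = rng.choice(idxs, size=m, replace=False)
        rows_y.append(batch.y_hat[pick].mean(axis=0))
        first = meta.iloc[idxs[0]]
        rows_meta.append({"word": first["word"],
                          "sentence_id": first["sentence_id"],
                          "subject": first["subject"] if mode != "across_subjects"
                          else "pooled",
                          "position": first["position"]})
    if not rows_y:
        raise UndefinedMetricError(f"no group has >= {m} repetitions")
    return PredictionBatch(y_hat=np.stack(rows_y), meta=pd.DataFrame(rows_meta))


def averaging_curve(batch: PredictionBatch, vocab: Vocabulary,
                    ms: list[int], mode: str = "both", k: int = 10,
                    n_resamples: int = 10, seed: int = 0) -> pd.DataFrame:
    """Balanced top-k as a function of m averaged repetitions.

    Returns a tidy table (m, mean, std) where std is over the resampling of
    which occurrences enter each average.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xae]))
    rows = []
    for m in ms:
        vals = []
        for _ in range(n_resamples):
            avg = average_predictions(batch, mode=mode, m=m, rng=rng)
            res = evaluate_predictions(avg, vocab, k=k)
            vals.append(balanced_topk(res))
        rows.append((m, float(np.mean(vals)), float(np.std(vals))))
    return pd.DataFrame(rows, columns=["m", "mean", "std"])


# -- mistake analysis -----------------------------------------------------------

def _feature_match(true: str, pred: str, feature: str,
                   pos_tags: dict[str, str] | None) -> float:
    if feature == "first_letter":
        return float(true[:1] == pred[:1])
    if feature == "last_letter":
        return float(true[-1:] == pred[-1:])
    if feature == "length":
        return float(len(true) == len(pred))
    if feature == "pos":
        if pos_tags is None:
            raise ValueError("POS tags required for the pos feature")
        return float(pos_tags.get(true) == pos_tags.get(pred))
    raise ValueError(f"unknown feature {feature}")


def mistake_features(results: pd.DataFrame,
                     pos_tags: dict[str, str] | None = None,
                     n_permutations: int = 1000,
                     seed: int = 0) -> pd.DataFrame:
    """Shared properties of incorrect top-1 predictions and their true words.

    For each subject and feature (first letter, last letter, length, POS),
    the observed match rate over incorrect trials is compared to a chance
    rate estimated by permuting the predicted words across that subject's
    incorrect trials.  Returns one row per (subject, feature) with observed,
    chance, and a pooled one-sided t-test across subjects per feature
    (observed > chance).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3a]))
    inc = results.loc[~results["excluded"] & (results["rank"] != 1)]
    if not len(inc):
        return pd.DataFrame(columns=["subject", "feature", "observed",
                                     "chance", "n_mistakes", "t", "p"])
    features = [f for f in MISTAKE_FEATURES if f != "pos" or pos_tags is not None]
    rows = []
    for subject, g in inc.groupby("subject"):
        true = g["word"].to_list()
        pred = g["pred_word"].to_list()
        for feat in features:
            obs = float(np.mean([_feature_match(t, p, feat, pos_tags)
                                 for t, p in zip(true, pred)]))
            perm_rates = np.empty(n_permutations)
            pred_arr = np.array(pred)
            for it in range(n_permutations):
                perm = rng.permutation(pred_arr)
                perm_rates[it] = np.mean([_feature_match(t, p, feat, pos_tags)
                                          for t, p in zip(true, perm)])
            rows.append((subject, feat, obs, float(perm_rates.mean()), len(g)))
    df = pd.DataFrame(rows, columns=["subject", "feature", "observed",
                                     "chance", "n_mistakes"])
    # one-sided paired t-test across subjects, per feature
    tp = {}
    for feat, g in df.groupby("feature"):
        diff = g["observed"] - g["chance"]
        if len(diff) > 1 and diff.std() > 0:
            t, p = stats.ttest_rel(g["observed"], g["chance"], alternative="greater")
        else:
            t, p = np.nan, np.nan
        tp[feat] = (t, p)
    df["t"] = [tp[f][0] for f in df["feature"]]
    df["p"] = [tp[f][1] for f in df["feature"]]
    return df


# -- frequency / POS stratification ---------------------------------------------

def stratified_accuracy(results: pd.DataFrame,
                        strata: str = "train_occurrences",
                        k: int | None = None) -> pd.DataFrame:
    """Balanced top-k per stratum with subject-level SEM.

    ``train_occurrences``: test words are split into quartiles of their
    training-set occurrence count; words never seen in training form the
    ``oov`` stratum.  ``pos``: strata are the POS categories.  Empty strata
    are simply absent from the output.
    """
    inc = results.loc[~results["excluded"]].copy()
    if not len(inc):
        raise UndefinedMetricError("no included trials")
    if strata == "train_occurrences":
        if "train_count" not in inc.columns:
            raise ValueError("results lack train_count; pass train_counts to "
                             "evaluate_predictions")
        word_counts = inc.groupby("word")["train_count"].first()
        seen = word_counts[word_counts > 0]
        qs = np.quantile(seen, [0.25, 0.5, 0.75]) if len(seen) else []

        def stratum(w):
            c = word_counts[w]
            if c == 0:
                return "oov"
            q = int(np.searchsorted(qs, c, side="left"))
            return f"q{q + 1}"

        inc["stratum"] = [stratum(w) for w in inc["word"]]
        order = ["oov", "q1", "q2", "q3", "q4"]
    elif strata == "pos":
        if "pos" not in inc.columns:
            raise ValueError("results lack pos; pass pos_tags to "
                             "evaluate_predictions")
        inc["stratum"] = inc["pos"]
        order = sorted(inc["stratum"].unique())
    else:
        raise ValueError("strata must be 'train_occurrences' or 'pos'")

    rows = []
    for st in order:
        g = inc.loc[inc["stratum"] == st]
        if not len(g):
            continue
        per_subj = per_subject_balanced_topk(
            g.assign(hit=g["hit"] if k is None else (g["rank"] <= k)))
        sem = float(per_subj.std(ddof=1) / np.sqrt(len(per_subj))) \
            if len(per_subj) > 1 else np.nan
        rows.append((st, balanced_topk(g, k=k), sem, len(g)))
    return pd.DataFrame(rows, columns=["stratum", "balanced_topk", "sem",
                                       "n_trials"])


def scaling_curves(runs: list[dict], factor: str = "n_subjects") -> pd.DataFrame:
    """Tidy (factor, mean, sem, n) table from repeated runs.

    Each run dict carries the varied ``factor`` value and an ``accuracy``;
    this is orchestration for plotting scaling trends, nothing more.
    """
    df = pd.DataFrame(runs)
    if not len(df):
        return pd.DataFrame(columns=[factor, "mean", "sem", "n"])
    out = df.groupby(factor)["accuracy"].agg(
        mean="mean",
        sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
        n="count").reset_index()
    return out
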