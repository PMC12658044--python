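"""Retrieval metrics: balanced top-k algebra, chance calibration, analyses."""

import numpy as np
import pandas as pd
import pytest

from neuroword.embeddings import FallbackBackend, embed_words
from neuroword.evaluation import (UndefinedMetricError, Vocabulary,
                                  average_predictions, averaging_curve,
                                  balanced_topk, build_vocabulary,
                                  mistake_features, rank_true_words, retrieve,
                                  scaling_curves, stratified_accuracy)
from neuroword.model import PredictionBatch


def results_frame(rows):
    """rows: (word, rank, subject). rank 0 encodes an excluded (OOV) trial."""
    df = pd.DataFrame(rows, columns=["word", "rank", "subject"])
    df["sentence_id"] = "s0"
    df["excluded"] = df["rank"] == 0
    df["hit"] = (df["rank"] > 0) & (df["rank"] <= 10)
    df["pred_word"] = df["word"]
    return df


def unit_vocab(words, dim=32, seed=0):
    table = embed_words(words, FallbackBackend(dim=dim, seed=seed))
    return Vocabulary(words=list(words), embeddings=table.matrix(list(words)))


# -- balanced top-k ---------------------------------------------------------------

def test_balanced_topk_hand_example():
    # word A hits {1,1,0}, word B hits {0} -> (2/3 + 0)/2 = 1/3
    rows = [("a", 1, "s"), ("a", 2, "s"), ("a", 99, "s"), ("b", 99, "s")]
    assert balanced_topk(results_frame(rows)) == pytest.approx(1 / 3)


def test_balanced_topk_duplication_invariance():
    rows = [("a", 1, "s"), ("a", 99, "s"), ("b", 3, "s")]
    base = balanced_topk(results_frame(rows))
    dup = balanced_topk(results_frame(rows + [("a", 1, "s"), ("a", 99, "s")]))
    assert base == pytest.approx(dup)


def test_balanced_topk_all_hits_and_empty():
    assert balanced_topk(results_frame([("a", 1, "s"), ("b", 5, "s")])) == 1.0
    with pytest.raises(UndefinedMetricError):
        balanced_topk(results_frame([("a", 0, "s")]))


# -- retrieval --------------------------------------------------------------------

def test_exact_embedding_ranks_first():
    vocab = unit_vocab([f"w{i}" for i in range(20)])
    pred = vocab.embeddings[7]
    ranks = rank_true_words(pred[None, :], ["w7"], vocab)
    assert ranks[0] == 1
    top = retrieve(pred, vocab, k=3)
    assert top[0, 0] == 7


def test_retrieve_sort_semantics_and_tie_break():
    emb = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, 1.0]])
    vocab = Vocabulary(words=["a", "b", "c", "d"], embeddings=emb)
    pred = np.array([0.1, 1.0])
    order = retrieve(pred, vocab, k=4)[0]
    # b and d tie: vocabulary order wins
    assert order.tolist()[:2] == [1, 3]


def test_k_larger_than_vocab_clamped():
    vocab = unit_vocab(["a", "b", "c"] + [f"w{i}" for i in range(17)])
    out = retrieve(np.ones(32), vocab, k=50)
    assert out.shape == (1, 20)


def test_retrieval_with_full_vocab_always_hits_at_k_equals_v():
    vocab = unit_vocab([f"w{i}" for i in range(15)])
    rng = np.random.default_rng(0)
    preds = rng.standard_normal((30, 32))
    words = [f"w{i % 15}" for i in range(30)]
    ranks = rank_true_words(preds, words, vocab)
    assert np.all((ranks >= 1) & (ranks <= 15))


def test_chance_level_calibration_small():
    # uniform-random predictions vs near-orthogonal vocab: P(top-10) ~ 10/|V|
    rng = np.random.default_rng(11)
    vocab = unit_vocab([f"word{i}" for i in range(100)], dim=256)
    preds = rng.standard_normal((4000, 256))
    words = [f"word{i}" for i in rng.integers(0, 100, 4000)]
    ranks = rank_true_words(preds, words, vocab)
    hit = (ranks <= 10).mean()
    assert hit == pytest.approx(0.10, abs=0.02)


# -- vocabulary -------------------------------------------------------------------

def test_build_vocabulary_frequency_and_tie_rule():
    train = ["b"] * 3 + ["a"] * 3 + ["c"] * 2 + ["d"]
    table = embed_words(["a", "b", "c", "d"], FallbackBackend(dim=16))
    vocab = build_vocabulary(train, table, size=3)
    assert vocab.words == ["a", "b", "c"]  # tie a/b broken lexicographically


def test_vocabulary_coverage_matches_harmonic_ratio():
    # Zipf corpus: top-250 coverage ~ H(250)/H(2000)
    rng = np.random.default_rng(0)
    n_vocab = 2000
    ranks = np.arange(1, n_vocab + 1)
    w = 1.0 / ranks
    w /= w.sum()
    words = [f"w{i:04d}" for i in range(n_vocab)]
    train = list(rng.choice(words, size=60_000, p=w))
    test = list(rng.choice(words, size=10_000, p=w))
    table = embed_words(words, FallbackBackend(dim=16))
    vocab = build_vocabulary(train, table, size=250, test_words=test)
    expected = w[:250].sum()  # harmonic-sum ratio
    assert vocab.coverage == pytest.approx(expected, abs=0.03)


def test_small_vocab_uses_all_words():
    table = embed_words(["a", "b"], FallbackBackend(dim=16))
    vocab = build_vocabulary(["a", "b", "a"], table, size=250)
    assert len(vocab) == 2 and vocab.source == "full"


# -- averaging --------------------------------------------------------------------

def batch_for_averaging():
    rng = np.random.default_rng(3)
    words = ["alpha"] * 6 + ["beta"] * 3
    y = rng.standard_normal((9, 8))
    meta = pd.DataFrame({"word": words,
                         "sentence_id": [f"s{i}" for i in range(9)],
                         "subject": ["s1"] * 5 + ["s2"] * 4,
                         "position": 0})
    return PredictionBatch(y_hat=y, meta=meta)


def test_average_m1_preserves_per_group_predictions():
    batch = batch_for_averaging()
    rng = np.random.default_rng(0)
    avg = average_predictions(batch, mode="both", m=1, rng=rng)
    assert sorted(avg.meta["word"]) == ["alpha", "beta"]


def test_average_identical_predictions_is_identity():
    batch = batch_for_averaging()
    batch.y_hat[:6] = 1.5
    avg = average_predictions(batch, mode="both", m=4,
                              rng=np.random.default_rng(0))
    row = avg.y_hat[list(avg.meta["word"]).index("alpha")]
    np.testing.assert_allclose(row, 1.5)


def test_average_group_too_small_skipped_and_error_when_none():
    batch = batch_for_averaging()
    avg = average_predictions(batch, mode="both", m=5,
                              rng=np.random.default_rng(0))
    assert list(avg.meta["word"]) == ["alpha"]
    with pytest.raises(UndefinedMetricError):
        average_predictions(batch, mode="both", m=10,
                            rng=np.random.default_rng(0))


def test_across_subjects_requires_shared_contexts():
    batch = batch_for_averaging()
    batch.meta["subject"] = "only-one"
    with pytest.raises(ValueError):
        average_predictions(batch, mode="across_subjects", m=2,
                            rng=np.random.default_rng(0))


def test_averaging_reduces_noise_on_synthetic_predictions():
    # predictions = true embedding + noise; averaging m raises balanced top-k
    rng = np.random.default_rng(5)
    words = [f"w{i}" for i in range(30)]
    vocab = unit_vocab(words, dim=64)
    reps = 8
    y, meta_rows = [], []
    for i, w in enumerate(words):
        for r in range(reps):
            y.append(vocab.embeddings[i] + 1.5 * rng.standard_normal(64))
            meta_rows.append((w, f"s{i}_{r}", "s1", 0))
    batch = PredictionBatch(
        y_hat=np.stack(y),
        meta=pd.DataFrame(meta_rows,
                          columns=["word", "sentence_id", "subject", "position"]))
    curve = averaging_curve(batch, vocab, ms=[1, 8], mode="both", k=5,
                            n_resamples=6, seed=0)
    assert curve.loc[curve["m"] == 8, "mean"].iloc[0] >= \
        curve.loc[curve["m"] == 1, "mean"].iloc[0]


# -- mistake features -------------------------------------------------------------

def test_mistake_feature_hand_example():
    res = pd.DataFrame({
        "subject": ["s1"] * 2,
        "word": ["night", "day"],
        "sentence_id": ["a", "b"],
        "rank": [2, 1],           # only "night" is a mistake
        "excluded": [False, False],
        "hit": [True, True],
        "pred_word": ["nights", "day"],
    })
    out = mistake_features(res, pos_tags={"night": "NOUN", "nights": "NOUN",
                                          "day": "NOUN"}, n_permutations=10)
    row = out.set_index("feature")
    assert row.loc["first_letter", "observed"] == 1.0   # n == n
    assert row.loc["last_letter", "observed"] == 0.0    # t != s
    assert row.loc["length", "observed"] == 0.0         # 5 != 6
    assert row.loc["pos", "observed"] == 1.0


def test_mistake_features_empty_when_all_correct():
    res = results_frame([("a", 1, "s1"), ("b", 1, "s1")])
    assert len(mistake_features(res, n_permutations=5)) == 0


def test_permutation_null_matches_chance():
    # predictions that are themselves a random permutation of the true words
    rng = np.random.default_rng(0)
    words = [f"w{i}" for i in range(60)]
    perm = list(rng.permutation(words))
    res = pd.DataFrame({
        "subject": "s1", "word": words, "sentence_id": "x",
        "rank": 2, "excluded": False, "hit": False, "pred_word": perm,
    })
    out = mistake_features(res, n_permutations=300, seed=1)
    for _, r in out.iterrows():
        assert abs(r["observed"] - r["chance"]) < 0.08


# -- stratified accuracy ----------------------------------------------------------

def strat_results():
    rows = []
    counts = {"hi": 40, "mid": 6, "lo": 1, "oovw": 0}
    hits = {"hi": True, "mid": True, "lo": False, "oovw": False}
    for w, c in counts.items():
        for s in ("s1", "s2"):
            rows.append({"subject": s, "word": w, "sentence_id": "x",
                         "rank": 1 if hits[w] else 50, "excluded": False,
                         "hit": hits[w], "pred_word": w, "train_count": c})
    return pd.DataFrame(rows)


def test_stratified_accuracy_oov_and_quartiles():
    out = stratified_accuracy(strat_results())
    strata = dict(zip(out["stratum"], out["balanced_topk"]))
    assert "oov" in strata and strata["oov"] == 0.0
    assert strata["q4"] == 1.0


def test_oov_stratum_absent_when_all_words_seen():
    df = strat_results()
    df = df[df["word"] != "oovw"]
    out = stratified_accuracy(df)
    assert "oov" not in set(out["stratum"])


def test_scaling_curves_single_and_multiple_runs():
    single = scaling_curves([{"n_subjects": 1, "accuracy": 0.5}])
    assert len(single) == 1 and np.isnan(single["sem"].iloc[0])
    multi = scaling_curves([{"n_subjects": n, "accuracy": a, "seed": s}
                            for n, a, s in [(1, .4, 0), (1, .5, 1),
                                            (2, .6, 0), (2, .7, 1)]])
    assert multi["mean"].tolist() == [pytest.approx(.45), pytest.approx(.65)]
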