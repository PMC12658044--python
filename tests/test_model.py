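"""Architecture contracts: layer symmetries, masking, determinism, persistence."""

import numpy as np
import pytest

from neuroword._autodiff import Tensor
from neuroword.containers import EpochSet
from neuroword.model import (BrainDecoder, ModelConfig, SpatialAttention,
                             SubjectLayer, TemporalPool, TransformerLayer,
                             ConvStack, sentence_groups, sort_by_sentence)

RNG = np.random.default_rng(0)


def compact_config(**kw):
    base = dict(n_sensors=6, n_subjects=2, model_dim=16, latent_channels=8,
                conv_blocks=2, transformer_layers=1, transformer_heads=4,
                spatial_harmonics=3, dtype="float64")
    base.update(kw)
    return ModelConfig(**base)


def make_model(**kw):
    cfg = compact_config(**kw)
    positions = RNG.uniform(0, 1, (cfg.n_sensors, 2))
    return BrainDecoder(cfg, positions, [f"sub-{i}" for i in range(cfg.n_subjects)],
                        seed=1), cfg, positions


def toy_epochs(n_sent=3, words_per=4, t=40, n=6, subjects=("sub-0",)):
    total = n_sent * words_per * len(subjects)
    X = RNG.standard_normal((total, t, n))
    words, sids, subs = [], [], []
    for s in subjects:
        for j in range(n_sent):
            for k in range(words_per):
                words.append(f"w{j}_{k}")
                sids.append(f"s{j}")
                subs.append(s)
    return EpochSet(X=X, words=words, sentence_ids=sids, subject_ids=subs,
                    sampling_rate_hz=50.0)


# -- spatial attention ------------------------------------------------------------

def test_single_sensor_passes_through():
    cfg = compact_config(n_sensors=1)
    layer = SpatialAttention(cfg, np.random.default_rng(0))
    x = RNG.standard_normal((2, 10, 1))
    out = layer(Tensor(x), np.array([[0.5, 0.5]]), cfg.spatial_harmonics)
    # softmax over one sensor = 1, so every latent channel is that series
    for j in range(cfg.latent_channels):
        np.testing.assert_allclose(out.numpy()[..., j], x[..., 0], atol=1e-12)


def test_sensor_permutation_invariance():
    cfg = compact_config()
    layer = SpatialAttention(cfg, np.random.default_rng(0))
    x = RNG.standard_normal((1, 12, 6))
    pos = RNG.uniform(0, 1, (6, 2))
    perm = np.random.default_rng(1).permutation(6)
    a = layer(Tensor(x), pos, cfg.spatial_harmonics).numpy()
    b = layer(Tensor(x[:, :, perm]), pos[perm], cfg.spatial_harmonics).numpy()
    np.testing.assert_allclose(a, b, atol=1e-10)


def test_duplicate_sensors_interchangeable():
    cfg = compact_config(n_sensors=2)
    layer = SpatialAttention(cfg, np.random.default_rng(0))
    series = RNG.standard_normal((1, 12, 1))
    x = np.concatenate([series, series], axis=2)
    pos = np.array([[0.3, 0.7], [0.3, 0.7]])
    a = layer(Tensor(x), pos, cfg.spatial_harmonics).numpy()
    b = layer(Tensor(x[:, :, ::-1]), pos, cfg.spatial_harmonics).numpy()
    np.testing.assert_allclose(a, b, atol=1e-12)


# -- subject layer ----------------------------------------------------------------

def test_subject_layer_identity_at_init_and_pointwise_in_time():
    layer = SubjectLayer(compact_config())
    h = RNG.standard_normal((4, 10, 8))
    out = layer(Tensor(h), np.array([0, 1, 0, 1]))
    np.testing.assert_allclose(out.numpy(), h, atol=1e-12)
    # time-constant input stays time-constant after training-like perturbation
    layer.M.data = layer.M.data + 0.1 * RNG.standard_normal(layer.M.data.shape)
    const = np.repeat(RNG.standard_normal((1, 1, 8)), 10, axis=1)
    out = layer(Tensor(const), np.array([1])).numpy()
    np.testing.assert_allclose(out, np.repeat(out[:, :1], 10, axis=1), atol=1e-10)


def test_subject_layer_contiguous_runs_match_gather():
    layer = SubjectLayer(compact_config())
    layer.M.data = RNG.standard_normal(layer.M.data.shape)
    h = RNG.standard_normal((5, 6, 8))
    sorted_idx = np.array([0, 0, 0, 1, 1])
    mixed_idx = np.array([0, 1, 0, 1, 0])
    a = layer(Tensor(h), sorted_idx).numpy()      # run-based path
    b = layer(Tensor(h), mixed_idx).numpy()       # gather fallback
    for i, s in enumerate(sorted_idx):
        np.testing.assert_allclose(a[i], h[i] @ layer.M.data[s], atol=1e-10)
    for i, s in enumerate(mixed_idx):
        np.testing.assert_allclose(b[i], h[i] @ layer.M.data[s], atol=1e-10)


def test_unknown_subject_rejected():
    layer = SubjectLayer(compact_config(n_subjects=2))
    with pytest.raises(KeyError):
        layer(Tensor(np.zeros((1, 4, 8))), np.array([2]))


# -- conv stack -------------------------------------------------------------------

@pytest.mark.parametrize("t", [8, 40, 150])
def test_conv_stack_preserves_length(t):
    cfg = compact_config()
    conv = ConvStack(cfg, np.random.default_rng(0))
    out = conv(Tensor(RNG.standard_normal((2, t, 8))))
    assert out.shape == (2, t, 16)
    assert np.all(np.isfinite(out.numpy()))


def test_conv_stack_gradient_reaches_first_block():
    cfg = compact_config()
    conv = ConvStack(cfg, np.random.default_rng(0))
    out = conv(Tensor(RNG.standard_normal((1, 20, 8))))
    (out ** 2).sum().backward()
    g = conv.blocks[0].taps[0].grad
    assert g is not None and np.linalg.norm(g) > 0


# -- temporal pooling -------------------------------------------------------------

def test_pool_is_convex_combination_at_init():
    pool = TemporalPool(16, np.random.default_rng(0))
    v = RNG.standard_normal(16)
    x = np.tile(v, (2, 7, 1))
    out = pool(Tensor(x)).numpy()
    np.testing.assert_allclose(out, np.tile(v, (2, 1)), atol=1e-10)
    w = pool.attention_weights(Tensor(RNG.standard_normal((3, 9, 16))))
    assert np.all(w >= 0)
    np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)


def test_pool_single_step_returns_value_projection():
    pool = TemporalPool(16, np.random.default_rng(0))
    pool.Wv.data = RNG.standard_normal((16, 16))  # non-identity value map
    x = RNG.standard_normal((1, 1, 16))
    out = pool(Tensor(x)).numpy()
    np.testing.assert_allclose(out, x[0] @ pool.Wv.data, atol=1e-10)


# -- transformer ------------------------------------------------------------------

def test_padding_does_not_change_real_positions():
    layer = TransformerLayer(16, 4, dropout=0.0, rng=np.random.default_rng(0),
                             idx=0)
    x = RNG.standard_normal((1, 5, 16))
    mask5 = np.ones((1, 5), dtype=bool)
    padded = np.concatenate([x, np.zeros((1, 3, 16))], axis=1)
    mask8 = np.concatenate([mask5, np.zeros((1, 3), dtype=bool)], axis=1)
    a = layer(Tensor(x), mask5, train=False, rng=None).numpy()
    b = layer(Tensor(padded), mask8, train=False, rng=None).numpy()
    np.testing.assert_allclose(a, b[:, :5], atol=1e-5)


def test_eval_mode_is_deterministic_despite_dropout_config():
    model, _, _ = make_model()
    eps = toy_epochs(subjects=("sub-0",))
    a = model.predict(eps).y_hat
    b = model.predict(eps).y_hat
    np.testing.assert_array_equal(a, b)


# -- full forward -----------------------------------------------------------------

def test_forward_shape_and_row_alignment():
    model, _, _ = make_model()
    eps = toy_epochs(n_sent=3, words_per=4, subjects=("sub-0", "sub-1"))
    batch = model.predict(eps)
    assert batch.y_hat.shape == (24, 16)
    assert list(batch.meta["word"]) == eps.words
    assert np.all(np.isfinite(batch.y_hat))


def test_swapping_sentences_swaps_predictions():
    model, _, _ = make_model()
    eps = toy_epochs(n_sent=2, words_per=3)
    order = np.concatenate([np.arange(3, 6), np.arange(0, 3)])
    swapped = eps.select(order)
    a = model.predict(eps).y_hat
    b = model.predict(swapped).y_hat
    np.testing.assert_allclose(a[order], b, atol=1e-5)


def test_mixed_subject_sentence_rejected():
    model, _, _ = make_model()
    eps = toy_epochs(n_sent=1, words_per=4)
    eps.subject_ids[2] = "sub-1"
    with pytest.raises(ValueError, match="contiguous|mixed"):
        model.predict(eps)


def test_sentence_groups_require_contiguity():
    eps = toy_epochs(n_sent=2, words_per=2)
    shuffled = eps.select(np.array([0, 2, 1, 3]))
    with pytest.raises(ValueError):
        sentence_groups(shuffled)
    restored = sort_by_sentence(shuffled)
    assert [s for s, _ in
            [(x, 0) for x in restored.sentence_ids]] == ["s0", "s0", "s1", "s1"]


def test_checkpoint_roundtrip_reproduces_predictions(tmp_path):
    model, _, _ = make_model()
    eps = toy_epochs()
    before = model.predict(eps).y_hat
    model.save(tmp_path / "ckpt")
    loaded = BrainDecoder.load(tmp_path / "ckpt")
    after = loaded.predict(eps).y_hat
    np.testing.assert_allclose(before, after, atol=1e-7)


def test_zero_transformer_layers_supported():
    model, _, _ = make_model(transformer_layers=0)
    batch = model.predict(toy_epochs())
    assert batch.y_hat.shape == (12, 16)
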