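"""CNN matcher: shapes, padding invariance, gradients, training contracts."""

import numpy as np
import pytest

from reportmatch import matcher_cnn as mc
from reportmatch.corpus_io import PAD_INDEX, PairDataset, Vocabulary, build_vocabulary
from reportmatch.errors import ConfigurationError
from reportmatch.matcher_cnn import (
    CNNConfig,
    TrainedMatcher,
    encode_report,
    forward,
    init_matcher,
    predict_scores,
    train,
)
from reportmatch.ontology_embedding import EmbeddingMatrix, build_embedding_matrix

from conftest import make_pair


def tiny_vocab():
    return Vocabulary({"<pad>": 0, "<oov>": 1, "a": 2, "b": 3, "c": 4, "d": 5})


def tiny_matcher(seed=0, **kw):
    vocab = tiny_vocab()
    defaults = dict(embed_dim=8, window_sizes=(2, 3), filters_per_window=4, hidden_dim=5, max_len=16, seed=seed)
    defaults.update(kw)
    cfg = CNNConfig(**defaults)
    emb = build_embedding_matrix(vocab, None, embed_dim=cfg.embed_dim, seed=seed)
    return init_matcher(cfg, emb, vocab)


def default_matcher(vocab):
    cfg = CNNConfig(max_len=64, seed=0)
    emb = build_embedding_matrix(vocab, None, embed_dim=128, seed=0)
    return init_matcher(cfg, emb, vocab)


class TestEncode:
    def test_output_dimension_96(self, toy_dataset):
        vocab = build_vocabulary(toy_dataset)
        m = default_matcher(vocab)
        feats = encode_report(m, ("thyroid", "nodule", "clear"), "imaging")
        assert feats.shape == (96,)  # 3 windows x 32 filters

    def test_padding_invariance(self, rng):
        m = tiny_matcher()
        tokens_all = ["a", "b", "c", "d"]
        for _ in range(100):
            n = int(rng.integers(1, 9))
            toks = [tokens_all[i] for i in rng.integers(0, 4, size=n)]
            base = encode_report(m, toks, "imaging")
            idx = m._indices(toks)
            for extra in (1, 5):
                x, lens = mc._batchify([idx + [PAD_INDEX] * 0], 2, 16)
                xpad = np.full((1, x.shape[1] + extra), PAD_INDEX, dtype=np.int64)
                xpad[0, : x.shape[1]] = x[0]
                feats = mc._encode_batch(m, xpad, lens, "imaging")[0]
                np.testing.assert_allclose(feats, base, atol=1e-12)

    def test_short_sequence_defined(self):
        m = tiny_matcher()
        feats = encode_report(m, ["a"], "imaging")  # shorter than both windows
        assert feats.shape == (8,) and np.all(np.isfinite(feats))

    def test_empty_report_maps_to_oov(self):
        m = tiny_matcher()
        np.testing.assert_array_equal(
            encode_report(m, [], "imaging"), encode_report(m, ["<oov>"], "imaging")
        )


class TestForward:
    def test_zero_output_layer_gives_half(self):
        m = tiny_matcher()
        m.params["Wo"][:] = 0.0
        m.params["bo"][:] = 0.0
        pair = make_pair("p", ["a", "b"], ["c", "d"])
        assert forward(m, pair) == pytest.approx(0.5)

    def test_probability_strictly_inside_unit_interval(self, rng):
        m = tiny_matcher(seed=3)
        for i in range(20):
            toks = [["a", "b", "c", "d"][j] for j in rng.integers(0, 4, size=5)]
            p = forward(m, make_pair(f"p{i}", toks, toks[::-1]))
            assert 0.0 < p < 1.0

    def test_sides_not_symmetric(self):
        m = tiny_matcher(seed=1)
        a = forward(m, make_pair("p", ["a", "b", "c"], ["d", "c", "a"]))
        b = forward(m, make_pair("p", ["d", "c", "a"], ["a", "b", "c"]))
        assert a != pytest.approx(b, abs=1e-12)

    def test_vocab_size_mismatch_rejected(self):
        vocab = tiny_vocab()
        cfg = CNNConfig(embed_dim=8, window_sizes=(2,), filters_per_window=2, hidden_dim=3, max_len=8)
        with pytest.raises(ConfigurationError):
            init_matcher(cfg, EmbeddingMatrix(np.zeros((3, 8))), vocab)


class TestGradients:
    def test_numerical_gradient_agreement(self):
        """Analytic vs central-difference gradients within 1e-4 relative.

        The PAD embedding row is excluded: it is frozen by contract, so its
        analytic gradient is identically zero.
        """
        vocab = Vocabulary({"<pad>": 0, "<oov>": 1, "a": 2, "b": 3})
        cfg = CNNConfig(embed_dim=3, window_sizes=(2, 3), filters_per_window=1, hidden_dim=2, max_len=8, seed=1, filter_init="glorot")
        rng = np.random.default_rng(0)
        emb = EmbeddingMatrix(np.vstack([np.zeros(3), rng.normal(size=(3, 3))]))
        m = init_matcher(cfg, emb, vocab)
        xi = np.array([[2, 3, 2, 0], [3, 2, 3, 3]])
        li = np.array([3, 4])
        xp = np.array([[3, 2, 0, 0], [2, 2, 3, 2]])
        lp = np.array([2, 4])
        y = np.array([1.0, 0.0])
        _, grads = mc._loss_and_grads(m, xi, li, xp, lp, y)
        eps = 1e-6
        for key, p in m.params.items():
            num = np.zeros_like(p)
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = p[ix]
                p[ix] = orig + eps
                up = mc._loss_and_grads(m, xi, li, xp, lp, y)[0]
                p[ix] = orig - eps
                down = mc._loss_and_grads(m, xi, li, xp, lp, y)[0]
                p[ix] = orig
                num[ix] = (up - down) / (2 * eps)
            analytic = grads[key]
            if key == "E":
                num, analytic = num[1:], analytic[1:]
            denom = max(np.abs(num).max(), np.abs(analytic).max(), 1e-8)
            assert np.abs(analytic - num).max() / denom < 1e-4, key


class TestTraining:
    def _toy_train(self, **kw):
        pairs = [
            make_pair("p0", ["a", "a", "b"], ["a", "c"], 1),
            make_pair("p1", ["b", "c"], ["b", "b", "d"], 1),
            make_pair("p2", ["c", "d", "a"], ["c", "a"], 1),
            make_pair("p3", ["d", "a"], ["b", "c", "c"], 0),
            make_pair("p4", ["a", "c"], ["d", "d"], 0),
            make_pair("p5", ["b", "d", "c"], ["a", "b"], 0),
            make_pair("p6", ["c", "c"], ["d", "a", "b"], 0),
            make_pair("p7", ["d", "b", "a"], ["c", "d"], 0),
            make_pair("p8", ["a", "b", "c"], ["a", "b"], 1),
            make_pair("p9", ["d", "c"], ["b", "a", "d"], 0),
        ]
        ds = PairDataset(pairs)
        vocab = build_vocabulary(ds)
        defaults = dict(
            embed_dim=8,
            window_sizes=(2, 3),
            filters_per_window=4,
            hidden_dim=8,
            max_len=8,
            learning_rate=0.5,
            batch_size=5,
            epochs=200,
            seed=7,
        )
        defaults.update(kw)
        cfg = CNNConfig(**defaults)
        emb = build_embedding_matrix(vocab, None, embed_dim=cfg.embed_dim, seed=7)
        return cfg, emb, ds, vocab

    def test_memorizes_toy_set(self):
        cfg, emb, ds, vocab = self._toy_train()
        m = train(cfg, emb, ds, vocab)
        scores = predict_scores(m, ds)
        preds = (scores > 0.5).astype(int)
        np.testing.assert_array_equal(preds, [p.label for p in ds])
        assert m.training_log[-1] < m.training_log[0]

    def test_frozen_embeddings_bitwise_identical(self):
        cfg, emb, ds, vocab = self._toy_train(embeddings_trainable=False, epochs=5)
        before = emb.weights.copy()
        m = train(cfg, emb, ds, vocab)
        np.testing.assert_array_equal(m.params["E"], before)

    def test_training_deterministic_under_seed(self):
        cfg, emb, ds, vocab = self._toy_train(epochs=3)
        m1 = train(cfg, emb, ds, vocab)
        m2 = train(cfg, emb, ds, vocab)
        np.testing.assert_array_equal(
            predict_scores(m1, ds), predict_scores(m2, ds)
        )

    def test_single_class_warns(self):
        cfg, emb, ds, vocab = self._toy_train(epochs=1)
        from dataclasses import replace

        ds_pos = PairDataset([replace(p, label=1) for p in ds])
        with pytest.warns(UserWarning, match="single class"):
            train(cfg, emb, ds_pos, vocab)


class TestPredictAndCheckpoint:
    def test_batch_equals_single_and_repeatable(self, toy_dataset):
        vocab = build_vocabulary(toy_dataset)
        m = default_matcher(vocab)
        scores = predict_scores(m, toy_dataset)
        assert scores.shape == (len(toy_dataset),)
        np.testing.assert_array_equal(scores, predict_scores(m, toy_dataset))
        singles = np.array([forward(m, p) for p in toy_dataset])
        np.testing.assert_allclose(scores, singles, atol=1e-12)

    def test_checkpoint_roundtrip_bit_identical(self, toy_dataset, tmp_path):
        vocab = build_vocabulary(toy_dataset)
        m = default_matcher(vocab)
        m.training_log = [0.7, 0.5]
        path = tmp_path / "matcher.zip"
        m.save(path)
        back = TrainedMatcher.load(path)
        assert back.config == m.config
        assert back.vocab.token_to_index == m.vocab.token_to_index
        assert back.training_log == m.training_log
        np.testing.assert_array_equal(
            predict_scores(back, toy_dataset), predict_scores(m, toy_dataset)
        )
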