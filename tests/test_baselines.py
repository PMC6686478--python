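"""Similarity baselines: exact oracles for Jaccard/cosine, contract tests
for LSA/LDA/Doc2Vec/Siamese LSTM."""

import numpy as np
import pytest

from reportmatch.baselines import (
    Doc2VecModel,
    KeywordDictionary,
    KeywordJaccardModel,
    doc2vec_score,
    entity_cosine_score,
    fit_doc2vec,
    fit_lda,
    fit_lsa,
    jaccard_keyword_score,
    lda_score,
    lsa_score,
    siamese_score,
    train_siamese_lstm,
)
from reportmatch.corpus_io import PairDataset, build_vocabulary
from reportmatch.errors import ConfigurationError
from reportmatch.ontology_embedding import build_embedding_matrix

from conftest import make_pair

WORDS = [f"w{i}" for i in range(30)]


def random_pair(rng, pair_id="p"):
    n1, n2 = rng.integers(0, 12, size=2)
    a = [WORDS[i] for i in rng.integers(0, len(WORDS), size=n1)]
    b = [WORDS[i] for i in rng.integers(0, len(WORDS), size=n2)]
    return make_pair(pair_id, a, b)


class TestJaccard:
    DICT = KeywordDictionary(frozenset(WORDS))

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (["w1", "w2", "w3"], ["w2", "w3", "w4"], 0.5),
            (["w1", "w2"], ["w2", "w1", "w1"], 1.0),
            (["zzz"], ["yyy"], 0.0),  # nothing survives the dictionary
        ],
    )
    def test_examples(self, a, b, expected):
        assert jaccard_keyword_score(make_pair("p", a, b), self.DICT) == expected

    def test_empty_dictionary_rejected(self):
        with pytest.raises(ConfigurationError):
            jaccard_keyword_score(make_pair("p", ["a"], ["b"]), KeywordDictionary(frozenset()))

    def test_brute_force_equivalence_1000_random_pairs(self, rng):
        """Exact match against an independent set computation."""
        for i in range(1000):
            pair = random_pair(rng, f"p{i}")
            a = {t for t in pair.imaging.tokens if t in self.DICT.terms}
            b = {t for t in pair.pathology.tokens if t in self.DICT.terms}
            expected = len(a & b) / len(a | b) if (a | b) else 0.0
            assert jaccard_keyword_score(pair, self.DICT) == expected

    def test_symmetry(self, rng):
        for i in range(50):
            p = random_pair(rng, f"p{i}")
            swapped = make_pair("q", p.pathology.tokens, p.imaging.tokens)
            assert jaccard_keyword_score(p, self.DICT) == jaccard_keyword_score(swapped, self.DICT)


def two_theme_corpus(n=30):
    """Disjoint vocabularies: heart-words vs bone-words."""
    heart = [f"heart{i}" for i in range(8)]
    bone = [f"bone{i}" for i in range(8)]
    rng = np.random.default_rng(5)
    pairs = []
    for i in range(n):
        theme = heart if i % 2 == 0 else bone
        a = [theme[j] for j in rng.integers(0, 8, size=10)]
        b = [theme[j] for j in rng.integers(0, 8, size=10)]
        pairs.append(make_pair(f"p{i}", a, b, 1))
    cross = [
        make_pair(f"x{i}", [heart[j] for j in rng.integers(0, 8, size=10)],
                  [bone[j] for j in rng.integers(0, 8, size=10)], 0)
        for i in range(n // 2)
    ]
    return PairDataset(pairs), PairDataset(cross)


class TestLSA:
    def test_identical_documents_cosine_one(self):
        within, _ = two_theme_corpus()
        model = fit_lsa(within, k=10)
        p = make_pair("q", ["heart1", "heart2"], ["heart1", "heart2"])
        assert lsa_score(model, p) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self):
        within, _ = two_theme_corpus()
        model = fit_lsa(within, k=10)
        p = make_pair("q", ["heart1", "bone2"], ["bone2", "bone3"])
        q = make_pair("q", ["bone2", "bone3"], ["heart1", "bone2"])
        assert lsa_score(model, p) == pytest.approx(lsa_score(model, q), abs=1e-12)

    def test_rank_one_corpus_all_scores_one(self):
        docs = [["alpha", "beta", "gamma"]] * 12
        model = fit_lsa(docs, k=5)
        p = make_pair("q", ["alpha", "beta", "gamma"], ["alpha", "beta", "gamma"])
        assert lsa_score(model, p) == pytest.approx(1.0, abs=1e-9)

    def test_theme_separation(self):
        within, cross = two_theme_corpus()
        model = fit_lsa(within, k=8)
        w = np.mean([lsa_score(model, p) for p in within])
        c = np.mean([lsa_score(model, p) for p in cross])
        assert w > c

    def test_argument_error(self):
        with pytest.raises(ValueError):
            fit_lsa(two_theme_corpus()[0], k=0)


class TestLDA:
    @pytest.fixture(scope="class")
    def fitted(self):
        within, cross = two_theme_corpus()
        return fit_lda(within, n_topics=4, seed=0), within, cross

    def test_topic_vectors_on_simplex(self, fitted):
        model, within, _ = fitted
        for p in list(within)[:10]:
            v = model.topic_vector(p.imaging.tokens)
            assert np.all(v >= 0)
            assert v.sum() == pytest.approx(1.0, abs=1e-6)

    def test_identical_reports_cosine_one(self, fitted):
        model, _, _ = fitted
        p = make_pair("q", ["heart1", "heart2"], ["heart1", "heart2"])
        assert lda_score(model, p) == pytest.approx(1.0, abs=1e-9)

    def test_theme_separation(self, fitted):
        model, within, cross = fitted
        w = np.mean([lda_score(model, p) for p in within])
        c = np.mean([lda_score(model, p) for p in cross])
        assert w > c

    def test_argument_error(self):
        with pytest.raises(ValueError):
            fit_lda(two_theme_corpus()[0], n_topics=1)


class TestDoc2Vec:
    @pytest.fixture(scope="class")
    def fitted(self):
        within, cross = two_theme_corpus()
        return fit_doc2vec(within, dim=16, epochs=8, seed=0), within, cross

    def test_vector_dimension(self, fitted):
        model, within, _ = fitted
        assert model.infer_vector(within[0].imaging.tokens).shape == (16,)

    def test_scoring_symmetric(self, fitted):
        model, within, _ = fitted
        p = within[0]
        swapped = make_pair("q", p.pathology.tokens, p.imaging.tokens)
        assert doc2vec_score(model, p) == pytest.approx(doc2vec_score(model, swapped), abs=1e-9)

    def test_theme_separation(self, fitted):
        model, within, cross = fitted
        w = np.mean([doc2vec_score(model, p) for p in within])
        c = np.mean([doc2vec_score(model, p) for p in cross])
        assert w > c


class TestSiameseLSTM:
    def _fit(self, ds, **kw):
        vocab = build_vocabulary(ds)
        emb = build_embedding_matrix(vocab, None, embed_dim=12, seed=0)
        defaults = dict(hidden=8, epochs=60, learning_rate=0.2, seed=0)
        defaults.update(kw)
        return train_siamese_lstm(ds, emb, vocab, **defaults)

    @pytest.fixture(scope="class")
    def toy(self):
        pairs = [
            make_pair("p0", ["a", "b", "c"], ["a", "b", "c"], 1),
            make_pair("p1", ["d", "e"], ["d", "e", "e"], 1),
            make_pair("p2", ["a", "c", "b"], ["c", "a"], 1),
            make_pair("p3", ["a", "b"], ["d", "e"], 0),
            make_pair("p4", ["e", "d"], ["b", "c"], 0),
            make_pair("p5", ["c"], ["e", "d", "e"], 0),
            make_pair("p6", ["b", "a"], ["e", "e"], 0),
            make_pair("p7", ["d", "d", "e"], ["a", "c"], 0),
            make_pair("p8", ["b", "c", "a"], ["b", "c"], 1),
            make_pair("p9", ["e"], ["a", "b", "c"], 0),
        ]
        return PairDataset(pairs)

    def test_identical_sequences_score_exactly_one(self, toy):
        model = self._fit(toy, epochs=2)
        p = make_pair("q", ["a", "b", "c"], ["a", "b", "c"])
        assert siamese_score(model, p) == 1.0

    def test_score_in_unit_interval(self, toy, rng):
        model = self._fit(toy, epochs=2)
        for i in range(20):
            toks = [["a", "b", "c", "d", "e"][j] for j in rng.integers(0, 5, size=4)]
            s = siamese_score(model, make_pair(f"r{i}", toks, toks[::-1]))
            assert 0.0 < s <= 1.0

    def test_symmetry(self, toy):
        model = self._fit(toy, epochs=2)
        p = make_pair("q", ["a", "b"], ["d", "e", "c"])
        swapped = make_pair("q", ["d", "e", "c"], ["a", "b"])
        assert siamese_score(model, p) == pytest.approx(siamese_score(model, swapped), abs=1e-12)

    def test_memorizes_toy_set_at_prevalence_cutoff(self, toy):
        model = self._fit(toy)
        scores = np.array([siamese_score(model, p) for p in toy])
        labels = np.array([p.label for p in toy])
        cutoff = labels.mean()
        np.testing.assert_array_equal((scores > cutoff).astype(int), labels)

    def test_unlabeled_training_rejected(self):
        ds = PairDataset([make_pair("p", ["a"], ["b"], None)])
        with pytest.raises(ValueError):
            self._fit(ds, epochs=1)


class TestEntityCosine:
    LEX = KeywordDictionary(frozenset(["a", "b", "site"]))

    def test_count_vector_example(self):
        # counts {a:2,b:1} vs {a:1,b:2}: cosine = (2+2)/5 = 0.8
        pair = make_pair("p", ["a", "a", "b", "x"], ["a", "b", "b", "y"])
        assert entity_cosine_score(pair, self.LEX) == pytest.approx(0.8)

    def test_disjoint_and_identical(self):
        assert entity_cosine_score(make_pair("p", ["a"], ["b"]), self.LEX) == 0.0
        assert entity_cosine_score(make_pair("p", ["a", "b"], ["a", "b"]), self.LEX) == pytest.approx(1.0)

    def test_empty_side_is_zero(self):
        assert entity_cosine_score(make_pair("p", ["zzz"], ["a"]), self.LEX) == 0.0

    def test_custom_tagger_plugin(self):
        tagger = lambda toks: [t for t in toks if t.startswith("site")]
        pair = make_pair("p", ["site1", "noise"], ["site1", "other"])
        assert entity_cosine_score(pair, self.LEX, tagger=tagger) == pytest.approx(1.0)

    def test_cosine_brute_force_equivalence(self, rng):
        lex = KeywordDictionary(frozenset(WORDS[:15]))
        for i in range(1000):
            pair = random_pair(rng, f"p{i}")
            ea = [t for t in pair.imaging.tokens if t in lex.terms]
            eb = [t for t in pair.pathology.tokens if t in lex.terms]
            if not ea or not eb:
                expected = 0.0
            else:
                keys = sorted(set(ea) | set(eb))
                va = np.array([ea.count(k) for k in keys], dtype=float)
                vb = np.array([eb.count(k) for k in keys], dtype=float)
                expected = float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
            assert entity_cosine_score(pair, lex) == pytest.approx(expected, abs=1e-12)
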