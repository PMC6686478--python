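"""Classical similarity baselines for report-pair matching.

Six comparison models behind one interface (``model.score(pair)``, higher
means more similar): keyword Jaccard over a medical dictionary, LSA and
LDA document vectors, Doc2Vec paragraph vectors, a supervised Siamese
LSTM with exp(-Manhattan) similarity, and an entity bag-of-words cosine
(a dictionary-lookup stand-in for an NER tagger: any callable with the
same tokens->entities contract can be plugged in instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.decomposition import LatentDirichletAllocation, TruncatedSVD
from sklearn.feature_extraction.text import CountVectorizer, TfidfVectorizer

from .corpus_io import PairDataset, ReportPair, Vocabulary, preprocess_text
from .errors import ConfigurationError
from .ontology_embedding import EmbeddingMatrix

__all__ = [
    "KeywordDictionary",
    "jaccard_keyword_score",
    "KeywordJaccardModel",
    "fit_lsa",
    "lsa_score",
    "fit_lda",
    "lda_score",
    "fit_doc2vec",
    "doc2vec_score",
    "train_siamese_lstm",
    "siamese_score",
    "entity_cosine_score",
    "EntityCosineModel",
    "corpus_token_lists",
]


@dataclass(frozen=True)
class KeywordDictionary:
    """A set of medical/site terms used to filter report tokens."""

    terms: frozenset[str]

    @classmethod
    def from_file(cls, path: str | Path) -> "KeywordDictionary":
        terms = [t.strip() for t in Path(path).read_text(encoding="utf-8").splitlines()]
        return cls(frozenset(t for t in terms if t))

    def __len__(self) -> int:
        return len(self.terms)


def _tokens(pair: ReportPair, side: str) -> tuple[str, ...]:
    rep = pair.side(side)
    return rep.tokens if rep.tokens else tuple(preprocess_text(rep.raw_text))


def corpus_token_lists(corpus: PairDataset | Sequence[Sequence[str]]) -> list[list[str]]:
    """Flatten a dataset into one token list per report (both sides)."""
    if isinstance(corpus, PairDataset):
        docs: list[list[str]] = []
        for p in corpus:
            docs.append(list(_tokens(p, "imaging")))
            docs.append(list(_tokens(p, "pathology")))
        return docs
    return [list(doc) for doc in corpus]


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = float(np.linalg.norm(a)), float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b) / (na * nb)


# ---------------------------------------------------------------- keyword


def jaccard_keyword_score(pair: ReportPair, dictionary: KeywordDictionary) -> float:
    """|A∩B| / |A∪B| over dictionary-filtered token sets; 0/0 -> 0."""
    if len(dictionary) == 0:
        raise ConfigurationError("keyword dictionary is empty")
    a = set(_tokens(pair, "imaging")) & dictionary.terms
    b = set(_tokens(pair, "pathology")) & dictionary.terms
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclass
class KeywordJaccardModel:
    dictionary: KeywordDictionary
    name: str = "keyword_jaccard"

    def score(self, pair: ReportPair) -> float:
        return jaccard_keyword_score(pair, self.dictionary)


# ---------------------------------------------------------------- LSA


@dataclass
class LSAModel:
    vectorizer: TfidfVectorizer | CountVectorizer
    svd: TruncatedSVD
    name: str = "lsa"

    def _vector(self, tokens: Sequence[str]) -> np.ndarray:
        return self.svd.transform(self.vectorizer.transform([list(tokens)]))[0]

    def score(self, pair: ReportPair) -> float:
        return _cosine(self._vector(_tokens(pair, "imaging")), self._vector(_tokens(pair, "pathology")))


def fit_lsa(
    corpus: PairDataset | Sequence[Sequence[str]],
    k: int = 100,
    weighting: str = "tfidf",
    seed: int = 0,
) -> LSAModel:
    """Truncated SVD of the (tf-idf by default) term-document matrix."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    docs = corpus_token_lists(corpus)
    if not docs:
        raise ValueError("corpus is empty")
    vec_cls = TfidfVectorizer if weighting == "tfidf" else CountVectorizer
    vectorizer = vec_cls(analyzer=lambda toks: toks, lowercase=False)
    matrix = vectorizer.fit_transform(docs)
    k_eff = max(1, min(k, matrix.shape[1] - 1, matrix.shape[0] - 1))
    svd = TruncatedSVD(n_components=k_eff, random_state=seed)
    svd.fit(matrix)
    return LSAModel(vectorizer, svd)


def lsa_score(model: LSAModel, pair: ReportPair) -> float:
    return model.score(pair)


# ---------------------------------------------------------------- LDA


@dataclass
class LDAModel:
    vectorizer: CountVectorizer
    lda: LatentDirichletAllocation
    name: str = "lda"

    def topic_vector(self, tokens: Sequence[str]) -> np.ndarray:
        """Topic proportions (nonnegative, summing to 1)."""
        return self.lda.transform(self.vectorizer.transform([list(tokens)]))[0]

    def score(self, pair: ReportPair) -> float:
        return _cosine(
            self.topic_vector(_tokens(pair, "imaging")),
            self.topic_vector(_tokens(pair, "pathology")),
        )


def fit_lda(
    corpus: PairDataset | Sequence[Sequence[str]], n_topics: int = 50, seed: int = 0
) -> LDAModel:
    """Latent Dirichlet Allocation topic mixtures per report."""
    if n_topics < 2:
        raise ValueError(f"n_topics must be >= 2, got {n_topics}")
    docs = corpus_token_lists(corpus)
    if not docs:
        raise ValueError("corpus is empty")
    vectorizer = CountVectorizer(analyzer=lambda toks: toks, lowercase=False)
    matrix = vectorizer.fit_transform(docs)
    lda = LatentDirichletAllocation(n_components=n_topics, random_state=seed)
    lda.fit(matrix)
    return LDAModel(vectorizer, lda)


def lda_score(model: LDAModel, pair: ReportPair) -> float:
    return model.score(pair)


# ---------------------------------------------------------------- Doc2Vec


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


@dataclass
class Doc2VecModel:
    """Distributed-memory paragraph vectors (PV-DM), numpy implementation.

    The context for predicting a center word is the mean of the document
    vector and the surrounding word vectors; training uses negative
    sampling. Unseen documents are embedded at scoring time by gradient
    steps on a fresh document vector with word matrices frozen.
    """

    dim: int
    window: int
    word_to_idx: dict[str, int]
    w_in: np.ndarray  # (V, dim) word input vectors
    w_out: np.ndarray  # (V, dim) output vectors
    noise_cum: np.ndarray  # cumulative unigram^0.75 distribution
    negative: int = 5
    infer_epochs: int = 20
    learning_rate: float = 0.05
    name: str = "doc2vec"

    def infer_vector(self, tokens: Sequence[str], seed: int = 0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        dvec = (rng.random(self.dim) - 0.5) / self.dim
        idxs = [self.word_to_idx[t] for t in tokens if t in self.word_to_idx]
        if not idxs:
            return dvec
        for _ in range(self.infer_epochs):
            for pos, center in enumerate(idxs):
                lo, hi = max(0, pos - self.window), min(len(idxs), pos + self.window + 1)
                ctx = [idxs[j] for j in range(lo, hi) if j != pos]
                mean_in = (dvec + self.w_in[ctx].sum(axis=0)) / (1 + len(ctx))
                negs = np.searchsorted(self.noise_cum, rng.random(self.negative))
                targets = np.concatenate([[center], negs]).astype(int)
                labels = np.zeros(len(targets))
                labels[0] = 1.0
                score = _sigmoid(self.w_out[targets] @ mean_in)
                grad_scale = (score - labels) / (1 + len(ctx))
                dvec -= self.learning_rate * (grad_scale @ self.w_out[targets])
        return dvec

    def score(self, pair: ReportPair) -> float:
        return _cosine(
            self.infer_vector(_tokens(pair, "imaging")),
            self.infer_vector(_tokens(pair, "pathology")),
        )


def fit_doc2vec(
    corpus: PairDataset | Sequence[Sequence[str]],
    dim: int = 128,
    window: int = 5,
    negative: int = 5,
    epochs: int = 10,
    learning_rate: float = 0.05,
    seed: int = 0,
) -> Doc2VecModel:
    docs = corpus_token_lists(corpus)
    if not docs:
        raise ValueError("corpus is empty")
    rng = np.random.default_rng(seed)
    vocab = sorted({t for doc in docs for t in doc})
    word_to_idx = {w: i for i, w in enumerate(vocab)}
    v = len(vocab)
    counts = np.zeros(max(v, 1))
    for doc in docs:
        for t in doc:
            counts[word_to_idx[t]] += 1
    noise = counts**0.75
    noise /= max(noise.sum(), 1e-12)
    noise_cum = np.cumsum(noise)
    w_in = (rng.random((v, dim)) - 0.5) / dim
    w_out = np.zeros((v, dim))
    dvecs = (rng.random((len(docs), dim)) - 0.5) / dim
    for _ in range(epochs):
        for di in rng.permutation(len(docs)):
            idxs = [word_to_idx[t] for t in docs[di]]
            for pos, center in enumerate(idxs):
                lo, hi = max(0, pos - window), min(len(idxs), pos + window + 1)
                ctx = [idxs[j] for j in range(lo, hi) if j != pos]
                denom = 1 + len(ctx)
                mean_in = (dvecs[di] + w_in[ctx].sum(axis=0)) / denom
                negs = np.searchsorted(noise_cum, rng.random(negative))
                targets = np.concatenate([[center], negs]).astype(int)
                labels = np.zeros(len(targets))
                labels[0] = 1.0
                score = _sigmoid(w_out[targets] @ mean_in)
                gout = np.outer(score - labels, mean_in)
                gin = ((score - labels) @ w_out[targets]) / denom
                w_out[targets] -= learning_rate * gout
                dvecs[di] -= learning_rate * gin
                if ctx:
                    w_in[ctx] -= learning_rate * gin
    return Doc2VecModel(
        dim=dim,
        window=window,
        word_to_idx=word_to_idx,
        w_in=w_in,
        w_out=w_out,
        noise_cum=noise_cum,
        negative=negative,
        learning_rate=learning_rate,
    )


def doc2vec_score(model: Doc2VecModel, pair: ReportPair) -> float:
    return model.score(pair)


# ---------------------------------------------------------------- Siamese LSTM


@dataclass
class SiameseLSTMModel:
    """Weight-shared LSTM encoders scored by exp(-Manhattan distance).

    Both reports run through the same LSTM; the similarity is
    exp(-||h_imaging - h_pathology||_1) over the final hidden states, so
    identical token sequences score exactly 1. Trained supervised with
    mean-squared error against the binary overlap label.
    """

    vocab: Vocabulary
    embeddings: np.ndarray  # (V, d), frozen
    W: np.ndarray  # (d, 4H) input weights, gate order i,f,o,g
    U: np.ndarray  # (H, 4H) recurrent weights
    b: np.ndarray  # (4H,)
    max_len: int = 256
    name: str = "siamese_lstm"

    @property
    def hidden(self) -> int:
        return self.U.shape[0]

    def _encode_indices(self, tokens: Sequence[str]) -> list[int]:
        idx = self.vocab.encode(tokens)[: self.max_len]
        return idx if idx else [1]

    def _run(self, x: np.ndarray, lens: np.ndarray, cache: list | None = None) -> np.ndarray:
        """Batched LSTM forward; returns final hidden states (B, H)."""
        B, T = x.shape
        H = self.hidden
        emb = self.embeddings[x]  # (B, T, d)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        for t in range(T):
            m = (t < lens).astype(np.float64)[:, None]  # (B,1)
            z = emb[:, t, :] @ self.W + h @ self.U + self.b
            i, f, o = (_sigmoid(z[:, k * H : (k + 1) * H]) for k in range(3))
            g = np.tanh(z[:, 3 * H : 4 * H])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if cache is not None:
                cache.append(
                    {"x": emb[:, t, :], "h_prev": h, "c_prev": c, "i": i, "f": f, "o": o, "g": g, "tc": tc, "m": m}
                )
            h = m * h_new + (1 - m) * h
            c = m * c_new + (1 - m) * c
        return h

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        idx = self._encode_indices(tokens)
        x = np.asarray([idx], dtype=np.int64)
        return self._run(x, np.array([len(idx)]))[0]

    def score(self, pair: ReportPair) -> float:
        h1 = self.encode(_tokens(pair, "imaging"))
        h2 = self.encode(_tokens(pair, "pathology"))
        return float(np.exp(-np.abs(h1 - h2).sum()))


def _siamese_grads(
    model: SiameseLSTMModel,
    xi: np.ndarray,
    li: np.ndarray,
    xp: np.ndarray,
    lp: np.ndarray,
    y: np.ndarray,
) -> tuple[float, dict[str, np.ndarray]]:
    cache_i: list = []
    cache_p: list = []
    h1 = model._run(xi, li, cache_i)
    h2 = model._run(xp, lp, cache_p)
    diff = h1 - h2
    s = np.exp(-np.abs(diff).sum(axis=1))
    loss = float(np.mean((s - y) ** 2))
    ds = 2.0 * (s - y) / len(y)
    sign = np.sign(diff)
    dh1 = (-ds * s)[:, None] * sign
    dh2 = (ds * s)[:, None] * sign
    grads = {"W": np.zeros_like(model.W), "U": np.zeros_like(model.U), "b": np.zeros_like(model.b)}
    H = model.hidden
    for cache, dh_final in ((cache_i, dh1), (cache_p, dh2)):
        dh = dh_final.copy()
        dc = np.zeros_like(dh)
        for step in reversed(cache):
            m = step["m"]
            dh_new = dh * m
            dc_new = dc * m
            dc_prev_direct = dc * (1 - m)
            do = dh_new * step["tc"]
            dc_new = dc_new + dh_new * step["o"] * (1 - step["tc"] ** 2)
            di = dc_new * step["g"]
            df = dc_new * step["c_prev"]
            dg = dc_new * step["i"]
            dz = np.concatenate(
                [
                    di * step["i"] * (1 - step["i"]),
                    df * step["f"] * (1 - step["f"]),
                    do * step["o"] * (1 - step["o"]),
                    dg * (1 - step["g"] ** 2),
                ],
                axis=1,
            )
            grads["W"] += step["x"].T @ dz
            grads["U"] += step["h_prev"].T @ dz
            grads["b"] += dz.sum(axis=0)
            dh = dh * (1 - m) + dz @ model.U.T
            dc = dc_prev_direct + dc_new * step["f"]
    return loss, grads


def train_siamese_lstm(
    train_set: PairDataset,
    embeddings: EmbeddingMatrix,
    vocab: Vocabulary,
    hidden: int = 64,
    epochs: int = 20,
    learning_rate: float = 0.1,
    batch_size: int = 32,
    max_len: int = 256,
    seed: int = 0,
) -> SiameseLSTMModel:
    """Supervised Manhattan-LSTM training on labeled pairs."""
    pairs = train_set.labeled
    if not pairs:
        raise ValueError("Siamese LSTM requires labeled training pairs")
    rng = np.random.default_rng(seed)
    d = embeddings.dim
    s = np.sqrt(6.0 / (d + 4 * hidden))
    model = SiameseLSTMModel(
        vocab=vocab,
        embeddings=embeddings.weights.copy(),
        W=rng.uniform(-s, s, size=(d, 4 * hidden)),
        U=rng.uniform(-s, s, size=(hidden, 4 * hidden)),
        b=np.zeros(4 * hidden),
        max_len=max_len,
    )
    # forget-gate bias starts positive, the usual LSTM trick for gradient flow
    model.b[hidden : 2 * hidden] = 1.0
    idx_i = [model._encode_indices(_tokens(p, "imaging")) for p in pairs]
    idx_p = [model._encode_indices(_tokens(p, "pathology")) for p in pairs]
    li = np.array([len(q) for q in idx_i])
    lp = np.array([len(q) for q in idx_p])
    ti, tp = li.max(), lp.max()
    xi = np.zeros((len(pairs), ti), dtype=np.int64)
    xp = np.zeros((len(pairs), tp), dtype=np.int64)
    for j, q in enumerate(idx_i):
        xi[j, : len(q)] = q
    for j, q in enumerate(idx_p):
        xp[j, : len(q)] = q
    y = np.array([p.label for p in pairs], dtype=np.float64)
    for _ in range(epochs):
        order = rng.permutation(len(pairs))
        for start in range(0, len(pairs), batch_size):
            sel = order[start : start + batch_size]
            _, grads = _siamese_grads(model, xi[sel], li[sel], xp[sel], lp[sel], y[sel])
            model.W -= learning_rate * grads["W"]
            model.U -= learning_rate * grads["U"]
            model.b -= learning_rate * grads["b"]
    return model


def siamese_score(model: SiameseLSTMModel, pair: ReportPair) -> float:
    return model.score(pair)


# ---------------------------------------------------------------- entity cosine


def entity_cosine_score(
    pair: ReportPair,
    entity_lexicon: KeywordDictionary,
    tagger: Callable[[Sequence[str]], Sequence[str]] | None = None,
) -> float:
    """Cosine of entity-word count vectors; either side empty -> 0.

    By default entities are tokens found in ``entity_lexicon`` (the
    dictionary substitute for a trained NER tagger); pass ``tagger`` to use
    any tokens->entities function instead.
    """
    if tagger is None:
        if len(entity_lexicon) == 0:
            raise ConfigurationError("entity lexicon is empty")
        tagger = lambda toks: [t for t in toks if t in entity_lexicon.terms]
    ents_a = list(tagger(_tokens(pair, "imaging")))
    ents_b = list(tagger(_tokens(pair, "pathology")))
    if not ents_a or not ents_b:
        return 0.0
    vocab = sorted(set(ents_a) | set(ents_b))
    pos = {t: i for i, t in enumerate(vocab)}
    va = np.zeros(len(vocab))
    vb = np.zeros(len(vocab))
    for t in ents_a:
        va[pos[t]] += 1
    for t in ents_b:
        vb[pos[t]] += 1
    return _cosine(va, vb)


@dataclass
class EntityCosineModel:
    lexicon: KeywordDictionary
    name: str = "entity_cosine"

    def score(self, pair: ReportPair) -> float:
        return entity_cosine_score(pair, self.lexicon)
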