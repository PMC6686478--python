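"""Convolutional pair-matcher for imaging/pathology report overlap.

Architecture: each report side is mapped through a (optionally pre-trained)
128-dimensional word-embedding layer, convolved with 1-D filters of window
lengths 3, 4 and 5 (32 filters per window), ReLU-activated and max-pooled
over valid (non-padding) windows, yielding a 96-dimensional feature vector
per report. The two feature vectors are concatenated and passed through a
fully connected ReLU layer and a sigmoid output giving the probability
that the pair describes overlapping body sites. Training minimizes binary
cross-entropy by mini-batch stochastic gradient descent; embedding rows
may be updated during training (the padding row stays frozen at zero).

The implementation is pure numpy with explicit analytic gradients, which
keeps the model single-threaded deterministic and lets the test suite
verify the gradients numerically.
"""

from __future__ import annotations

import io
import json
import warnings
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import (
    OOV_INDEX,
    PAD_INDEX,
    PairDataset,
    ReportPair,
    Vocabulary,
    preprocess_text,
)
from .errors import ConfigurationError
from .ontology_embedding import EmbeddingMatrix

__all__ = ["CNNConfig", "TrainedMatcher", "init_matcher", "train", "encode_report", "forward", "predict_scores"]

_SIDES = ("imaging", "pathology")


@dataclass(frozen=True)
class CNNConfig:
    embed_dim: int = 128
    window_sizes: tuple[int, ...] = (3, 4, 5)
    filters_per_window: int = 32
    hidden_dim: int = 64
    max_len: int = 256
    init_strategy: str = "random"  # random | pretrained | concept
    filter_init: str = "salient"  # salient (embedding-row detectors) | glorot
    embeddings_trainable: bool = True
    share_towers: bool = False
    learning_rate: float = 0.01
    optimizer: str = "sgd"  # sgd | adam (plain SGD is the default)
    momentum: float = 0.0
    weight_decay: float = 0.0  # decoupled L2 on non-embedding weights
    batch_size: int = 64
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.embed_dim, self.filters_per_window, self.hidden_dim, self.max_len) < 1:
            raise ValueError("all dimensions must be positive")
        if any(w < 1 for w in self.window_sizes):
            raise ValueError("window sizes must be positive")
        if max(self.window_sizes) > self.max_len:
            raise ValueError("window sizes must not exceed max_len")

    @property
    def feature_dim(self) -> int:
        return len(self.window_sizes) * self.filters_per_window


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape)


def _salient_filter_banks(
    config: "CNNConfig", embeddings: np.ndarray, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """Initialize each filter as a one-position word detector.

    A filter's weights are a unit-normalized embedding row placed at one
    window offset (zeros elsewhere), so at initialization filter k already
    answers "does a token similar to word k appear here"; max-pooled
    features are then informative from the first gradient step. Rows are
    sampled with probability proportional to their squared norm, which
    favors pre-trained concept rows over the smaller random-initialized
    ones and is uniform when all rows are i.i.d. random. Falls back to
    Glorot draws for a degenerate (all-zero) embedding matrix.
    """
    d = config.embed_dim
    norms2 = (embeddings**2).sum(axis=1)
    total = norms2.sum()
    banks: dict[int, np.ndarray] = {}
    for w in config.window_sizes:
        if total <= 0:
            banks[w] = _glorot(rng, (w * d, config.filters_per_window))
            continue
        bank = np.zeros((w * d, config.filters_per_window))
        rows = rng.choice(len(embeddings), size=config.filters_per_window, p=norms2 / total)
        offsets = rng.integers(0, w, size=config.filters_per_window)
        for f in range(config.filters_per_window):
            vec = embeddings[rows[f]]
            bank[offsets[f] * d : (offsets[f] + 1) * d, f] = vec / np.linalg.norm(vec)
        banks[w] = bank
    return banks


@dataclass
class TrainedMatcher:
    """Parameters + vocabulary + config of the CNN pair-matcher."""

    config: CNNConfig
    vocab: Vocabulary
    params: dict[str, np.ndarray]
    training_log: list[float] = field(default_factory=list)

    # -- encoding -----------------------------------------------------

    def _indices(self, tokens: Sequence[str]) -> list[int]:
        idx = self.vocab.encode(tokens)[: self.config.max_len]
        if not idx:
            idx = [OOV_INDEX]
        return idx

    def _pair_indices(self, pair: ReportPair) -> tuple[list[int], list[int]]:
        out = []
        for side in _SIDES:
            rep = pair.side(side)
            tokens = rep.tokens if rep.tokens else tuple(preprocess_text(rep.raw_text))
            out.append(self._indices(tokens))
        return out[0], out[1]

    def predict_pair(self, pair: ReportPair) -> float:
        return forward(self, pair)

    def predict_scores(self, dataset: PairDataset) -> np.ndarray:
        return predict_scores(self, dataset)

    # -- persistence --------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint: config JSON + vocab TSV + tensors."""
        buf = io.BytesIO()
        np.savez(buf, **self.params, _training_log=np.asarray(self.training_log))
        vocab_tsv = "".join(
            f"{tok}\t{idx}\n"
            for tok, idx in sorted(self.vocab.token_to_index.items(), key=lambda kv: kv[1])
        )
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(asdict(self.config)))
            zf.writestr("vocab.tsv", vocab_tsv)
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "TrainedMatcher":
        with zipfile.ZipFile(path) as zf:
            cfg = json.loads(zf.read("config.json"))
            cfg["window_sizes"] = tuple(cfg["window_sizes"])
            config = CNNConfig(**cfg)
            mapping: dict[str, int] = {}
            for line in zf.read("vocab.tsv").decode("utf-8").splitlines():
                tok, idx = line.rsplit("\t", 1)
                mapping[tok] = int(idx)
            with np.load(io.BytesIO(zf.read("params.npz"))) as npz:
                params = {k: npz[k] for k in npz.files if not k.startswith("_")}
                log = npz["_training_log"].tolist() if "_training_log" in npz.files else []
        return cls(config, Vocabulary(mapping), params, log)


def init_matcher(
    config: CNNConfig, embeddings: EmbeddingMatrix, vocab: Vocabulary
) -> TrainedMatcher:
    """Fresh matcher with seed-reproducible parameter initialization."""
    if embeddings.dim != config.embed_dim:
        raise ConfigurationError(
            f"embedding matrix dim {embeddings.dim} != config embed_dim {config.embed_dim}"
        )
    if embeddings.n_tokens != len(vocab):
        raise ConfigurationError(
            f"embedding matrix has {embeddings.n_tokens} rows but vocabulary has {len(vocab)}"
        )
    rng = np.random.default_rng(config.seed)
    params: dict[str, np.ndarray] = {"E": embeddings.weights.copy()}
    sides = _SIDES[:1] if config.share_towers else _SIDES
    salient_banks = None
    if config.filter_init == "salient":
        salient_banks = _salient_filter_banks(config, embeddings.weights, rng)
    for side in sides:
        for w in config.window_sizes:
            if salient_banks is not None:
                # both towers start from the same detector bank so that the
                # hidden layer can learn cross-side coincidences; the copies
                # are independent parameters and diverge during training
                params[f"Wc_{side}_{w}"] = salient_banks[w].copy()
            else:
                params[f"Wc_{side}_{w}"] = _glorot(
                    rng, (w * config.embed_dim, config.filters_per_window)
                )
            params[f"bc_{side}_{w}"] = np.zeros(config.filters_per_window)
    params["Wh"] = _glorot(rng, (2 * config.feature_dim, config.hidden_dim))
    params["bh"] = np.zeros(config.hidden_dim)
    params["Wo"] = _glorot(rng, (config.hidden_dim, 1))[:, 0]
    params["bo"] = np.zeros(1)
    return TrainedMatcher(config, vocab, params)


def _tower_side(matcher: TrainedMatcher, side: str) -> str:
    return _SIDES[0] if matcher.config.share_towers else side


def _batchify(indices: list[list[int]], min_len: int, max_len: int) -> tuple[np.ndarray, np.ndarray]:
    lens = np.array([min(len(s), max_len) for s in indices], dtype=np.int64)
    pad_to = max(int(lens.max()), min_len)
    x = np.full((len(indices), pad_to), PAD_INDEX, dtype=np.int64)
    for i, seq in enumerate(indices):
        x[i, : lens[i]] = seq[: lens[i]]
    return x, lens


def _encode_batch(
    matcher: TrainedMatcher, x: np.ndarray, lens: np.ndarray, side: str, cache: dict | None = None
):
    """Convolve + masked max-pool one side; optionally record a backward cache."""
    cfg = matcher.config
    tower = _tower_side(matcher, side)
    emb = matcher.params["E"][x]  # (B, L, d)
    B, L, d = emb.shape
    feats = []
    for w in cfg.window_sizes:
        P = L - w + 1
        cols = np.concatenate([emb[:, i : i + P, :] for i in range(w)], axis=2)  # (B,P,w*d)
        z = cols @ matcher.params[f"Wc_{tower}_{w}"] + matcher.params[f"bc_{tower}_{w}"]
        a = _relu(z)
        n_valid = np.clip(lens - w + 1, 1, P)  # short sequences: window 0 only
        invalid = np.arange(P)[None, :] >= n_valid[:, None]
        a_masked = np.where(invalid[:, :, None], -np.inf, a)
        argmax = np.argmax(a_masked, axis=1)  # (B, F)
        pooled = np.take_along_axis(a, argmax[:, None, :], axis=1)[:, 0, :]
        feats.append(pooled)
        if cache is not None:
            cache[(side, w)] = {"cols": cols, "argmax": argmax, "pooled": pooled}
    if cache is not None:
        cache[(side, "x")] = x
        cache[(side, "L")] = L
    return np.concatenate(feats, axis=1)  # (B, feature_dim)


def _forward_batch(
    matcher: TrainedMatcher,
    xi: np.ndarray,
    li: np.ndarray,
    xp: np.ndarray,
    lp: np.ndarray,
    cache: dict | None = None,
) -> np.ndarray:
    fi = _encode_batch(matcher, xi, li, "imaging", cache)
    fp = _encode_batch(matcher, xp, lp, "pathology", cache)
    feats = np.concatenate([fi, fp], axis=1)
    h_pre = feats @ matcher.params["Wh"] + matcher.params["bh"]
    h = _relu(h_pre)
    logit = h @ matcher.params["Wo"] + matcher.params["bo"][0]
    prob = _sigmoid(logit)
    if cache is not None:
        cache["feats"], cache["h_pre"], cache["h"], cache["prob"] = feats, h_pre, h, prob
    return prob


def _loss_and_grads(
    matcher: TrainedMatcher,
    xi: np.ndarray,
    li: np.ndarray,
    xp: np.ndarray,
    lp: np.ndarray,
    y: np.ndarray,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean binary cross-entropy and analytic gradients for one mini-batch."""
    cfg = matcher.config
    cache: dict = {}
    prob = _forward_batch(matcher, xi, li, xp, lp, cache)
    eps = 1e-12
    loss = float(-np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps)))
    B = len(y)
    grads = {k: np.zeros_like(v) for k, v in matcher.params.items()}

    dlogit = (prob - y) / B  # (B,)
    grads["Wo"] = cache["h"].T @ dlogit
    grads["bo"] = np.array([dlogit.sum()])
    dh = np.outer(dlogit, matcher.params["Wo"]) * (cache["h_pre"] > 0)
    grads["Wh"] = cache["feats"].T @ dh
    grads["bh"] = dh.sum(axis=0)
    dfeats = dh @ matcher.params["Wh"].T  # (B, 2*feature_dim)

    F = cfg.filters_per_window
    d = cfg.embed_dim
    for s_idx, side in enumerate(_SIDES):
        tower = _tower_side(matcher, side)
        x = cache[(side, "x")]
        L = cache[(side, "L")]
        d_emb = np.zeros((B, L, d))
        offset = s_idx * cfg.feature_dim
        for w_idx, w in enumerate(cfg.window_sizes):
            c = cache[(side, w)]
            d_pool = dfeats[:, offset + w_idx * F : offset + (w_idx + 1) * F]  # (B,F)
            # ReLU gate at the pooled position: gradient flows iff max > 0
            g = d_pool * (c["pooled"] > 0)
            cols_at = np.take_along_axis(
                c["cols"], c["argmax"][:, :, None], axis=1
            )  # (B, F, w*d) -- window content at each filter's argmax
            grads[f"Wc_{tower}_{w}"] += np.einsum("bfk,bf->kf", cols_at, g)
            grads[f"bc_{tower}_{w}"] += g.sum(axis=0)
            dcols_at = np.einsum("kf,bf->bfk", matcher.params[f"Wc_{tower}_{w}"], g)
            rows = np.arange(B)[:, None]
            for i in range(w):
                np.add.at(d_emb, (rows, c["argmax"] + i), dcols_at[:, :, i * d : (i + 1) * d])
        if cfg.embeddings_trainable:
            np.add.at(grads["E"], x, d_emb)
    grads["E"][PAD_INDEX] = 0.0
    return loss, grads


def train(
    config: CNNConfig, embeddings: EmbeddingMatrix, train_set: PairDataset, vocab: Vocabulary
) -> TrainedMatcher:
    """Fit the matcher on labeled pairs with mini-batch SGD.

    ``training_log[0]`` is the pre-training mean loss; one entry per epoch
    follows. Reproducible under ``config.seed`` at a fixed thread count.
    """
    pairs = train_set.labeled
    if not pairs:
        raise ValueError("training set has no labeled pairs")
    y_all = np.array([p.label for p in pairs], dtype=np.float64)
    if len(set(y_all.tolist())) < 2:
        warnings.warn("training set contains a single class; training proceeds", stacklevel=2)
    matcher = init_matcher(config, embeddings, vocab)
    max_w = max(config.window_sizes)
    idx_i = [matcher._indices(p.imaging.tokens or preprocess_text(p.imaging.raw_text)) for p in pairs]
    idx_p = [matcher._indices(p.pathology.tokens or preprocess_text(p.pathology.raw_text)) for p in pairs]
    xi, li = _batchify(idx_i, max_w, config.max_len)
    xp, lp = _batchify(idx_p, max_w, config.max_len)

    prob0 = _forward_batch(matcher, xi, li, xp, lp)
    eps = 1e-12
    matcher.training_log.append(
        float(-np.mean(y_all * np.log(prob0 + eps) + (1 - y_all) * np.log(1 - prob0 + eps)))
    )

    rng = np.random.default_rng(config.seed + 1)
    velocity = {k: np.zeros_like(v) for k, v in matcher.params.items()}
    second = {k: np.zeros_like(v) for k, v in matcher.params.items()}
    adam_t = 0
    n = len(pairs)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            loss, grads = _loss_and_grads(matcher, xi[sel], li[sel], xp[sel], lp[sel], y_all[sel])
            epoch_losses.append(loss * len(sel))
            adam_t += 1
            for k, gradient in grads.items():
                if k == "E" and not config.embeddings_trainable:
                    continue
                if config.optimizer == "adam":
                    b1, b2, eps_a = 0.9, 0.999, 1e-8
                    velocity[k] = b1 * velocity[k] + (1 - b1) * gradient
                    second[k] = b2 * second[k] + (1 - b2) * gradient**2
                    m_hat = velocity[k] / (1 - b1**adam_t)
                    v_hat = second[k] / (1 - b2**adam_t)
                    matcher.params[k] -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps_a)
                elif config.momentum > 0:
                    velocity[k] = config.momentum * velocity[k] - config.learning_rate * gradient
                    matcher.params[k] += velocity[k]
                else:
                    matcher.params[k] -= config.learning_rate * gradient
                if config.weight_decay > 0 and k != "E" and not k.startswith("b"):
                    matcher.params[k] *= 1.0 - config.learning_rate * config.weight_decay
        matcher.params["E"][PAD_INDEX] = 0.0
        matcher.training_log.append(float(np.sum(epoch_losses) / n))
    return matcher


def encode_report(matcher: TrainedMatcher, tokens: Sequence[str], side: str) -> np.ndarray:
    """Feature vector (|windows| x filters = 96 dims by default) for one report."""
    if side not in _SIDES:
        raise ValueError(f"side must be one of {_SIDES}, got {side!r}")
    idx = matcher._indices(tokens)
    x, lens = _batchify([idx], max(matcher.config.window_sizes), matcher.config.max_len)
    return _encode_batch(matcher, x, lens, side)[0]


def forward(matcher: TrainedMatcher, pair: ReportPair) -> float:
    """Overlap probability in (0,1) for one pair."""
    idx_i, idx_p = matcher._pair_indices(pair)
    max_w = max(matcher.config.window_sizes)
    xi, li = _batchify([idx_i], max_w, matcher.config.max_len)
    xp, lp = _batchify([idx_p], max_w, matcher.config.max_len)
    return float(_forward_batch(matcher, xi, li, xp, lp)[0])


def predict_scores(matcher: TrainedMatcher, dataset: PairDataset) -> np.ndarray:
    """Deterministic batch scores, order-aligned with the dataset."""
    if len(dataset) == 0:
        return np.zeros(0)
    idx_i, idx_p = zip(*(matcher._pair_indices(p) for p in dataset))
    max_w = max(matcher.config.window_sizes)
    xi, li = _batchify(list(idx_i), max_w, matcher.config.max_len)
    xp, lp = _batchify(list(idx_p), max_w, matcher.config.max_len)
    out = []
    for start in range(0, len(dataset), 256):
        sl = slice(start, start + 256)
        out.append(_forward_batch(matcher, xi[sl], li[sl], xp[sl], lp[sl]))
    return np.concatenate(out)
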