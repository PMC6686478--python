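"""Concept embeddings from an anatomy/medical ontology graph.

An ontology (MeSH-like: concepts plus is-a / part-of relations) is read as
an undirected, untyped graph. For every concept a fixed-length uniform
random walk over relation edges is sampled (source node followed by up to 9
neighbor draws, i.e. walks of length 10), the walk corpus is fed to a
skip-gram word2vec model with negative sampling, and the resulting concept
vectors can seed the matcher's word-embedding layer. Concepts that are close
in the ontology (e.g. "parotid gland" under "salivary glands") co-occur in
walks and end up with similar vectors, which is exactly the affiliation
signal a body-site matcher needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .corpus_io import PAD_INDEX, Vocabulary
from .errors import ConfigurationError, SchemaError

__all__ = [
    "OntologyGraph",
    "WalkCorpus",
    "ConceptVectors",
    "EmbeddingMatrix",
    "read_ontology",
    "write_ontology",
    "sample_walks",
    "train_skipgram",
    "nearest_concepts",
    "build_embedding_matrix",
]


@dataclass
class OntologyGraph:
    """Undirected concept-relation graph with deterministic neighbor order."""

    concepts: set[str] = field(default_factory=set)
    edges: set[frozenset[str]] = field(default_factory=set)
    edge_relations: dict[frozenset[str], str] = field(default_factory=dict)

    def add_concept(self, label: str) -> None:
        self.concepts.add(label)

    def add_edge(self, a: str, b: str, relation: str = "related") -> None:
        if a == b:
            raise SchemaError(f"self-loop on concept {a!r} is not allowed")
        self.concepts.add(a)
        self.concepts.add(b)
        key = frozenset((a, b))
        self.edges.add(key)
        self.edge_relations.setdefault(key, relation)

    @property
    def adjacency(self) -> dict[str, tuple[str, ...]]:
        adj: dict[str, list[str]] = {c: [] for c in self.concepts}
        for e in self.edges:
            a, b = sorted(e)
            adj[a].append(b)
            adj[b].append(a)
        return {c: tuple(sorted(ns)) for c, ns in adj.items()}

    def neighbors(self, label: str) -> tuple[str, ...]:
        return self.adjacency[label]

    def __len__(self) -> int:
        return len(self.concepts)


def read_ontology(path: str | Path) -> OntologyGraph:
    """Read a TSV edge list: concept_a<TAB>relation<TAB>concept_b.

    Lines starting with '#' are comments. Duplicate rows collapse to one
    edge; a self-loop row is a schema error.
    """
    graph = OntologyGraph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split("\t")
            if len(parts) != 3:
                raise SchemaError(
                    f"line {lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            a, relation, b = parts
            if a == b:
                raise SchemaError(f"line {lineno}: self-loop on concept {a!r}")
            graph.add_edge(a, b, relation)
    return graph


def write_ontology(graph: OntologyGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# concept_a\trelation\tconcept_b\n")
        for e in sorted(graph.edges, key=sorted):
            a, b = sorted(e)
            fh.write(f"{a}\t{graph.edge_relations.get(e, 'related')}\t{b}\n")


@dataclass
class WalkCorpus:
    sequences: list[list[str]]
    walk_length: int = 10
    walks_per_node: int = 1

    def __len__(self) -> int:
        return len(self.sequences)

    def vocabulary(self) -> list[str]:
        seen: set[str] = set()
        for seq in self.sequences:
            seen.update(seq)
        return sorted(seen)


def sample_walks(
    graph: OntologyGraph,
    walk_length: int = 10,
    walks_per_node: int = 1,
    seed: int = 0,
) -> WalkCorpus:
    """Uniform random walks over relation edges, one source per concept.

    Each walk starts at its source node and repeatedly moves to a uniformly
    chosen direct neighbor of the current node, up to ``walk_length`` nodes
    in total (so the default emits the source plus 9 sampled successors).
    Isolated nodes yield the singleton walk; dead ends stop early.
    """
    if walk_length < 1:
        raise ValueError(f"walk_length must be >= 1, got {walk_length}")
    if len(graph) == 0:
        raise ValueError("graph is empty")
    rng = np.random.default_rng(seed)
    adjacency = graph.adjacency
    sequences: list[list[str]] = []
    for source in sorted(graph.concepts):
        for _ in range(walks_per_node):
            walk = [source]
            current = source
            while len(walk) < walk_length:
                nbrs = adjacency[current]
                if not nbrs:
                    break
                current = nbrs[rng.integers(len(nbrs))]
                walk.append(current)
            sequences.append(walk)
    return WalkCorpus(sequences, walk_length=walk_length, walks_per_node=walks_per_node)


@dataclass
class ConceptVectors:
    """Dense real vectors per concept label, all of one dimension."""

    dimension: int
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for label, vec in self.vectors.items():
            if vec.shape != (self.dimension,):
                raise ConfigurationError(
                    f"vector for {label!r} has shape {vec.shape}, expected ({self.dimension},)"
                )

    def __contains__(self, label: str) -> bool:
        return label in self.vectors

    def __getitem__(self, label: str) -> np.ndarray:
        return self.vectors[label]

    def __len__(self) -> int:
        return len(self.vectors)

    def save_word2vec(self, path: str | Path) -> None:
        """word2vec text format: header "count dim", then one row per label."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vectors)} {self.dimension}\n")
            for label in sorted(self.vectors):
                vals = " ".join(f"{v:.8g}" for v in self.vectors[label])
                fh.write(f"{label} {vals}\n")

    @classmethod
    def load_word2vec(cls, path: str | Path) -> "ConceptVectors":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise SchemaError("word2vec text file must start with 'count dim' header")
            count, dim = int(header[0]), int(header[1])
            vectors: dict[str, np.ndarray] = {}
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise SchemaError(
                        f"row for {parts[0]!r} has {len(parts) - 1} values, expected {dim}"
                    )
                vectors[parts[0]] = np.asarray([float(x) for x in parts[1:]], dtype=np.float64)
        if len(vectors) != count:
            raise SchemaError(f"header promised {count} rows, found {len(vectors)}")
        return cls(dimension=dim, vectors=vectors)


def _cooccurrence_pairs(
    walks: WalkCorpus, label_to_idx: Mapping[str, int], window: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(center, context) index pairs with word2vec-style random window shrink."""
    centers: list[int] = []
    contexts: list[int] = []
    for seq in walks.sequences:
        idxs = [label_to_idx[t] for t in seq]
        for pos, center in enumerate(idxs):
            span = int(rng.integers(1, window + 1))
            lo = max(0, pos - span)
            hi = min(len(idxs), pos + span + 1)
            for other in range(lo, hi):
                if other != pos:
                    centers.append(center)
                    contexts.append(idxs[other])
    return np.asarray(centers, dtype=np.int64), np.asarray(contexts, dtype=np.int64)


def train_skipgram(
    walks: WalkCorpus,
    dimension: int = 128,
    window: int = 5,
    negative: int = 5,
    epochs: int = 5,
    learning_rate: float = 0.025,
    seed: int = 0,
) -> ConceptVectors:
    """Skip-gram with negative sampling (SGNS) over the walk corpus.

    Plain word2vec objective: for each (center, context) co-occurrence
    within the window, push sigmoid(u_ctx . v_center) toward 1 and, for
    ``negative`` unigram^0.75-sampled noise labels, toward 0. Input vectors
    are returned as the concept embeddings.
    """
    if dimension < 1:
        raise ValueError(f"dimension must be >= 1, got {dimension}")
    if not walks.sequences:
        raise ValueError("walk corpus is empty")
    labels = walks.vocabulary()
    label_to_idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    rng = np.random.default_rng(seed)

    counts = np.zeros(n)
    for seq in walks.sequences:
        for t in seq:
            counts[label_to_idx[t]] += 1
    noise = counts**0.75
    noise /= noise.sum()

    w_in = (rng.random((n, dimension)) - 0.5) / dimension
    w_out = np.zeros((n, dimension))

    for _ in range(epochs):
        centers, contexts = _cooccurrence_pairs(walks, label_to_idx, window, rng)
        order = rng.permutation(len(centers))
        centers, contexts = centers[order], contexts[order]
        for start in range(0, len(centers), 512):
            c = centers[start : start + 512]
            o = contexts[start : start + 512]
            b = len(c)
            negs = rng.choice(n, size=(b, negative), p=noise)
            # targets: context (label 1) then negatives (label 0)
            tgt = np.concatenate([o[:, None], negs], axis=1)  # (b, 1+neg)
            v = w_in[c]  # (b, d)
            u = w_out[tgt]  # (b, 1+neg, d)
            score = 1.0 / (1.0 + np.exp(-np.einsum("bd,bkd->bk", v, u)))
            grad = score.copy()
            grad[:, 0] -= 1.0  # dL/dscore_logit
            gv = np.einsum("bk,bkd->bd", grad, u)
            gu = grad[:, :, None] * v[:, None, :]
            np.add.at(w_in, c, -learning_rate * gv)
            np.add.at(w_out, tgt.ravel(), -learning_rate * gu.reshape(-1, dimension))
    return ConceptVectors(dimension=dimension, vectors={lab: w_in[i].copy() for lab, i in label_to_idx.items()})


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def nearest_concepts(vectors: ConceptVectors, query: str, k: int) -> list[str]:
    """The k labels most cosine-similar to ``query`` (query excluded)."""
    if query not in vectors:
        raise KeyError(f"no vector for concept {query!r}")
    q = vectors[query]
    scored = [
        (-_cosine(q, vectors[lab]), lab) for lab in vectors.vectors if lab != query
    ]
    scored.sort()
    return [lab for _, lab in scored[:k]]


@dataclass
class EmbeddingMatrix:
    """V x d matrix of word vectors aligned to Vocabulary indices.

    Row 0 (PAD) is all-zero and stays frozen during matcher training.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.ascontiguousarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 2:
            raise ConfigurationError("embedding matrix must be 2-D")
        if not np.all(np.isfinite(self.weights)):
            raise ConfigurationError("embedding matrix has non-finite entries")

    @property
    def n_tokens(self) -> int:
        return self.weights.shape[0]

    @property
    def dim(self) -> int:
        return self.weights.shape[1]


def build_embedding_matrix(
    vocab: Vocabulary,
    vectors: ConceptVectors | str | Path | None = None,
    embed_dim: int = 128,
    scale: float = 0.25,
    seed: int = 0,
) -> EmbeddingMatrix:
    """Initialize the matcher's embedding layer from a vector source.

    Tokens whose exact string has a source vector (concept label or word2vec
    key) get that vector; every other non-PAD row is an i.i.d.
    uniform(-scale, +scale) draw; PAD is zero. ``vectors=None`` is the
    fully random strategy; a word2vec text file path is the "pretrained"
    strategy; a :class:`ConceptVectors` is the ontology-concept strategy.
    """
    if isinstance(vectors, (str, Path)):
        vectors = ConceptVectors.load_word2vec(vectors)
    if vectors is not None and vectors.dimension != embed_dim:
        raise ConfigurationError(
            f"source vectors have dimension {vectors.dimension}, expected {embed_dim}"
        )
    rng = np.random.default_rng(seed)
    n = len(vocab)
    weights = rng.uniform(-scale, scale, size=(n, embed_dim))
    weights[PAD_INDEX] = 0.0
    if vectors is not None:
        for tok, idx in vocab.token_to_index.items():
            if idx != PAD_INDEX and tok in vectors:
                weights[idx] = vectors[tok]
    return EmbeddingMatrix(weights)
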