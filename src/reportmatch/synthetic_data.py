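"""Synthetic report-pair corpora with planted body-site overlap structure.

Real imaging/pathology pair corpora (and the CMeSH ontology) cannot be
redistributed, so this module fabricates both: a rooted anatomy-like
concept tree, and labeled report pairs whose positive/negative status is
planted from that tree.

Planting rules, mirroring how overlap arises in real report pairs:

* positive — both sides mention the same site concept, or the imaging side
  mentions an ancestor of the pathology side's concept (the imaging report
  names the broad region, the pathology report the precise organ), or, with
  a configurable probability, two sibling leaves ("adjacent structures"
  such as kidney vs. adrenal gland);
* negative — the two concepts' only common ancestor is the root (unrelated
  branches), or, with a configurable probability, the same organ with
  opposite laterality (left vs. right variants of one parent), the classic
  false-positive trap.

Every report is padded with filler tokens drawn from vocabularies shared
across classes and sides, so no filler is label-informative in expectation;
a few number-like measurement tokens are injected into the raw text only,
to be removed by preprocessing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .corpus_io import PairDataset, Report, ReportPair, write_pairs
from .errors import GenerationError
from .ontology_embedding import OntologyGraph, write_ontology

__all__ = ["SynthConfig", "PairProvenance", "GeneratedCorpus", "generate_ontology", "generate_pair", "generate_corpus"]

ROOT_LABEL = "site"
_N_FINDING_TOKENS = 50


@dataclass(frozen=True)
class SynthConfig:
    n_pairs: int = 1000
    positive_rate: float = 0.148
    ontology_depth: int = 4
    branching: int = 3
    tokens_per_report: tuple[int, int] = (15, 60)
    noise_vocab_size: int = 500
    noise_token_rate: float = 0.7
    laterality_confuser_rate: float = 0.1
    adjacency_positive_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("positive_rate", "noise_token_rate", "laterality_confuser_rate", "adjacency_positive_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.ontology_depth < 2:
            raise ValueError("ontology_depth must be >= 2")
        if self.branching < 2:
            raise ValueError("branching must be >= 2")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        lo, hi = self.tokens_per_report
        if not 1 <= lo <= hi:
            raise ValueError("tokens_per_report must be a nondecreasing positive range")


@dataclass(frozen=True)
class PairProvenance:
    """Which site concepts were planted on each side and by which rule."""

    pair_id: str
    rule: str  # same_concept | ancestor_descendant | sibling_leaves | disjoint | laterality
    imaging_sites: tuple[str, ...]
    pathology_sites: tuple[str, ...]


@dataclass
class GeneratedCorpus:
    dataset: PairDataset
    ontology: OntologyGraph
    provenance: list[PairProvenance]
    config: SynthConfig

    def write(self, out_dir: str | Path) -> None:
        """Emit corpus JSONL, ontology TSV and a manifest JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_pairs(self.dataset, out / "corpus.jsonl")
        write_ontology(self.ontology, out / "ontology.tsv")
        manifest = {
            "config": asdict(self.config),
            "provenance": [asdict(p) for p in self.provenance],
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, ensure_ascii=False), encoding="utf-8"
        )


def generate_ontology(depth: int, branching: int, seed: int = 0) -> OntologyGraph:
    """A rooted concept tree with path-encoded labels.

    The root is ``site``; the child c of a node X is labeled ``X_c``. At the
    deepest level the first two children of every parent are the left/right
    laterality variants of that organ (``X_left``, ``X_right``); further
    siblings keep numeric labels and act as distinct adjacent structures.
    Edges are reported undirected. Labels are purely structural, so the
    graph is identical for every seed.
    """
    if depth < 2 or branching < 2:
        raise ValueError("need depth >= 2 and branching >= 2")
    graph = OntologyGraph()
    graph.add_concept(ROOT_LABEL)
    frontier = [ROOT_LABEL]
    for level in range(1, depth + 1):
        nxt: list[str] = []
        for parent in frontier:
            for c in range(branching):
                if level == depth:
                    suffix = {0: "left", 1: "right"}.get(c, str(c))
                else:
                    suffix = str(c)
                child = f"{parent}_{suffix}"
                graph.add_edge(parent, child, "is_a")
                nxt.append(child)
        frontier = nxt
    return graph


@dataclass
class _Tree:
    parent: dict[str, Optional[str]]
    children: dict[str, list[str]]
    depth: dict[str, int]
    leaves: list[str]
    leaf_parents: list[str]

    @classmethod
    def from_graph(cls, graph: OntologyGraph, root: str = ROOT_LABEL) -> "_Tree":
        if root not in graph.concepts:
            raise GenerationError(f"ontology has no root concept {root!r}")
        parent: dict[str, Optional[str]] = {root: None}
        children: dict[str, list[str]] = {c: [] for c in graph.concepts}
        depth = {root: 0}
        queue = [root]
        adjacency = graph.adjacency
        while queue:
            node = queue.pop(0)
            for nb in adjacency[node]:
                if nb not in parent:
                    parent[nb] = node
                    children[node].append(nb)
                    depth[nb] = depth[node] + 1
                    queue.append(nb)
        leaves = sorted(c for c in graph.concepts if not children[c])
        leaf_parents = sorted({parent[l] for l in leaves if parent[l] is not None})
        return cls(parent, children, depth, leaves, leaf_parents)

    def ancestors(self, node: str) -> list[str]:
        out = []
        cur = self.parent[node]
        while cur is not None:
            out.append(cur)
            cur = self.parent[cur]
        return out

    def descendants(self, node: str) -> list[str]:
        out: list[str] = []
        stack = list(self.children[node])
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(self.children[cur])
        return sorted(out)

    def subtree_root_of(self, node: str) -> str:
        """The depth-1 ancestor (or the node itself at depth 1)."""
        cur = node
        while self.depth[cur] > 1:
            cur = self.parent[cur]  # type: ignore[assignment]
        return cur


def _is_lateral_pair(a: str, b: str) -> bool:
    return {a.rsplit("_", 1)[-1], b.rsplit("_", 1)[-1]} == {"left", "right"} and (
        a.rsplit("_", 1)[0] == b.rsplit("_", 1)[0]
    )


def _pick(rng: np.random.Generator, items: list[str]) -> str:
    return items[rng.integers(len(items))]


def _plant_sites(
    tree: _Tree, label: int, config: SynthConfig, rng: np.random.Generator
) -> tuple[str, tuple[str, ...], tuple[str, ...]]:
    """Choose the rule and the site tokens for each side."""
    non_root = sorted(tree.parent.keys() - {None, ROOT_LABEL})
    non_root = [c for c in non_root if tree.depth[c] >= 1]
    if label == 1:
        u = rng.random()
        sib_pairs = [
            (a, b)
            for p in tree.leaf_parents
            for i, a in enumerate(tree.children[p])
            for b in tree.children[p][i + 1 :]
            if not _is_lateral_pair(a, b)
        ]
        if u < config.adjacency_positive_rate and sib_pairs:
            a, b = sib_pairs[rng.integers(len(sib_pairs))]
            if rng.random() < 0.5:
                a, b = b, a
            return "sibling_leaves", (a,), (b,)
        if rng.random() < 0.5:
            c = _pick(rng, non_root)
            return "same_concept", (c,), (c,)
        # imaging gets the ancestor (broad region), pathology the descendant
        with_desc = [c for c in non_root if tree.children[c]]
        anc = _pick(rng, with_desc)
        desc = _pick(rng, tree.descendants(anc))
        return "ancestor_descendant", (anc,), (desc,)
    # negative
    if rng.random() < config.laterality_confuser_rate:
        organs = [
            p
            for p in tree.leaf_parents
            if any(c.endswith("_left") for c in tree.children[p])
            and any(c.endswith("_right") for c in tree.children[p])
        ]
        if organs:
            organ = _pick(rng, organs)
            left = next(c for c in tree.children[organ] if c.endswith("_left"))
            right = next(c for c in tree.children[organ] if c.endswith("_right"))
            if rng.random() < 0.5:
                left, right = right, left
            return "laterality", (organ, left), (organ, right)
    roots = sorted({tree.subtree_root_of(c) for c in non_root})
    if len(roots) < 2:
        raise GenerationError("ontology too small: need >= 2 disjoint top-level branches")
    ra, rb = rng.choice(len(roots), size=2, replace=False)
    branch_a = [roots[ra]] + tree.descendants(roots[ra])
    branch_b = [roots[rb]] + tree.descendants(roots[rb])
    return "disjoint", (_pick(rng, branch_a),), (_pick(rng, branch_b),)


def _render_report(
    sites: tuple[str, ...],
    config: SynthConfig,
    rng: np.random.Generator,
) -> tuple[str, list[str]]:
    """Compose token list (sites + shared fillers) and a raw text with
    measurement strings that preprocessing must strip."""
    lo, hi = config.tokens_per_report
    total = int(rng.integers(lo, hi + 1))
    n_fill = max(total - len(sites), 0)
    fillers = []
    for _ in range(n_fill):
        if rng.random() < config.noise_token_rate:
            fillers.append(f"noise{rng.integers(config.noise_vocab_size)}")
        else:
            fillers.append(f"finding{rng.integers(_N_FINDING_TOKENS)}")
    pool = fillers + list(sites)
    tokens = [pool[i] for i in rng.permutation(len(pool))]
    # raw text additionally carries measurements/punctuation to exercise
    # preprocessing; they never survive into .tokens
    raw = list(tokens)
    for _ in range(int(rng.integers(0, 4))):
        size = f"{rng.integers(1, 40)}.{rng.integers(10)}"
        raw.insert(int(rng.integers(len(raw) + 1)), size)
    if rng.random() < 0.5:
        raw.insert(int(rng.integers(len(raw) + 1)), ",")
    return " ".join(raw), tokens


def generate_pair(
    ontology: OntologyGraph,
    config: SynthConfig,
    label: int,
    rng: np.random.Generator,
    pair_id: str = "pair_0",
    _tree: _Tree | None = None,
) -> tuple[ReportPair, PairProvenance]:
    """Generate one labeled pair; site tokens appear verbatim in .tokens."""
    tree = _tree if _tree is not None else _Tree.from_graph(ontology)
    if len(tree.children[ROOT_LABEL]) < 2:
        raise GenerationError("ontology too small: root needs >= 2 children")
    rule, im_sites, pa_sites = _plant_sites(tree, label, config, rng)
    im_raw, im_tokens = _render_report(im_sites, config, rng)
    pa_raw, pa_tokens = _render_report(pa_sites, config, rng)
    pair = ReportPair(
        pair_id=pair_id,
        imaging=Report(id=f"{pair_id}:imaging", kind="imaging", raw_text=im_raw, tokens=tuple(im_tokens)),
        pathology=Report(id=f"{pair_id}:pathology", kind="pathology", raw_text=pa_raw, tokens=tuple(pa_tokens)),
        label=label,
    )
    return pair, PairProvenance(pair_id, rule, im_sites, pa_sites)


def generate_corpus(config: SynthConfig) -> GeneratedCorpus:
    """n_pairs pairs with Bernoulli(positive_rate) labels, seed-deterministic."""
    rng = np.random.default_rng(config.seed)
    ontology = generate_ontology(config.ontology_depth, config.branching, config.seed)
    tree = _Tree.from_graph(ontology)
    labels = (rng.random(config.n_pairs) < config.positive_rate).astype(int)
    pairs: list[ReportPair] = []
    provenance: list[PairProvenance] = []
    width = len(str(config.n_pairs))
    for i, label in enumerate(labels):
        pair, prov = generate_pair(
            ontology, config, int(label), rng, pair_id=f"pair_{i:0{width}d}", _tree=tree
        )
        pairs.append(pair)
        provenance.append(prov)
    return GeneratedCorpus(PairDataset(pairs), ontology, provenance, config)


def site_labels(ontology: OntologyGraph) -> set[str]:
    """All concept labels of an ontology (the site keyword dictionary)."""
    return set(ontology.concepts)
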