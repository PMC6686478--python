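"""Report-pair data model, preprocessing, vocabulary and (de)serialization.

The classification unit throughout the package is a :class:`ReportPair`:
one free-text imaging report matched with one free-text pathology report,
optionally carrying a binary label (1 = the two reports describe overlapping
body sites). Preprocessing removes punctuation-only tokens, number-like
tokens (measurements such as ``14.6`` or ``1.2*1*1``) and stop words, while
keeping mixed alphanumerics like ``T2`` that may encode anatomy.
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional, Sequence

import numpy as np

from .errors import SchemaError

__all__ = [
    "Report",
    "ReportPair",
    "PairDataset",
    "Vocabulary",
    "StopList",
    "preprocess_text",
    "preprocess_dataset",
    "build_vocabulary",
    "split_dataset",
    "read_pairs",
    "write_pairs",
]

PAD_TOKEN = "<pad>"
OOV_TOKEN = "<oov>"
PAD_INDEX = 0
OOV_INDEX = 1

# Number-like tokens: digits mixed only with decimal points, dimension
# separators and percent/ratio marks. "14.6", "1.2*1*1", "1/2", "50%" are
# removed; "T2" or "S/D" are kept (they contain letters).
_NUMERIC_RE = re.compile(r"[0-9.*×xX%/+\-]*[0-9][0-9.*×xX%/+\-]*$")


def _is_numeric_token(token: str) -> bool:
    return _NUMERIC_RE.fullmatch(token) is not None


def _is_punctuation_token(token: str) -> bool:
    return not any(ch.isalnum() for ch in token)


@dataclass(frozen=True)
class StopList:
    """An exact-string stop-word list."""

    stop_tokens: frozenset[str] = frozenset()

    @classmethod
    def from_file(cls, path: str | Path) -> "StopList":
        """Load one token per line, UTF-8; blank lines ignored."""
        tokens = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            tok = line.strip()
            if tok:
                tokens.append(tok)
        return cls(frozenset(tokens))

    @classmethod
    def demo(cls) -> "StopList":
        """A small English function-word list for demonstrations.

        Real deployments should supply a corpus-appropriate list (the
        default is empty: no token is removed unless asked).
        """
        return cls(
            frozenset(
                "a an and are as at be by for from in is it of on or "
                "that the to was were with".split()
            )
        )

    def __contains__(self, token: str) -> bool:
        return token in self.stop_tokens


def whitespace_segmenter(text: str) -> list[str]:
    """Default segmenter: split on any whitespace (corpus is pre-spaced)."""
    return text.split()


def dictionary_segmenter(lexicon: Iterable[str]) -> Callable[[str], list[str]]:
    """Build a greedy longest-match segmenter over ``lexicon``.

    Intended for unsegmented CJK text: within each whitespace chunk the
    longest lexicon entry anchored at the cursor is consumed; characters not
    starting any entry are emitted as single-character tokens. An external
    segmenter (e.g. jieba) can be adapted by passing any callable with the
    same ``str -> list[str]`` signature to :func:`preprocess_text` instead.
    """
    lex = set(lexicon)
    max_len = max((len(w) for w in lex), default=1)

    def segment(text: str) -> list[str]:
        out: list[str] = []
        for chunk in text.split():
            i = 0
            while i < len(chunk):
                for j in range(min(len(chunk), i + max_len), i, -1):
                    if chunk[i:j] in lex:
                        out.append(chunk[i:j])
                        i = j
                        break
                else:
                    out.append(chunk[i])
                    i += 1
        return out

    return segment


def preprocess_text(
    raw_text: str,
    stoplist: StopList | None = None,
    segmenter: Callable[[str], list[str]] | None = None,
) -> list[str]:
    """Segment ``raw_text`` and drop punctuation, numbers and stop words.

    Order is preserved and duplicates are kept. Idempotent under the
    default whitespace segmenter: re-preprocessing the joined output is a
    no-op.
    """
    if segmenter is None:
        segmenter = whitespace_segmenter
    if stoplist is None:
        stoplist = StopList()
    out = []
    for tok in segmenter(raw_text):
        if not tok or _is_punctuation_token(tok) or _is_numeric_token(tok):
            continue
        if tok in stoplist:
            continue
        out.append(tok)
    return out


@dataclass(frozen=True)
class Report:
    id: str
    kind: str  # "imaging" | "pathology"
    raw_text: str
    tokens: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("imaging", "pathology"):
            raise ValueError(f"unknown report kind: {self.kind!r}")


@dataclass(frozen=True)
class ReportPair:
    pair_id: str
    imaging: Report
    pathology: Report
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.imaging.kind != "imaging":
            raise ValueError("imaging side must have kind='imaging'")
        if self.pathology.kind != "pathology":
            raise ValueError("pathology side must have kind='pathology'")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0/1 or None, got {self.label!r}")

    def side(self, which: str) -> Report:
        if which == "imaging":
            return self.imaging
        if which == "pathology":
            return self.pathology
        raise ValueError(f"unknown side: {which!r}")


@dataclass
class PairDataset:
    pairs: list[ReportPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.pair_id for p in self.pairs]
        if len(ids) != len(set(ids)):
            raise ValueError("pair_ids must be unique")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[ReportPair]:
        return iter(self.pairs)

    def __getitem__(self, i: int) -> ReportPair:
        return self.pairs[i]

    @property
    def labeled(self) -> list[ReportPair]:
        return [p for p in self.pairs if p.label is not None]

    @property
    def positive_rate(self) -> float:
        """Fraction of label=1 among labeled pairs (nan if none labeled)."""
        labeled = self.labeled
        if not labeled:
            return float("nan")
        return sum(p.label for p in labeled) / len(labeled)

    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.labeled], dtype=int)


def preprocess_dataset(
    dataset: PairDataset,
    stoplist: StopList | None = None,
    segmenter: Callable[[str], list[str]] | None = None,
) -> PairDataset:
    """Return a new dataset with ``tokens`` filled on every report."""
    out = []
    for p in dataset:
        out.append(
            replace(
                p,
                imaging=replace(
                    p.imaging,
                    tokens=tuple(preprocess_text(p.imaging.raw_text, stoplist, segmenter)),
                ),
                pathology=replace(
                    p.pathology,
                    tokens=tuple(preprocess_text(p.pathology.raw_text, stoplist, segmenter)),
                ),
            )
        )
    return PairDataset(out)


@dataclass(frozen=True)
class Vocabulary:
    """Token-to-index map with reserved PAD=0 and OOV=1 slots."""

    token_to_index: dict[str, int]

    def __len__(self) -> int:
        return len(self.token_to_index)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    def index(self, token: str) -> int:
        return self.token_to_index.get(token, OOV_INDEX)

    def encode(self, tokens: Sequence[str]) -> list[int]:
        return [self.index(t) for t in tokens]

    @property
    def tokens_by_index(self) -> list[str]:
        inv = {i: t for t, i in self.token_to_index.items()}
        return [inv[i] for i in range(len(inv))]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for tok, idx in sorted(self.token_to_index.items(), key=lambda kv: kv[1]):
                fh.write(f"{tok}\t{idx}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Vocabulary":
        mapping: dict[str, int] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            tok, idx = line.rsplit("\t", 1)
            mapping[tok] = int(idx)
        return cls(mapping)


def build_vocabulary(dataset: PairDataset, min_count: int = 1) -> Vocabulary:
    """Index every token with corpus frequency >= ``min_count``.

    Indices are assigned frequency-descending with lexicographic
    tie-breaking, starting at 2 (0 and 1 are PAD and OOV).
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    counts: Counter[str] = Counter()
    for p in dataset:
        counts.update(p.imaging.tokens)
        counts.update(p.pathology.tokens)
    kept = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    mapping = {PAD_TOKEN: PAD_INDEX, OOV_TOKEN: OOV_INDEX}
    for i, tok in enumerate(kept, start=2):
        mapping[tok] = i
    return Vocabulary(mapping)


def split_dataset(
    dataset: PairDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[PairDataset, PairDataset]:
    """Random disjoint+exhaustive split; train size = round(fraction * N)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0,1), got {train_fraction}")
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 pairs to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    train_idx = sorted(order[:n_train].tolist())
    test_idx = sorted(order[n_train:].tolist())
    return (
        PairDataset([dataset[i] for i in train_idx]),
        PairDataset([dataset[i] for i in test_idx]),
    )


_FIELDS = ("pair_id", "imaging_text", "pathology_text")


def _pair_from_record(rec: dict, where: str) -> ReportPair:
    for key in _FIELDS:
        if key not in rec or rec[key] is None:
            raise SchemaError(f"{where}: missing required field {key!r}")
    label_raw = rec.get("label")
    if label_raw is None or label_raw == "":
        label = None
    else:
        try:
            label = int(label_raw)
        except (TypeError, ValueError):
            raise SchemaError(f"{where}: unknown label value {label_raw!r}") from None
        if label not in (0, 1):
            raise SchemaError(f"{where}: unknown label value {label_raw!r}")
    pid = str(rec["pair_id"])
    return ReportPair(
        pair_id=pid,
        imaging=Report(id=f"{pid}:imaging", kind="imaging", raw_text=str(rec["imaging_text"])),
        pathology=Report(
            id=f"{pid}:pathology", kind="pathology", raw_text=str(rec["pathology_text"])
        ),
        label=label,
    )


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".jsonl", ".ndjson"):
        return "jsonl"
    if suffix == ".csv":
        return "csv"
    raise SchemaError(f"cannot infer format from {path!s}; pass format='jsonl'|'csv'")


def read_pairs(path: str | Path, format: str | None = None) -> PairDataset:
    """Read a pair file (JSONL or CSV; see the package README for schema)."""
    fmt = _infer_format(path, format)
    pairs: list[ReportPair] = []
    if fmt == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"line {lineno}: invalid JSON ({exc})") from None
                pairs.append(_pair_from_record(rec, f"line {lineno}"))
    elif fmt == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not set(_FIELDS) <= set(reader.fieldnames):
                raise SchemaError(
                    f"CSV header must contain {_FIELDS}, got {reader.fieldnames}"
                )
            for recno, rec in enumerate(reader, start=1):
                pairs.append(_pair_from_record(rec, f"record {recno}"))
    else:
        raise SchemaError(f"unknown format {fmt!r}")
    return PairDataset(pairs)


def write_pairs(dataset: PairDataset, path: str | Path, format: str | None = None) -> None:
    """Write the canonical dialect of the pair schema (JSONL or CSV)."""
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for p in dataset:
                rec = {
                    "pair_id": p.pair_id,
                    "imaging_text": p.imaging.raw_text,
                    "pathology_text": p.pathology.raw_text,
                }
                if p.label is not None:
                    rec["label"] = p.label
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    elif fmt == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(list(_FIELDS) + ["label"])
            for p in dataset:
                writer.writerow(
                    [
                        p.pair_id,
                        p.imaging.raw_text,
                        p.pathology.raw_text,
                        "" if p.label is None else p.label,
                    ]
                )
    else:
        raise SchemaError(f"unknown format {fmt!r}")
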