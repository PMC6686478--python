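"""Pair-wise LIME: per-word importances for one side of a report pair.

One side of the pair is held fixed; the other is perturbed by randomly
deleting distinct words (a deleted word vanishes from every position).
The matcher scores every perturbed pair, and a ridge-regularized linear
surrogate on the binary word-presence features, weighted by an
exponential kernel on the cosine distance from the unperturbed mask,
is fitted to the scores. The surrogate's coefficients are the relative
importances: a large positive weight marks a word whose presence drives
the overlap probability up.
"""

from __future__ import annotations

import html
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import Ridge

from .corpus_io import ReportPair, preprocess_text

__all__ = ["LimeConfig", "Explanation", "perturb_masks", "explain_pair", "render_explanation"]

PredictFn = Callable[[ReportPair], float]


@dataclass(frozen=True)
class LimeConfig:
    n_samples: int = 1000
    deletion_prob: float = 0.5
    kernel_width: float = 0.75  # on cosine distance between presence vectors
    ridge_alpha: float = 1e-3
    top_k: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.deletion_prob < 1.0:
            raise ValueError("deletion_prob must be in (0,1)")
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")


@dataclass
class Explanation:
    pair_id: str
    side: str
    prediction_probability: float
    importances: list[tuple[str, float]]  # sorted by weight descending

    def top(self, k: int) -> list[tuple[str, float]]:
        return self.importances[:k]


def perturb_masks(n_words: int, config: LimeConfig, rng: np.random.Generator) -> np.ndarray:
    """n_samples binary masks over distinct-word slots; sample 0 is all-ones.

    Each bit is kept with probability 1 - deletion_prob.
    """
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    masks = (rng.random((config.n_samples, n_words)) >= config.deletion_prob).astype(np.int64)
    masks[0] = 1
    return masks


def _variant_tokens(tokens: Sequence[str], words: list[str], mask: np.ndarray) -> tuple[str, ...]:
    dropped = {w for w, keep in zip(words, mask) if not keep}
    return tuple(t for t in tokens if t not in dropped)


def _kernel_weights(masks: np.ndarray, width: float) -> np.ndarray:
    """exp(-d^2 / width^2) with d the cosine distance to the all-ones mask."""
    n_words = masks.shape[1]
    norms = np.sqrt(masks.sum(axis=1) * n_words)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(norms > 0, masks.sum(axis=1) / norms, 0.0)
    dist = 1.0 - cos
    return np.exp(-(dist**2) / width**2)


def explain_pair(
    predict: PredictFn, pair: ReportPair, side: str, config: LimeConfig = LimeConfig()
) -> Explanation:
    """Fit the local surrogate for one side of the pair.

    ``predict`` is any pair -> probability function (a trained matcher's
    ``predict_pair`` or, in principle, any baseline's score).
    """
    if side not in ("imaging", "pathology"):
        raise ValueError(f"side must be 'imaging' or 'pathology', got {side!r}")
    rep = pair.side(side)
    tokens = rep.tokens if rep.tokens else tuple(preprocess_text(rep.raw_text))
    words: list[str] = []
    for t in tokens:  # distinct words, first-occurrence order
        if t not in words:
            words.append(t)
    if not words:
        raise ValueError(f"{side} report has no words to perturb")
    rng = np.random.default_rng(config.seed)
    masks = perturb_masks(len(words), config, rng)
    scores = np.empty(len(masks))
    from dataclasses import replace

    for i, mask in enumerate(masks):
        variant = replace(rep, tokens=_variant_tokens(tokens, words, mask))
        variant_pair = replace(pair, **{side: variant})
        try:
            scores[i] = predict(variant_pair)
        except Exception as exc:
            raise RuntimeError(f"matcher failed on perturbation mask {mask.tolist()}") from exc
    weights = _kernel_weights(masks, config.kernel_width)
    surrogate = Ridge(alpha=config.ridge_alpha)
    surrogate.fit(masks.astype(np.float64), scores, sample_weight=weights)
    ranked = sorted(zip(words, surrogate.coef_), key=lambda wc: (-wc[1], wc[0]))
    return Explanation(
        pair_id=pair.pair_id,
        side=side,
        prediction_probability=float(scores[0]),
        importances=[(w, float(c)) for w, c in ranked],
    )


def surrogate_r2(
    predict: PredictFn, pair: ReportPair, side: str, config: LimeConfig = LimeConfig()
) -> float:
    """R² of the fitted surrogate on its own perturbation samples."""
    rep = pair.side(side)
    tokens = rep.tokens if rep.tokens else tuple(preprocess_text(rep.raw_text))
    words: list[str] = []
    for t in tokens:
        if t not in words:
            words.append(t)
    rng = np.random.default_rng(config.seed)
    masks = perturb_masks(len(words), config, rng)
    from dataclasses import replace

    scores = np.array(
        [
            predict(replace(pair, **{side: replace(rep, tokens=_variant_tokens(tokens, words, m))}))
            for m in masks
        ]
    )
    weights = _kernel_weights(masks, config.kernel_width)
    surrogate = Ridge(alpha=config.ridge_alpha)
    surrogate.fit(masks.astype(np.float64), scores, sample_weight=weights)
    return float(surrogate.score(masks.astype(np.float64), scores, sample_weight=weights))


def render_explanation(
    explanations: tuple[Explanation, Explanation],
    path: str | Path,
    top_k: int = 12,
) -> tuple[Path, Path]:
    """Write a two-sided TSV and an HTML view of one pair's explanations.

    ``path`` is a prefix; ``<path>.tsv`` and ``<path>.html`` are written.
    Rows are sorted by importance descending within each side.
    """
    exps = {e.side: e for e in explanations}
    if set(exps) != {"imaging", "pathology"}:
        raise ValueError("need one explanation per side")
    if len({e.pair_id for e in explanations}) != 1:
        raise ValueError("explanations must describe the same pair")
    base = Path(path)
    tsv_path = base.with_suffix(".tsv")
    html_path = base.with_suffix(".html")
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("pair_id\tside\tword\timportance\n")
        for side in ("imaging", "pathology"):
            e = exps[side]
            for word, weight in e.top(top_k):
                fh.write(f"{e.pair_id}\t{side}\t{word}\t{weight:.6g}\n")

    def _span(word: str, weight: float, max_abs: float) -> str:
        alpha = 0.0 if max_abs == 0 else min(abs(weight) / max_abs, 1.0)
        color = "46, 139, 87" if weight >= 0 else "178, 34, 34"
        return (
            f'<span style="background-color: rgba({color}, {alpha:.2f}); '
            f'padding:1px 3px; margin:1px;">{html.escape(word)} ({weight:.3f})</span>'
        )

    parts = [
        "<html><head><meta charset='utf-8'><title>Pair explanation</title></head><body>",
        f"<h2>Pair {html.escape(explanations[0].pair_id)}</h2>",
    ]
    for side in ("imaging", "pathology"):
        e = exps[side]
        rows = e.top(top_k)
        max_abs = max((abs(w) for _, w in rows), default=0.0)
        parts.append(
            f"<h3>{side} report (prediction probability = {e.prediction_probability:.3f})</h3><p>"
        )
        parts.extend(_span(word, weight, max_abs) for word, weight in rows)
        parts.append("</p>")
    parts.append("</body></html>")
    html_path.write_text("\n".join(parts), encoding="utf-8")
    return tsv_path, html_path
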