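"""Evaluation against a gold standard.

Predictions are scored at two levels and in two modes:

* **mention level**: individual spans.  *Strict* requires identical
  character offsets; *lenient* accepts any overlap, matched one-to-one
  (greedy on largest overlap, then leftmost, so one prediction never
  pays for two gold mentions).
* **document level**: the set of unique resource names per article,
  compared case-sensitively (strict) or case-insensitively (lenient)
  after name normalisation.

From the confusion counts the standard metrics follow:

    P = TP / (TP + FP)    R = TP / (TP + FN)    F = 2PR / (P + R)

with the convention that a zero denominator yields 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .doc_resolution import normalize_name

__all__ = [
    "ConfusionCounts",
    "EvaluationScores",
    "match_mentions",
    "match_documents",
    "compute_scores",
    "evaluate_mentions_corpus",
]

Span = tuple[int, int]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.FN + other.FN)


@dataclass(frozen=True)
class EvaluationScores:
    precision: float
    recall: float
    f_measure: float
    level: str = "mention"
    mode: str = "strict"


def match_mentions(
    gold: Sequence[Span], predicted: Sequence[Span], mode: str = "strict"
) -> ConfusionCounts:
    """Confusion counts for one document's mention spans.

    Strict: identical (start, end) pairs.  Lenient: one-to-one matching
    of overlapping spans, preferring the pair with the largest overlap
    (ties broken leftmost).
    """
    if mode == "strict":
        g, p = Counter(gold), Counter(predicted)
        tp = sum((g & p).values())
        return ConfusionCounts(tp, len(predicted) - tp, len(gold) - tp)
    if mode != "lenient":
        raise ValueError(f"unknown mode: {mode!r}")

    pairs = []
    for gi, gspan in enumerate(gold):
        for pi, pspan in enumerate(predicted):
            ov = min(gspan[1], pspan[1]) - max(gspan[0], pspan[0])
            if ov > 0:
                pairs.append((-ov, gspan[0], pspan[0], gi, pi))
    pairs.sort()
    matched_g: set[int] = set()
    matched_p: set[int] = set()
    tp = 0
    for _, _, _, gi, pi in pairs:
        if gi in matched_g or pi in matched_p:
            continue
        matched_g.add(gi)
        matched_p.add(pi)
        tp += 1
    return ConfusionCounts(tp, len(predicted) - tp, len(gold) - tp)


def match_documents(
    gold: Mapping[str, Iterable[str]],
    predicted: Mapping[str, Iterable[str]],
    mode: str = "strict",
) -> ConfusionCounts:
    """Document-level confusion counts over per-document name sets,
    summed across documents.  Names are normalised; lenient comparison
    additionally ignores case."""
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode: {mode!r}")
    total = ConfusionCounts()
    for doc_id in set(gold) | set(predicted):
        g = {_doc_key(n, mode) for n in gold.get(doc_id, ())}
        p = {_doc_key(n, mode) for n in predicted.get(doc_id, ())}
        total = total + ConfusionCounts(
            len(g & p), len(p - g), len(g - p)
        )
    return total


def _doc_key(name: str, mode: str) -> str:
    key = normalize_name(name)
    return key.casefold() if mode == "lenient" else key


def compute_scores(
    counts: ConfusionCounts, level: str = "mention", mode: str = "strict"
) -> EvaluationScores:
    """Precision, recall and F-measure from confusion counts."""
    p = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else 0.0
    r = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else 0.0
    f = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return EvaluationScores(p, r, f, level, mode)


def evaluate_mentions_corpus(
    gold_by_doc: Mapping[str, Sequence[Span]],
    pred_by_doc: Mapping[str, Sequence[Span]],
    mode: str = "strict",
) -> ConfusionCounts:
    """Mention-level counts summed over a corpus."""
    total = ConfusionCounts()
    for doc_id in set(gold_by_doc) | set(pred_by_doc):
        total = total + match_mentions(
            gold_by_doc.get(doc_id, ()), pred_by_doc.get(doc_id, ()), mode
        )
    return total
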