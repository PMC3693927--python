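"""Cross-mention weak clues, thresholding and document-level propagation.

Some mentions carry no strong local evidence but co-occur with weak
indicators ("we *used* X", "the X *platform*").  These firings are
tallied per resource name over the whole document, multiplied by the
weak score and added to *every* mention of that name.  Candidates whose
final score strictly exceeds the threshold are accepted; each accepted
surface is then propagated — every verbatim, token-boundary occurrence
of it elsewhere in the document becomes a tagged mention even where no
clue fired.  The result is one :class:`ResourceRecord` per normalised
name: the document-level resource list.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from .candidates import CandidateMention
from .lexicon import Lexicon
from .local_clues import ClueConfig
from .preprocess import Sentence, Token

__all__ = [
    "Mention",
    "ResourceRecord",
    "WeakTally",
    "normalize_name",
    "tally_weak_clues",
    "apply_weak_scores",
    "threshold_and_propagate",
]

# window (in tokens, each side) within which a weak indicator counts
WEAK_WINDOW = 4

_DASHES = re.compile(r"[-–]")
_WS = re.compile(r"\s+")


@dataclass(frozen=True)
class Mention:
    """One tagged mention in the final document annotation."""

    start: int
    end: int
    surface: str
    score: float
    propagated: bool


@dataclass
class ResourceRecord:
    """A document-level resource entry grouping all mentions of one name."""

    normalized_name: str
    mention_spans: list[tuple[int, int]] = field(default_factory=list)
    max_score: float = 0.0

    @property
    def mention_count(self) -> int:
        return len(self.mention_spans)


@dataclass(frozen=True)
class WeakTally:
    normalized_name: str
    weak_count: int


def normalize_name(surface: str) -> str:
    """Canonical name form: dashes to spaces, whitespace collapsed,
    case preserved (document-level grouping is case-sensitive)."""
    if not surface:
        raise ValueError("empty surface")
    return _WS.sub(" ", _DASHES.sub(" ", surface)).strip()


def tally_weak_clues(
    candidates: Sequence[CandidateMention],
    tokens: Sequence[Token],
    sentences: Sequence[Sentence],
    lexicon: Lexicon,
) -> dict[str, int]:
    """Count weak-indicator firings per normalised name over the document.

    A firing is a weak-indicator token inside the same sentence within
    ``WEAK_WINDOW`` tokens of a candidate (the candidate's own tokens
    do not count against themselves).
    """
    tallies: dict[str, int] = {}
    for cand in candidates:
        name = cand.normalized_name or normalize_name(cand.surface)
        cand.normalized_name = name
        sent = sentences[cand.sentence_index]
        lo = max(sent.tok_start, cand.tok_start - WEAK_WINDOW)
        hi = min(sent.tok_end, cand.tok_end + WEAK_WINDOW)
        fired = sum(
            1
            for k in range(lo, hi)
            if not (cand.tok_start <= k < cand.tok_end)
            and lexicon.is_weak(tokens[k].surface)
        )
        if fired:
            tallies[name] = tallies.get(name, 0) + fired
        else:
            tallies.setdefault(name, 0)
    return tallies


def apply_weak_scores(
    candidates: Sequence[CandidateMention],
    tallies: dict[str, int],
    config: ClueConfig,
) -> None:
    """final = local + weak_count(name) * weak_score, for every mention."""
    for cand in candidates:
        name = cand.normalized_name or normalize_name(cand.surface)
        cand.normalized_name = name
        cand.final_score = cand.local_score + tallies.get(name, 0) * config.Weak


def threshold_and_propagate(
    candidates: Sequence[CandidateMention],
    tokens: Sequence[Token],
    text: str,
    config: ClueConfig,
) -> tuple[list[Mention], list[ResourceRecord]]:
    """Accept, resolve overlaps, and propagate names document-wide.

    Acceptance requires ``final_score`` strictly greater than the
    threshold.  Among overlapping accepted spans the highest score wins
    (ties: longer span, then leftmost).  Every verbatim case-sensitive
    token-boundary occurrence of an accepted surface is then added as a
    propagated mention carrying the accepting name's best score.
    """
    accepted = [c for c in candidates if c.final_score > config.threshold]
    accepted.sort(key=lambda c: (-c.final_score, -(c.end - c.start), c.start))
    kept: list[CandidateMention] = []
    for cand in accepted:
        if not any(_overlaps(cand.span, k.span) for k in kept):
            kept.append(cand)

    best_score: dict[str, float] = {}
    surfaces: dict[str, str] = {}  # surface -> normalized name
    for cand in kept:
        name = cand.normalized_name or normalize_name(cand.surface)
        surfaces[cand.surface] = name
        best_score[name] = max(best_score.get(name, float("-inf")),
                               cand.final_score)

    mentions: list[Mention] = []
    taken: list[tuple[int, int]] = []
    accepted_spans = {c.span for c in kept}
    for cand in sorted(kept, key=lambda c: c.start):
        mentions.append(Mention(cand.start, cand.end, cand.surface,
                                cand.final_score, propagated=False))
        taken.append(cand.span)

    for start, end, surface in _scan_surfaces(tokens, text, set(surfaces)):
        if (start, end) in accepted_spans:
            continue
        if any(_overlaps((start, end), span) for span in taken):
            continue
        name = surfaces[surface]
        mentions.append(Mention(start, end, surface, best_score[name],
                                propagated=True))
        taken.append((start, end))

    mentions.sort(key=lambda m: (m.start, m.end))

    records: dict[str, ResourceRecord] = {}
    for m in mentions:
        name = surfaces[m.surface]
        rec = records.setdefault(name, ResourceRecord(name))
        rec.mention_spans.append((m.start, m.end))
        rec.max_score = max(rec.max_score, m.score)
    for rec in records.values():
        rec.mention_spans.sort()
    return mentions, sorted(records.values(), key=lambda r: r.normalized_name)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _scan_surfaces(
    tokens: Sequence[Token], text: str, surfaces: set[str]
) -> list[tuple[int, int, str]]:
    """Longest-match scan for verbatim occurrences of accepted surfaces,
    aligned to token boundaries."""
    if not surfaces:
        return []
    max_len = max(len(s) for s in surfaces)
    hits: list[tuple[int, int, str]] = []
    i, n = 0, len(tokens)
    while i < n:
        start = tokens[i].start
        best_j = -1
        best_surface = ""
        j = i
        while j < n and tokens[j].end - start <= max_len:
            candidate = text[start : tokens[j].end]
            if candidate in surfaces:
                best_j, best_surface = j, candidate
            j += 1
        if best_j >= 0:
            hits.append((start, tokens[best_j].end, best_surface))
            i = best_j + 1
        else:
            i += 1
    return hits
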