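"""Candidate mention generation.

Resource names in this literature are, almost always, contiguous runs
of nouns, so candidates come from two streams: dictionary matches and
maximal noun-only token runs.  A run ending in a descriptor keyword
("The PolyFreq *program*") is trimmed to the name part and the trimmed
head is remembered for the good-head clue; likewise a trailing
blacklisted head ("FASTA *format*") feeds the negative-head clue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .lexicon import DictMatch, Lexicon
from .preprocess import Sentence, Token

__all__ = ["CandidateMention", "extract_noun_runs", "merge_candidates",
           "MAX_RUN_TOKENS"]

# Noun runs longer than this many tokens are discarded as improbable names.
MAX_RUN_TOKENS = 6


@dataclass
class CandidateMention:
    """A candidate name span, later decorated with clue events and scores."""

    start: int
    end: int
    surface: str
    sentence_index: int
    origin: str  # "dictionary" | "noun_run" | "both"
    tok_start: int  # document-wide token indices (half-open)
    tok_end: int
    pending_head: str | None = None       # trimmed positive-keyword head
    pending_neg_head: str | None = None   # trimmed blacklisted head
    dict_sources: set[str] = field(default_factory=set)
    clue_events: list = field(default_factory=list)   # list[ClueEvent]
    local_score: float = 0.0
    final_score: float = 0.0
    normalized_name: str = ""

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def extract_noun_runs(
    sentence: Sentence,
    tokens: Sequence[Token],
    text: str,
    lexicon: Lexicon,
    max_run: int = MAX_RUN_TOKENS,
) -> list[CandidateMention]:
    """Maximal noun-only token runs of one sentence as candidates.

    Runs made up solely of descriptor keywords are discarded (they
    describe resources, they do not name them).  A trailing keyword or
    blacklisted head is stripped off and recorded on the candidate.
    """
    candidates: list[CandidateMention] = []
    i = sentence.tok_start
    while i < sentence.tok_end:
        if not tokens[i].is_noun:
            i += 1
            continue
        j = i
        while j < sentence.tok_end and tokens[j].is_noun:
            j += 1
        run_start, run_end = i, j
        i = j
        if run_end - run_start > max_run:
            continue
        if all(lexicon.is_keyword(tokens[k].surface) for k in range(run_start, run_end)):
            continue
        pending_head = pending_neg = None
        last = tokens[run_end - 1].surface
        if run_end - run_start > 1:
            if lexicon.is_keyword(last):
                pending_head = last
                run_end -= 1
            elif lexicon.is_neg_head(last):
                pending_neg = last
                run_end -= 1
            elif lexicon.is_weak(last):
                # ambiguous weak head ("the X platform"): the name is the
                # run minus the head; the head stays in the weak window
                run_end -= 1
        start = tokens[run_start].start
        end = tokens[run_end - 1].end
        candidates.append(
            CandidateMention(
                start=start,
                end=end,
                surface=text[start:end],
                sentence_index=sentence.index,
                origin="noun_run",
                tok_start=run_start,
                tok_end=run_end,
                pending_head=pending_head,
                pending_neg_head=pending_neg,
            )
        )
    return candidates


def merge_candidates(
    noun_runs: Sequence[CandidateMention],
    dict_matches: Sequence[DictMatch],
    sentences: Sequence[Sentence],
    text: str,
) -> list[CandidateMention]:
    """Merge the two candidate streams for a document.

    A dictionary match whose span exactly equals a noun run collapses
    into one candidate (origin ``both``); overlapping-but-unequal spans
    both survive — overlap resolution happens at threshold time.
    Dictionary matches crossing a sentence boundary are dropped.
    """
    by_span = {c.span: c for c in noun_runs}
    merged = list(noun_runs)
    for m in dict_matches:
        existing = by_span.get((m.start, m.end))
        if existing is not None:
            if existing.origin == "noun_run":
                existing.origin = "both"
            existing.dict_sources.add(m.source)
            continue
        sent = _sentence_of(m.start, m.end, sentences)
        if sent is None:
            continue
        cand = CandidateMention(
            start=m.start,
            end=m.end,
            surface=m.surface,
            sentence_index=sent.index,
            origin="dictionary",
            tok_start=m.tok_start,
            tok_end=m.tok_end,
        )
        cand.dict_sources.add(m.source)
        by_span[cand.span] = cand
        merged.append(cand)
    merged.sort(key=lambda c: (c.start, -(c.end - c.start)))
    return merged


def _sentence_of(start: int, end: int, sentences: Sequence[Sentence]) -> Sentence | None:
    for s in sentences:
        if start >= s.start and end <= s.end:
            return s
    return None
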