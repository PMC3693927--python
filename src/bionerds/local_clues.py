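"""Local clue firing and mention-level scoring.

Each candidate mention accumulates clue events — positive evidence
(dictionary hit, title pattern, Hearst/enumeration membership, good
head noun, trailing version number, reference, URL, helpful casing)
and negative evidence (English word, known acronym, blacklisted head,
lower case, partial word, Bioconductor homonymy).  The mention score is
the sum of the fired clue scores plus the number of *distinct* positive
clue types times the compound factor.  The weak (cross-mention) clue is
deliberately absent here: it is aggregated document-wide in
:mod:`bionerds.doc_resolution`.

Default scores::

    Dictionary     +5.50      Bioconductor     -1.75
    Title          +4.00      DictionaryWord   -4.00
    Enum           +3.00      KnownAcronym    -15.00
    Hearst         +4.00      NegativeHead    -15.00
    GoodHead       +2.00      LowerCase        -1.00
    Version        +3.00      PartialWord     -15.00
    Reference      +1.00
    HyperLink      +1.50      CompoundFactor   +0.50
    MixedCase      +1.00      Weak             +0.50
    UpperCase      +0.50      threshold        +5.00

All of these are tunable through :class:`ClueConfig` (flat
``key = value`` config files are supported); the defaults are the
empirically tuned operating point.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path
from typing import Sequence

from .candidates import CandidateMention
from .lexicon import Lexicon
from .preprocess import Sentence, Token

__all__ = [
    "Clue",
    "ClueEvent",
    "ClueConfig",
    "POSITIVE_CLUES",
    "fire_local_clues",
    "score_mention",
    "fire_title_clue",
    "fire_list_clues",
    "fire_head_clues",
    "fire_context_clues",
    "fire_orthographic_and_negative_clues",
]


class Clue(str, enum.Enum):
    DICTIONARY = "Dictionary"
    TITLE = "Title"
    ENUM = "Enum"
    HEARST = "Hearst"
    GOOD_HEAD = "GoodHead"
    VERSION = "Version"
    REFERENCE = "Reference"
    HYPERLINK = "HyperLink"
    MIXED_CASE = "MixedCase"
    UPPER_CASE = "UpperCase"
    BIOCONDUCTOR = "Bioconductor"
    DICTIONARY_WORD = "DictionaryWord"
    KNOWN_ACRONYM = "KnownAcronym"
    NEGATIVE_HEAD = "NegativeHead"
    LOWER_CASE = "LowerCase"
    PARTIAL_WORD = "PartialWord"
    WEAK = "Weak"


POSITIVE_CLUES = frozenset({
    Clue.DICTIONARY, Clue.TITLE, Clue.ENUM, Clue.HEARST, Clue.GOOD_HEAD,
    Clue.VERSION, Clue.REFERENCE, Clue.HYPERLINK, Clue.MIXED_CASE,
    Clue.UPPER_CASE,
})


@dataclass(frozen=True)
class ClueEvent:
    clue: Clue
    score_contribution: float
    evidence_span: tuple[int, int] | None = None


@dataclass
class ClueConfig:
    """Scores per clue, the compound factor and the acceptance threshold."""

    Dictionary: float = 5.50
    Title: float = 4.00
    Enum: float = 3.00
    Hearst: float = 4.00
    GoodHead: float = 2.00
    Version: float = 3.00
    Reference: float = 1.00
    HyperLink: float = 1.50
    MixedCase: float = 1.00
    UpperCase: float = 0.50
    Bioconductor: float = -1.75
    DictionaryWord: float = -4.00
    KnownAcronym: float = -15.00
    NegativeHead: float = -15.00
    LowerCase: float = -1.00
    PartialWord: float = -15.00
    CompoundFactor: float = 0.50
    Weak: float = 0.50
    threshold: float = 5.00

    def score_of(self, clue: Clue) -> float:
        return getattr(self, clue.value)

    @classmethod
    def from_file(cls, path: str | Path) -> "ClueConfig":
        """Read a flat ``key = value`` config; unset keys keep defaults."""
        cfg = cls()
        known = {f.name for f in dataclass_fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown clue {key!r}")
            setattr(cfg, key, float(value))
        return cfg

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dataclass_fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")


_TITLE_SEPARATORS = frozenset({":", "-", "–", "—"})
_VERSION_SHAPE = re.compile(r"^[vV]?\d+(?:\.\d+)*$")
_NUMBER_SHAPE = re.compile(r"^\d+(?:\.\d+)*$")
_URL_PREFIX = re.compile(r"^(?:https?://|ftp://|www\.)")
_LIST_SEPARATORS = frozenset({",", "and", "or"})


def _add_event(cand: CandidateMention, clue: Clue, config: ClueConfig,
               span: tuple[int, int] | None = None) -> None:
    # each clue type fires at most once per candidate
    if any(ev.clue is clue for ev in cand.clue_events):
        return
    cand.clue_events.append(ClueEvent(clue, config.score_of(clue), span))


# ---------------------------------------------------------------------------
# individual clue rules

def fire_title_clue(
    cand: CandidateMention,
    tokens: Sequence[Token],
    sentences: Sequence[Sentence],
    text: str,
    lexicon: Lexicon,
    config: ClueConfig,
) -> None:
    """"Name: a Keyword for ..." title pattern.

    Fires iff the candidate opens the title (offset 0), is immediately
    followed by a separator (colon or dash) and the rest of the title
    contains at least one descriptor keyword.
    """
    if cand.sentence_index != 0 or cand.start != 0 or not sentences:
        return
    title = sentences[0]
    if cand.tok_end >= title.tok_end:
        return
    sep = tokens[cand.tok_end]
    if sep.surface not in _TITLE_SEPARATORS:
        return
    remainder = tokens[cand.tok_end + 1 : title.tok_end]
    if any(lexicon.is_keyword(t.surface) for t in remainder):
        _add_event(cand, Clue.TITLE, config, (cand.start, title.end))


def fire_head_clues(
    cand: CandidateMention,
    tokens: Sequence[Token],
    sentences: Sequence[Sentence],
    lexicon: Lexicon,
    config: ClueConfig,
) -> None:
    """Good head ("The PolyFreq program") and blacklisted head
    ("FASTA format") on the token immediately after the candidate."""
    nxt: str | None = None
    sent = sentences[cand.sentence_index]
    if cand.tok_end < sent.tok_end:
        nxt = tokens[cand.tok_end].surface
    if cand.pending_head or (nxt is not None and lexicon.is_keyword(nxt)):
        _add_event(cand, Clue.GOOD_HEAD, config)
    if cand.pending_neg_head or (nxt is not None and lexicon.is_neg_head(nxt)):
        _add_event(cand, Clue.NEGATIVE_HEAD, config)


def fire_context_clues(
    cand: CandidateMention,
    tokens: Sequence[Token],
    sentences: Sequence[Sentence],
    config: ClueConfig,
) -> None:
    """Version number, citation and URL following the candidate."""
    sent = sentences[cand.sentence_index]
    after = tokens[cand.tok_end : sent.tok_end]

    # Version: the next non-punctuation token looks like "2.0" / "v1.2",
    # or is the word "version"/"v" followed by a number.
    for k, tok in enumerate(after):
        if not tok.surface[:1].isalnum():
            continue
        if _VERSION_SHAPE.match(tok.surface):
            _add_event(cand, Clue.VERSION, config, (tok.start, tok.end))
        elif tok.surface.lower() in {"v", "ver", "version"}:
            for tok2 in after[k + 1 :]:
                if not tok2.surface[:1].isalnum():
                    continue
                if _NUMBER_SHAPE.match(tok2.surface):
                    _add_event(cand, Clue.VERSION, config, (tok2.start, tok2.end))
                break
        break

    # Reference: "[3]" / "[3,7]" within 2 tokens, or "(Name et al., year)".
    for k, tok in enumerate(after[:2]):
        if tok.surface == "[":
            body = after[k + 1 : k + 9]
            inner = []
            for tok2 in body:
                if tok2.surface == "]":
                    if inner and all(
                        t.surface.isdigit() or t.surface == "," for t in inner
                    ):
                        _add_event(cand, Clue.REFERENCE, config,
                                   (tok.start, tok2.end))
                    break
                inner.append(tok2)
            break
        if tok.surface == "(":
            window = [t.surface for t in after[k + 1 : k + 8]]
            if "et" in window and ("al" in window or "al." in window):
                _add_event(cand, Clue.REFERENCE, config)
            break

    # HyperLink: a URL token within 3 tokens.
    for tok in after[:3]:
        if _URL_PREFIX.match(tok.surface):
            _add_event(cand, Clue.HYPERLINK, config, (tok.start, tok.end))
            break


def _case_class(surface: str) -> str | None:
    letters = [c for c in surface if c.isalpha()]
    if not letters:
        return None
    if all(c.isupper() for c in letters):
        return "upper" if len(letters) >= 2 else None
    if all(c.islower() for c in letters):
        return "lower"
    if any(c.isupper() for c in surface[1:]):
        return "mixed"
    return None  # single capitalised word ("Blast"): neutral


_CASE_CLUE = {"upper": Clue.UPPER_CASE, "mixed": Clue.MIXED_CASE,
              "lower": Clue.LOWER_CASE}


def fire_orthographic_and_negative_clues(
    cand: CandidateMention,
    tokens: Sequence[Token],
    text: str,
    lexicon: Lexicon,
    config: ClueConfig,
) -> None:
    """Casing boost/penalty, English-word and acronym penalties, partial
    word filtering and the Bioconductor homonymy penalty."""
    own = tokens[cand.tok_start : cand.tok_end]

    # exactly one case clue; multi-token candidates vote by majority
    classes = [_case_class(t.surface) for t in own]
    if len(own) == 1:
        cls = classes[0]
    else:
        tally: dict[str, int] = {}
        for c in classes:
            if c is not None:
                tally[c] = tally.get(c, 0) + 1
        cls = None
        if tally:
            best = max(tally.values())
            winners = [c for c, n in tally.items() if n == best]
            if len(winners) == 1 and best * 2 > len(own):
                cls = winners[0]
    if cls is not None:
        _add_event(cand, _CASE_CLUE[cls], config)

    if all(lexicon.contains("english", t.surface) for t in own):
        _add_event(cand, Clue.DICTIONARY_WORD, config)
    if lexicon.contains("acronym", cand.surface):
        _add_event(cand, Clue.KNOWN_ACRONYM, config)

    # partial word: flanked without whitespace by an alphanumeric or a
    # ":<digit>" identifier continuation (the "GO" of "GO:001234")
    before = text[cand.start - 1] if cand.start > 0 else ""
    after1 = text[cand.end] if cand.end < len(text) else ""
    after2 = text[cand.end + 1] if cand.end + 1 < len(text) else ""
    if (before.isalnum() or after1.isalnum()
            or (after1 == ":" and after2.isdigit())):
        _add_event(cand, Clue.PARTIAL_WORD, config)

    if "bioconductor" in cand.dict_sources or lexicon.contains(
        "bioconductor", cand.surface
    ):
        _add_event(cand, Clue.BIOCONDUCTOR, config)


def fire_list_clues(
    sentence: Sentence,
    sent_candidates: Sequence[CandidateMention],
    tokens: Sequence[Token],
    lexicon: Lexicon,
    config: ClueConfig,
) -> None:
    """Enumeration and Hearst-pattern membership for one sentence.

    Candidates chained by ``,``/``and``/``or`` form a list.  Every
    member of a list with at least one dictionary-matched member fires
    Enum; every member of a list introduced by "<keyword> such as" /
    "<keyword> including" or closed by "and other <keyword>" fires
    Hearst (a single member suffices for Hearst).
    """
    cands = sorted(sent_candidates, key=lambda c: (c.tok_start, -c.tok_end))
    chains: list[list[CandidateMention]] = []
    used_until = -1
    current: list[CandidateMention] = []
    for cand in cands:
        if cand.tok_start < used_until:
            continue  # overlapping alternative span: chain the outermost
        if current:
            between = tokens[current[-1].tok_end : cand.tok_start]
            if between and all(t.surface in _LIST_SEPARATORS for t in between):
                current.append(cand)
                used_until = cand.tok_end
                continue
            chains.append(current)
        current = [cand]
        used_until = cand.tok_end
    if current:
        chains.append(current)

    for chain in chains:
        first, last = chain[0], chain[-1]
        hearst = _hearst_intro(first, tokens, sentence, lexicon) or _hearst_outro(
            last, tokens, sentence, lexicon
        )
        if hearst:
            for cand in chain:
                _add_event(cand, Clue.HEARST, config)
        if len(chain) >= 2 and any(
            c.origin in ("dictionary", "both") for c in chain
        ):
            for cand in chain:
                _add_event(cand, Clue.ENUM, config)


def _hearst_intro(first: CandidateMention, tokens: Sequence[Token],
                  sentence: Sentence, lexicon: Lexicon) -> bool:
    """"<keyword NP> such as X" / "<keyword NP> including X"."""
    i = first.tok_start
    lo = sentence.tok_start
    if i - 1 >= lo and tokens[i - 1].surface.lower() == "including":
        return _keyword_before(i - 1, tokens, lo, lexicon)
    if (i - 2 >= lo and tokens[i - 1].surface.lower() == "as"
            and tokens[i - 2].surface.lower() == "such"):
        return _keyword_before(i - 2, tokens, lo, lexicon)
    return False


def _hearst_outro(last: CandidateMention, tokens: Sequence[Token],
                  sentence: Sentence, lexicon: Lexicon) -> bool:
    """"X, Y and other <keyword NP>"."""
    j = last.tok_end
    hi = sentence.tok_end
    if (j + 1 < hi
            and tokens[j].surface.lower() in {"and", "or"}
            and tokens[j + 1].surface.lower() == "other"):
        for tok in tokens[j + 2 : min(j + 5, hi)]:
            if lexicon.is_keyword(tok.surface):
                return True
    return False


def _keyword_before(pos: int, tokens: Sequence[Token], lo: int,
                    lexicon: Lexicon) -> bool:
    """Is the noun phrase just before ``pos`` headed by a keyword?"""
    k = pos - 1
    if k >= lo and tokens[k].surface == ",":
        k -= 1
    if k >= lo and lexicon.is_keyword(tokens[k].surface):
        return True
    # two-token keywords ("web service")
    if k - 1 >= lo and lexicon.is_keyword(
        tokens[k - 1].surface + " " + tokens[k].surface
    ):
        return True
    return False


# ---------------------------------------------------------------------------
# driver + scoring

def fire_local_clues(
    candidates: Sequence[CandidateMention],
    tokens: Sequence[Token],
    sentences: Sequence[Sentence],
    text: str,
    lexicon: Lexicon,
    config: ClueConfig,
) -> None:
    """Fire every local clue on every candidate and set local scores."""
    by_sentence: dict[int, list[CandidateMention]] = {}
    for cand in candidates:
        by_sentence.setdefault(cand.sentence_index, []).append(cand)

    for cand in candidates:
        if cand.origin in ("dictionary", "both"):
            _add_event(cand, Clue.DICTIONARY, config, cand.span)
        fire_title_clue(cand, tokens, sentences, text, lexicon, config)
        fire_head_clues(cand, tokens, sentences, lexicon, config)
        fire_context_clues(cand, tokens, sentences, config)
        fire_orthographic_and_negative_clues(cand, tokens, text, lexicon, config)

    for sent_index, sent_cands in by_sentence.items():
        fire_list_clues(sentences[sent_index], sent_cands, tokens, lexicon, config)

    for cand in candidates:
        cand.local_score = score_mention(cand, config)
        cand.final_score = cand.local_score


def score_mention(cand: CandidateMention, config: ClueConfig) -> float:
    """Sum of fired clue scores plus the compound bonus.

    The bonus is the number of distinct positive clue types fired,
    multiplied by the compound factor; the weak clue never enters here.
    """
    total = sum(ev.score_contribution for ev in cand.clue_events
                if ev.clue is not Clue.WEAK)
    n_positive = len({ev.clue for ev in cand.clue_events
                      if ev.clue in POSITIVE_CLUES})
    return total + n_positive * config.CompoundFactor
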