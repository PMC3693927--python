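"""Tokenisation, sentence splitting and part-of-speech tagging.

The tokeniser is rule-based and deterministic:

* whitespace separates tokens;
* punctuation characters are their own tokens, *except* dots inside
  version-like digit strings (``2.0``, ``v1.2.3`` stay atomic) and URLs
  (``http://...``, ``www....`` stay atomic);
* alphanumeric runs split at the alphanumeric/punctuation boundary, so
  identifier prefixes become their own token (``GO:001234`` ->
  ``GO`` ``:`` ``001234``);
* hyphenated words split at the hyphen.

Part-of-speech tagging is a pluggable contract: any callable mapping a
list of token surfaces to an equal-length list of Penn-style tag strings
may be injected.  The bundled :class:`HeuristicTagger` needs no model
files: it combines a closed-class word list with orthographic and
suffix rules, which is sufficient for the noun-run candidate logic this
pipeline feeds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Protocol, Sequence

from .corpus_io import Document

__all__ = [
    "Token",
    "Sentence",
    "Tagger",
    "HeuristicTagger",
    "tokenize",
    "split_sentences",
    "pos_tag",
    "preprocess_document",
]

NOUN_TAGS = frozenset({"NN", "NNS", "NNP", "NNPS"})

_TOKEN_RE = re.compile(
    r"""
    (?:https?|ftp)://[^\s)\]>"',;]+   # URLs stay atomic
    | www\.[^\s)\]>"',;]+
    | [vV]?\d+(?:\.\d+)+              # version-like digit strings: 2.0, v1.2.3
    | [A-Za-z][A-Za-z0-9]*            # words, possibly with trailing digits
    | \d+                             # bare numbers
    | [^\sA-Za-z0-9]                  # any other single character
    """,
    re.VERBOSE,
)

_URL_RE = re.compile(r"^(?:(?:https?|ftp)://|www\.)")
_VERSION_RE = re.compile(r"^[vV]?\d+(?:\.\d+)+$")


@dataclass(frozen=True)
class Token:
    """One token with offsets into the canonical document string."""

    surface: str
    start: int
    end: int
    pos: str | None = None

    @property
    def is_noun(self) -> bool:
        return self.pos in NOUN_TAGS


@dataclass(frozen=True)
class Sentence:
    """A contiguous token span; ``tok_start``/``tok_end`` index into the
    document-wide token list (half-open)."""

    index: int
    tok_start: int
    tok_end: int
    start: int
    end: int

    def tokens(self, all_tokens: Sequence[Token]) -> Sequence[Token]:
        return all_tokens[self.tok_start : self.tok_end]


class Tagger(Protocol):
    """Tagger plug-in contract: surfaces in, equal-length tag list out."""

    def __call__(self, surfaces: Sequence[str]) -> list[str]: ...


def tokenize(text: str) -> list[Token]:
    """Tokenise the canonical document string (or any text)."""
    return [
        Token(m.group(0), m.start(), m.end())
        for m in _TOKEN_RE.finditer(text)
    ]


_TERMINALS = frozenset({".", "!", "?"})


def split_sentences(tokens: Sequence[Token], document: Document | str) -> list[Sentence]:
    """Split a token stream into sentences.

    A boundary is placed after a ``.``/``!``/``?`` token followed by
    whitespace and an upper-case letter, or at end of text.  When a
    :class:`~bionerds.corpus_io.Document` is given, its title (the text
    before the first newline) is always its own sentence, so the title
    clue can address it directly.
    """
    text = document.text if isinstance(document, Document) else document
    title_end = len(document.title) if isinstance(document, Document) else None

    boundaries: set[int] = set()  # token index AFTER which a sentence ends
    for i, tok in enumerate(tokens):
        if tok.surface in _TERMINALS:
            if i + 1 == len(tokens):
                boundaries.add(i)
            else:
                nxt = tokens[i + 1]
                gap = text[tok.end : nxt.start]
                if gap and gap[0].isspace() and nxt.surface[:1].isupper():
                    boundaries.add(i)
        if title_end is not None and tok.end <= title_end and (
            i + 1 == len(tokens) or tokens[i + 1].end > title_end
        ):
            boundaries.add(i)

    sentences: list[Sentence] = []
    first = 0
    for i in range(len(tokens)):
        if i in boundaries or i + 1 == len(tokens):
            sentences.append(
                Sentence(
                    index=len(sentences),
                    tok_start=first,
                    tok_end=i + 1,
                    start=tokens[first].start,
                    end=tokens[i].end,
                )
            )
            first = i + 1
    return sentences


# ---------------------------------------------------------------------------
# Heuristic fallback tagger

# Closed-class words and common lexical items; enough to keep verbs,
# determiners and frequent adjectives out of noun runs.
_CLOSED_CLASS: dict[str, str] = {}


def _add(tag: str, words: str) -> None:
    for w in words.split():
        _CLOSED_CLASS.setdefault(w, tag)  # first listing wins


_add("DT", "the a an this that these those each every some any no all both another")
_add("PRP", "i we you he she it they me us him her them itself themselves")
_add("PRP$", "my our your his its their")
_add("IN", "of in on at by for with from into onto over under between through "
           "during against within without about across after before since until "
           "as per via than")
_add("CC", "and or but nor so yet")
_add("TO", "to")
_add("MD", "can could may might must shall should will would")
_add("EX", "there")
_add("WDT", "which what whose")
_add("WP", "who whom")
_add("WRB", "when where why how")
_add("VB", "be have do make take provide use run develop describe compare apply "
           "perform obtain show see find give allow require contain include "
           "consult measure extract identify")
_add("VBD", "was were did had made took provided used ran developed described "
            "compared applied performed obtained showed found gave allowed "
            "required contained included consulted measured extracted identified "
            "discussed presented tested built saw went came got put said wrote")
_add("VBZ", "is has does makes takes provides uses runs develops shows appears "
            "contains includes remains seems")
_add("VBP", "are have do make take provide use run develop show appear contain "
            "include remain seem")
_add("VBG", "being having using running developing providing showing containing "
            "including describing comparing applying performing tracking")
_add("VBN", "been done given taken shown seen known used made found applied "
            "performed obtained compared described developed extracted measured "
            "adopted")
_add("RB", "not also very often widely here there then now however therefore "
           "further below above freely only just more most today yesterday "
           "tomorrow again always never sometimes usually together already "
           "still yet soon later once twice")
_add("JJ", "quick new novel fast slow large small good bad high low available "
           "free open common standard such other several many few first second "
           "last next previous main key major minor full empty same different "
           "important recent early late")
_add("CD", "one two three four five six seven eight nine ten zero")

_NOUN_SUFFIXES = ("tion", "sion", "ment", "ness", "ity", "ance", "ence", "ship",
                  "ism", "ware", "base", "ology")


class HeuristicTagger:
    """Deterministic model-free tagger.

    Order of rules: closed-class lookup (skipped for all-caps tokens,
    which are almost always names or acronyms in this domain), then
    orthography (all-caps / internal capitals / digits -> NNP;
    capitalised unknown -> NNP), then suffix rules, then a plain-noun
    default for lowercase unknowns.
    """

    def __call__(self, surfaces: Sequence[str]) -> list[str]:
        return [self.tag_word(s) for s in surfaces]

    def tag_word(self, w: str) -> str:
        if not w:
            return "SYM"
        first = w[0]
        if not (first.isalnum()):
            if _URL_RE.match(w):
                return "URL"
            return w  # Penn convention: punctuation tags itself
        if w.isdigit():
            return "CD"
        if _VERSION_RE.match(w):
            return "CD"
        letters = [c for c in w if c.isalpha()]
        all_caps = len(letters) >= 2 and all(c.isupper() for c in letters)
        if not all_caps:
            tag = _CLOSED_CLASS.get(w.lower())
            if tag is not None:
                return tag
        if all_caps:
            return "NNP"
        if any(c.isupper() for c in w[1:]) or any(c.isdigit() for c in w):
            return "NNP"
        if first.isupper():
            return "NNP"
        if w.endswith("ly") and len(w) > 4:
            return "RB"
        if w.endswith(_NOUN_SUFFIXES):
            return "NN"
        if w.endswith("s") and len(w) > 3 and not w.endswith(("ss", "us", "is")):
            return "NNS"
        return "NN"


def pos_tag(
    tokens: Sequence[Token],
    tagger: Tagger | None = None,
) -> list[Token]:
    """Return tokens with ``pos`` filled in via the tagger contract."""
    if tagger is None:
        tagger = HeuristicTagger()
    tags = tagger([t.surface for t in tokens])
    if len(tags) != len(tokens):
        raise ValueError("tagger returned wrong number of tags")
    return [replace(t, pos=tag) for t, tag in zip(tokens, tags)]


def preprocess_document(
    document: Document,
    tagger: Tagger | None = None,
) -> tuple[list[Token], list[Sentence]]:
    """Tokenise, sentence-split and tag one document."""
    tokens = pos_tag(tokenize(document.text), tagger)
    sentences = split_sentences(tokens, document)
    return tokens, sentences
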