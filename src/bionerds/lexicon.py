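"""Word lists and case-sensitive longest-match dictionary tagging.

Seven lists drive the recogniser:

``resource_dict``
    the core case-sensitive dictionary of known database/software names
    (optionally ``variant<TAB>canonical`` lines);
``bioconductor``
    Bioconductor package names, which carry a small score penalty on
    top of the dictionary score because they are frequently homonymic
    with general concepts (``graph``, ``ROC``, ``affy``);
``english``
    common English words (case-insensitive; matching an entry is
    negative evidence);
``acronym``
    known biomedical acronyms (strong negative evidence);
``pos_keyword``
    resource-descriptor keywords (``database``, ``tool``, ...) used by
    the title, Hearst and good-head clues;
``neg_head``
    blacklisted head nouns (``format``, ``algorithm``, ...) marking
    out-of-scope entities;
``weak_indicator``
    ambiguous contextual indicators (``use``, ``ran``, ``platform``)
    tallied document-wide.

Bundled fixture lists ship with the package; full-scale lists are
drop-in replacements in the same one-entry-per-line format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus_io import Document
from .preprocess import Token

logger = logging.getLogger(__name__)

__all__ = [
    "SOURCES",
    "Lexicon",
    "DictMatch",
    "LexiconError",
    "load_lexicon",
    "default_lexicon",
    "dict_tag",
]

SOURCES = (
    "resource_dict",
    "bioconductor",
    "english",
    "acronym",
    "pos_keyword",
    "neg_head",
    "weak_indicator",
)

# Sources whose membership tests ignore case.
_CASE_INSENSITIVE = frozenset({"english", "pos_keyword", "neg_head", "weak_indicator"})

_BUNDLED_FILES = {
    "resource_dict": "resources.tsv",
    "bioconductor": "bioconductor.txt",
    "english": "english.txt",
    "acronym": "acronyms.txt",
    "pos_keyword": "keywords.txt",
    "neg_head": "neg_heads.txt",
    "weak_indicator": "weak.txt",
}


class LexiconError(ValueError):
    """Raised for missing mandatory lists or malformed lexicon files."""


@dataclass
class Lexicon:
    """All word lists merged into one lookup structure.

    ``entries[source]`` maps name variant -> canonical name (for plain
    lists the canonical name equals the variant).  Case-insensitive
    sources store casefolded keys.
    """

    entries: dict[str, dict[str, str]] = field(
        default_factory=lambda: {s: {} for s in SOURCES}
    )

    def add(self, source: str, variant: str, canonical: str | None = None) -> bool:
        """Add one entry; returns False (and logs) on duplicate variants."""
        if source not in self.entries:
            raise LexiconError(f"unknown lexicon source: {source!r}")
        if not variant:
            raise LexiconError(f"empty variant in source {source!r}")
        key = variant.casefold() if source in _CASE_INSENSITIVE else variant
        if key in self.entries[source]:
            logger.warning("duplicate %s entry ignored: %r", source, variant)
            return False
        self.entries[source][key] = canonical if canonical is not None else variant
        return True

    def contains(self, source: str, term: str) -> bool:
        key = term.casefold() if source in _CASE_INSENSITIVE else term
        return key in self.entries[source]

    def canonical(self, source: str, term: str) -> str | None:
        key = term.casefold() if source in _CASE_INSENSITIVE else term
        return self.entries[source].get(key)

    def size(self, source: str) -> int:
        return len(self.entries[source])

    # convenience views used by the clue modules -------------------------
    def is_keyword(self, term: str) -> bool:
        return self.contains("pos_keyword", term)

    def is_neg_head(self, term: str) -> bool:
        return self.contains("neg_head", term)

    def is_weak(self, term: str) -> bool:
        return self.contains("weak_indicator", term)


@dataclass(frozen=True)
class DictMatch:
    """One dictionary hit over the canonical document string."""

    start: int
    end: int
    surface: str
    canonical_name: str
    source: str
    tok_start: int  # index of first matched token in the document token list
    tok_end: int    # index one past the last matched token


def _read_list(path: str | Path) -> Iterable[tuple[str, str | None]]:
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if "\t" in line:
            variant, canonical = line.split("\t", 1)
            yield variant.strip(), canonical.strip() or None
        else:
            yield line.strip(), None


def load_lexicon(paths: Mapping[str, str | Path]) -> Lexicon:
    """Load and merge the word-list files given per source.

    The ``resource_dict`` file is mandatory; any other absent source is
    left empty with a warning.
    """
    unknown = set(paths) - set(SOURCES)
    if unknown:
        raise LexiconError(f"unknown lexicon sources: {sorted(unknown)}")
    if "resource_dict" not in paths:
        raise LexiconError("resource_dict list is mandatory")
    lex = Lexicon()
    for source in SOURCES:
        path = paths.get(source)
        if path is None:
            logger.warning("no %s list supplied; source left empty", source)
            continue
        path = Path(path)
        if not path.exists():
            if source == "resource_dict":
                raise LexiconError(f"mandatory resource_dict file missing: {path}")
            logger.warning("%s list missing (%s); source left empty", source, path)
            continue
        for variant, canonical in _read_list(path):
            lex.add(source, variant, canonical)
    return lex


def default_lexicon() -> Lexicon:
    """The bundled fixture lexicon (small drop-in stand-ins for the
    full-scale lists, same file formats)."""
    data = importlib_resources.files("bionerds") / "data"
    return load_lexicon({s: Path(str(data / f)) for s, f in _BUNDLED_FILES.items()})


def dict_tag(
    tokens: Sequence[Token],
    text: str,
    lexicon: Lexicon,
    source: str = "resource_dict",
) -> list[DictMatch]:
    """Left-to-right longest-match dictionary tagging over token spans.

    A match must start and end on token boundaries and reproduce a name
    variant verbatim (casefolded for case-insensitive sources).  Matches
    never overlap: after a hit the scan resumes past its last token.
    """
    entries = lexicon.entries[source]
    if not entries:
        return []
    fold = source in _CASE_INSENSITIVE
    max_len = max(len(v) for v in entries)
    matches: list[DictMatch] = []
    i = 0
    n = len(tokens)
    while i < n:
        best: tuple[int, str, str] | None = None  # (j_end, surface, canonical)
        start = tokens[i].start
        j = i
        while j < n and tokens[j].end - start <= max_len:
            surface = text[start : tokens[j].end]
            key = surface.casefold() if fold else surface
            canonical = entries.get(key)
            if canonical is not None:
                best = (j + 1, surface, canonical)
            j += 1
        if best is not None:
            j_end, surface, canonical = best
            matches.append(
                DictMatch(start, tokens[j_end - 1].end, surface, canonical,
                          source, i, j_end)
            )
            i = j_end
        else:
            i += 1
    return matches
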