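"""Deterministic synthetic fixture corpora.

Generates small full-text articles in which resource names are planted
inside the exact clue contexts the recogniser is built around — the
"Name: a database ..." title pattern, Hearst lists ("tools such as X
or Y"), trailing version numbers, bracketed citations, URLs and weak
verb contexts — alongside distractors that the negative clues must
reject (common English words, known acronyms, and identifier prefixes
like the "GO" of "GO:001234").  Gold annotations mark exactly the
planted resource-name spans, so the full pipeline can be evaluated
end-to-end without any external corpus.

Everything is driven by a seeded PRNG: the same
:class:`FixtureSpec` always yields a byte-identical corpus.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from .corpus_io import Document, GoldAnnotation

__all__ = [
    "NameRecipe",
    "FixtureSpec",
    "generate_corpus",
    "default_fixture_spec",
    "DEFAULT_DISTRACTORS",
]


@dataclass(frozen=True)
class NameRecipe:
    """Which clue contexts one planted name appears in."""

    name: str
    title: bool = False
    hearst: bool = False
    version: bool = False
    reference: bool = False
    url: bool = False
    weak_n: int = 0
    dict_member: str | None = None  # dictionary name placed beside it


@dataclass(frozen=True)
class FixtureSpec:
    names: tuple[NameRecipe, ...]
    distractors: tuple[tuple[str, str], ...]  # (kind, text)
    seed: int = 0
    n_documents: int = 12
    years: tuple[int, ...] = (2004, 2005, 2006, 2007, 2008, 2009, 2010, 2011)
    journals: tuple[str, ...] = ("Journal A", "Journal B")


DEFAULT_DISTRACTORS: tuple[tuple[str, str], ...] = (
    ("english_word", "analysis"),
    ("english_word", "network"),
    ("acronym", "DNA"),
    ("acronym", "PCR"),
    ("identifier_prefix", "GO"),
)


def default_fixture_spec(seed: int = 0, n_documents: int = 12) -> FixtureSpec:
    """The bundled study conditions: eight planted names covering every
    clue context (three of them from the bundled dictionary), plus the
    standard distractor set."""
    names = (
        NameRecipe("FooTool", title=True, version=True, reference=True),
        NameRecipe("BarBase", title=True, url=True, weak_n=2),
        NameRecipe("MUMmer", hearst=True, version=True, dict_member="Vmatch"),
        NameRecipe("QuuxAlign", hearst=True, reference=True, dict_member="BLAST"),
        NameRecipe("BLAST", version=True, reference=True),
        NameRecipe("WidgetDB", title=True, hearst=True, dict_member="GenBank"),
        NameRecipe("ZorpMapper", url=True, reference=True, weak_n=4),
        NameRecipe("Gene Ontology", hearst=True, reference=True,
                   dict_member="GenBank"),
    )
    return FixtureSpec(names=names, distractors=DEFAULT_DISTRACTORS,
                       seed=seed, n_documents=n_documents)


class _DocBuilder:
    """Accumulates title/body text while recording planted-name spans in
    canonical (title + newline + body) coordinates."""

    def __init__(self, doc_id: str) -> None:
        self.doc_id = doc_id
        self.title = ""
        self.sentences: list[str] = []
        self._pending: list[tuple[str, int, int]] = []  # name, local offsets
        self.gold: list[GoldAnnotation] = []

    def set_title(self, parts: Sequence[str | tuple[str]]) -> None:
        text, spans = _assemble(parts)
        self.title = text
        for name, start, end in spans:
            self.gold.append(GoldAnnotation(self.doc_id, start, end, name))

    def add_sentence(self, parts: Sequence[str | tuple[str]]) -> None:
        text, spans = _assemble(parts)
        self.sentences.append(text)
        self._pending.append((text, spans))  # type: ignore[arg-type]

    def build(self, year: int, journal: str) -> tuple[Document, list[GoldAnnotation]]:
        body = " ".join(self.sentences)
        doc = Document(self.doc_id, self.title, body, year=year, journal=journal)
        offset = len(self.title) + 1
        for text, spans in self._pending:  # type: ignore[misc]
            for name, start, end in spans:
                self.gold.append(
                    GoldAnnotation(self.doc_id, offset + start, offset + end, name)
                )
            offset += len(text) + 1
        self.gold.sort(key=lambda g: (g.start, g.end))
        return doc, self.gold


def _assemble(
    parts: Sequence[str | tuple[str]],
) -> tuple[str, list[tuple[str, int, int]]]:
    """Join literal strings and 1-tuples (planted names); returns the
    text and the local spans of the planted names."""
    text = ""
    spans: list[tuple[str, int, int]] = []
    for part in parts:
        if isinstance(part, tuple):
            (name,) = part
            spans.append((name, len(text), len(text) + len(name)))
            text += name
        else:
            text += part
    return text, spans


_GENERIC_TITLES = (
    "A comparative study of widget dynamics in yeast",
    "On the statistical properties of noisy measurements",
    "Exploring structural variation across model organisms",
    "Patterns of covariation in large measurement panels",
)

_FILLER = (
    "The experimental design followed established practice.",
    "Results were summarised across all replicates.",
    "Further details appear in the supplementary material.",
    "The remaining parameters were fixed throughout.",
)


def generate_corpus(
    spec: FixtureSpec,
) -> tuple[list[Document], list[GoldAnnotation], pd.DataFrame]:
    """Generate (documents, gold annotations, metadata) from a spec.

    Document ``i`` features recipe ``i mod len(names)``, so every
    recipe appears at least once when ``n_documents >= len(names)``.
    """
    if not spec.names:
        raise ValueError("fixture spec needs at least one planted name")
    rng = random.Random(spec.seed)
    documents: list[Document] = []
    gold: list[GoldAnnotation] = []
    meta_rows: list[tuple[str, str, int]] = []

    for i in range(spec.n_documents):
        recipe = spec.names[i % len(spec.names)]
        doc_id = f"synth{i:03d}"
        b = _DocBuilder(doc_id)
        name = (recipe.name,)

        if recipe.title:
            b.set_title([name, ": a database for sequence comparison"])
        else:
            b.set_title([rng.choice(_GENERIC_TITLES)])

        if recipe.hearst:
            member = recipe.dict_member or "BLAST"
            b.add_sentence(["Many tools such as ", name, " or ",
                            (member,), " have been described."])
        elif recipe.dict_member:
            b.add_sentence([(recipe.dict_member,),
                            " was also consulted during this work."])

        if recipe.version and recipe.reference:
            b.add_sentence(["We applied ", name, " 2.3 [7] to the data."])
        elif recipe.version:
            b.add_sentence(["We applied ", name, " 2.3 to the data."])
        elif recipe.reference:
            b.add_sentence(["The results were compared with ", name, " [3]."])

        if recipe.url:
            slug = recipe.name.replace(" ", "").lower()
            b.add_sentence([name, f" (http://{slug}.example.org) is freely available."])

        for _ in range(recipe.weak_n):
            b.add_sentence(["We used ", name, " here."])

        # one bare mention only reachable through propagation
        b.add_sentence([name, " is discussed further below."])

        for kind, term in rng.sample(spec.distractors, k=min(2, len(spec.distractors))):
            if kind == "identifier_prefix":
                b.add_sentence([f"The identifier {term}:001234 appears in the index."])
            elif kind == "acronym":
                b.add_sentence([f"The {term} was extracted and measured."])
            else:
                b.add_sentence([f"This {term} shows a broad trend."])

        b.add_sentence([rng.choice(_FILLER)])

        year = spec.years[i % len(spec.years)]
        journal = spec.journals[i % len(spec.journals)]
        doc, doc_gold = b.build(year, journal)
        documents.append(doc)
        gold.extend(doc_gold)
        meta_rows.append((doc_id, journal, year))

    metadata = pd.DataFrame(meta_rows, columns=["doc_id", "journal", "year"])
    return documents, gold, metadata
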