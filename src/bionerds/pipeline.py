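"""End-to-end wiring of the recognition pipeline.

preprocess -> dictionary lookup -> candidate generation -> local clue
scoring -> cross-mention weak clues -> threshold + propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .candidates import CandidateMention, extract_noun_runs, merge_candidates
from .corpus_io import Document
from .doc_resolution import (
    Mention,
    ResourceRecord,
    apply_weak_scores,
    tally_weak_clues,
    threshold_and_propagate,
)
from .lexicon import Lexicon, default_lexicon, dict_tag
from .local_clues import ClueConfig, fire_local_clues
from .preprocess import Tagger, preprocess_document

__all__ = ["DocumentAnnotation", "annotate_document", "annotate_corpus"]


@dataclass
class DocumentAnnotation:
    """Full annotation result for one document."""

    doc_id: str
    mentions: list[Mention]
    records: list[ResourceRecord]
    candidates: list[CandidateMention] = field(default_factory=list)

    @property
    def resource_names(self) -> set[str]:
        return {r.normalized_name for r in self.records}


def annotate_document(
    document: Document,
    lexicon: Lexicon | None = None,
    config: ClueConfig | None = None,
    tagger: Tagger | None = None,
) -> DocumentAnnotation:
    """Run the whole recognition pipeline on one document."""
    if lexicon is None:
        lexicon = default_lexicon()
    if config is None:
        config = ClueConfig()

    tokens, sentences = preprocess_document(document, tagger)
    text = document.text

    matches = dict_tag(tokens, text, lexicon, "resource_dict")
    matches += dict_tag(tokens, text, lexicon, "bioconductor")

    noun_runs = [
        cand
        for sent in sentences
        for cand in extract_noun_runs(sent, tokens, text, lexicon)
    ]
    candidates = merge_candidates(noun_runs, matches, sentences, text)

    fire_local_clues(candidates, tokens, sentences, text, lexicon, config)
    tallies = tally_weak_clues(candidates, tokens, sentences, lexicon)
    apply_weak_scores(candidates, tallies, config)
    mentions, records = threshold_and_propagate(candidates, tokens, text, config)
    return DocumentAnnotation(document.doc_id, mentions, records, candidates)


def annotate_corpus(
    documents: Iterable[Document],
    lexicon: Lexicon | None = None,
    config: ClueConfig | None = None,
    tagger: Tagger | None = None,
) -> dict[str, DocumentAnnotation]:
    """Annotate a corpus; returns results keyed by doc_id."""
    if lexicon is None:
        lexicon = default_lexicon()
    if config is None:
        config = ClueConfig()
    return {
        doc.doc_id: annotate_document(doc, lexicon, config, tagger)
        for doc in documents
    }
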