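import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from bionerds.corpus_io import Document
from bionerds.lexicon import Lexicon, default_lexicon
from bionerds.local_clues import ClueConfig
from bionerds.pipeline import annotate_document
from bionerds.preprocess import preprocess_document


@pytest.fixture(scope="session")
def lexicon() -> Lexicon:
    return default_lexicon()


@pytest.fixture()
def config() -> ClueConfig:
    return ClueConfig()


@pytest.fixture(scope="session")
def make_doc():
    def _make(text: str, doc_id: str = "d1") -> Document:
        title, _, body = text.partition("\n")
        return Document(doc_id, title, body)

    return _make


@pytest.fixture(scope="session")
def annotate(lexicon, make_doc):
    """Run the full pipeline on raw text (first line = title)."""

    def _run(text: str, config: ClueConfig | None = None):
        return annotate_document(make_doc(text), lexicon, config or ClueConfig())

    return _run


@pytest.fixture(scope="session")
def preprocess(make_doc):
    def _run(text: str):
        doc = make_doc(text)
        tokens, sentences = preprocess_document(doc)
        return doc, tokens, sentences

    return _run
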