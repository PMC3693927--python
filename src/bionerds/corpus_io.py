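"""Document, annotation and metadata I/O.

Every downstream stage works on one coordinate system: the canonical
document string ``title + "\\n" + body``.  All character offsets — gold
annotations, dictionary matches, candidate mentions — refer to that
string, 0-based with half-open ends.

Supported formats:

* plain text (UTF-8): first line is the title, the remainder the body;
* PMC-style JATS XML: ``article-title``, ``abstract`` and ``body``
  elements, with markup stripped and element boundaries replaced by a
  single whitespace character so offsets are stable;
* standoff TSV for annotations (``doc_id  start  end  surface``);
* metadata CSV (``doc_id, journal, year``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from lxml import etree

__all__ = [
    "Document",
    "GoldAnnotation",
    "CorpusIOError",
    "read_document",
    "read_standoff",
    "write_standoff",
    "read_metadata",
    "validate_annotations",
]

_STANDOFF_COLUMNS = ("doc_id", "start", "end", "surface")


class CorpusIOError(ValueError):
    """Raised for malformed documents, annotations or metadata."""


@dataclass(frozen=True)
class Document:
    """A full-text article with stable character offsets.

    ``text`` is the canonical string over which every offset in the
    system is defined.
    """

    doc_id: str
    title: str
    body: str
    year: int | None = None
    journal: str | None = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusIOError("doc_id must be non-empty")

    @property
    def text(self) -> str:
        return self.title + "\n" + self.body

    @property
    def char_count(self) -> int:
        return len(self.text)


@dataclass(frozen=True)
class GoldAnnotation:
    """One gold-standard mention span in a document."""

    doc_id: str
    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusIOError(
                f"invalid span [{self.start}, {self.end}) for doc {self.doc_id!r}"
            )


def read_document(
    path: str | Path,
    format: str = "plaintext",
    doc_id: str | None = None,
    year: int | None = None,
    journal: str | None = None,
) -> Document:
    """Read one article from ``path`` as a :class:`Document`.

    ``format`` is ``"plaintext"`` (first line = title) or ``"pmc_xml"``
    (JATS-style ``article-title``/``abstract``/``body`` elements).
    """
    path = Path(path)
    if doc_id is None:
        doc_id = path.stem
    raw = path.read_text(encoding="utf-8")
    if not raw.strip():
        raise CorpusIOError(f"empty document: {path}")
    if format == "plaintext":
        title, _, body = raw.partition("\n")
        return Document(doc_id, title.rstrip("\r"), body, year=year, journal=journal)
    if format == "pmc_xml":
        try:
            root = etree.fromstring(raw.encode("utf-8"))
        except etree.XMLSyntaxError as exc:
            raise CorpusIOError(f"malformed XML in {path}: {exc}") from exc
        title = _element_text(root, "article-title")
        abstract = _element_text(root, "abstract")
        body = _element_text(root, "body")
        full_body = " ".join(part for part in (abstract, body) if part)
        if not title and not full_body:
            raise CorpusIOError(f"no article-title/abstract/body content in {path}")
        return Document(doc_id, title, full_body, year=year, journal=journal)
    raise CorpusIOError(f"unknown document format: {format!r}")


def _element_text(root: etree._Element, tag: str) -> str:
    """Concatenated text of the first ``tag`` element, markup stripped.

    Element boundaries collapse to single spaces so that removing markup
    never glues two words together and offsets stay stable.
    """
    elems = root.findall(f".//{tag}")
    if not elems:
        return ""
    pieces = [t.strip() for t in elems[0].itertext()]
    return " ".join(p for p in pieces if p)


def read_standoff(path: str | Path) -> list[GoldAnnotation]:
    """Read standoff annotations from a TSV file, in file order."""
    path = Path(path)
    annotations: list[GoldAnnotation] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row_num, row in enumerate(reader, start=1):
            if not row or (row_num == 1 and row[:4] == list(_STANDOFF_COLUMNS)):
                continue
            if len(row) < 4:
                raise CorpusIOError(f"{path}:{row_num}: expected 4 columns, got {len(row)}")
            doc_id, start_s, end_s, surface = row[0], row[1], row[2], row[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise CorpusIOError(f"{path}:{row_num}: non-integer offsets") from exc
            if start >= end:
                raise CorpusIOError(f"{path}:{row_num}: start {start} >= end {end}")
            annotations.append(GoldAnnotation(doc_id, start, end, surface))
    return annotations


def write_standoff(annotations: Iterable[GoldAnnotation], path: str | Path) -> None:
    """Write annotations as standoff TSV; inverse of :func:`read_standoff`."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_STANDOFF_COLUMNS)
        for ann in annotations:
            writer.writerow([ann.doc_id, ann.start, ann.end, ann.surface])


def validate_annotations(
    annotations: Iterable[GoldAnnotation],
    documents: Mapping[str, Document] | Sequence[Document],
) -> None:
    """Check that each annotation's span and surface agree with its document.

    Raises :class:`CorpusIOError` naming the first offending annotation.
    """
    if not isinstance(documents, Mapping):
        documents = {doc.doc_id: doc for doc in documents}
    for i, ann in enumerate(annotations, start=1):
        doc = documents.get(ann.doc_id)
        if doc is None:
            raise CorpusIOError(f"annotation {i}: unknown doc_id {ann.doc_id!r}")
        if ann.end > doc.char_count:
            raise CorpusIOError(
                f"annotation {i}: span [{ann.start}, {ann.end}) exceeds "
                f"document length {doc.char_count} of {ann.doc_id!r}"
            )
        actual = doc.text[ann.start : ann.end]
        if actual != ann.surface:
            raise CorpusIOError(
                f"annotation {i}: surface {ann.surface!r} does not match "
                f"document slice {actual!r} in {ann.doc_id!r}"
            )


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the document metadata table (doc_id, journal, year) from CSV."""
    df = pd.read_csv(path, dtype={"doc_id": str})
    missing = {"doc_id", "journal", "year"} - set(df.columns)
    if missing:
        raise CorpusIOError(f"metadata missing columns: {sorted(missing)}")
    return df
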