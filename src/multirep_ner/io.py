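"""Readers and writers for every external artifact the pipeline touches.

Formats (all plain text, UTF-8):

* documents        -- one ``.txt`` file per document; the doc id is the stem
* annotations      -- ``.ann`` 5-column TSV: doc_id, start, end, type, surface
* lexicons         -- 2-column TSV: entity_type, term
* affix resources  -- 3-column TSV: affix_kind, affix, count
* embedding tables -- word2vec text format (header ``V D`` then rows)
* reports          -- JSON

Character offsets are 0-based, half-open; every reader sorts its output
deterministically so that downstream splits are reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

AFFIX_KINDS = ("prefix2", "prefix3", "suffix2", "suffix3")


@dataclass(frozen=True)
class Document:
    """A raw text document with a corpus-unique identifier."""

    doc_id: str
    text: str


@dataclass(frozen=True, order=True)
class Mention:
    """A typed character span in a document (gold annotation or candidate).

    ``start``/``end`` are 0-based half-open offsets into the document text;
    ``surface`` always equals ``text[start:end]`` of the owning document.
    """

    doc_id: str
    start: int
    end: int
    entity_type: str
    surface: str

    def key(self) -> tuple[str, int, int, str]:
        """Identity used for exact-match evaluation (surface excluded)."""
        return (self.doc_id, self.start, self.end, self.entity_type)


@dataclass(frozen=True)
class Lexicon:
    """A term list for one entity type, used by the gazetteer."""

    entity_type: str
    terms: frozenset[str]


@dataclass(frozen=True)
class AffixResource:
    """Occurrence counts of 2/3-character prefixes and suffixes from one
    terminological resource."""

    resource_name: str
    counts: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        for (kind, affix), count in self.counts.items():
            if kind not in AFFIX_KINDS:
                raise FormatError(f"unknown affix kind {kind!r}")
            if len(affix) != int(kind[-1]):
                raise FormatError(
                    f"affix {affix!r} has length {len(affix)}, kind {kind} "
                    f"requires {kind[-1]}"
                )
            if count < 0:
                raise FormatError(f"negative count for affix {affix!r}")


@dataclass
class EmbeddingTable:
    """A word -> vector lookup table (word2vec text format on disk)."""

    name: str
    dimension: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for word, vec in self.vectors.items():
            if vec.shape != (self.dimension,):
                raise FormatError(
                    f"vector for {word!r} has shape {vec.shape}, expected "
                    f"({self.dimension},)"
                )


# ---------------------------------------------------------------------------
# documents


def read_documents(path: str | Path) -> list[Document]:
    """Read all ``*.txt`` files under *path* as documents, sorted by id."""
    root = Path(path)
    if not root.is_dir():
        raise InputError(f"document directory not found: {root}")
    docs = []
    for file in sorted(root.glob("*.txt")):
        try:
            text = file.read_text(encoding="utf-8")
        except UnicodeDecodeError as exc:
            raise FormatError(f"undecodable UTF-8 in {file}: {exc}") from exc
        docs.append(Document(doc_id=file.stem, text=text))
    return docs


def write_documents(documents: Iterable[Document], path: str | Path) -> None:
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for doc in documents:
        (root / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")


# ---------------------------------------------------------------------------
# standoff annotations


def read_standoff(
    path: str | Path, documents: Sequence[Document]
) -> list[Mention]:
    """Read a 5-column TSV of standoff annotations, validating every span
    against the document text. The surface column, when present, is checked
    against the document slice rather than trusted."""
    file = Path(path)
    if not file.is_file():
        raise InputError(f"annotation file not found: {file}")
    by_id = {d.doc_id: d for d in documents}
    mentions = []
    for idx, line in enumerate(file.read_text(encoding="utf-8").splitlines()):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise FormatError(f"record {idx}: expected >= 4 TSV fields")
        doc_id, start_s, end_s, entity_type = parts[:4]
        if doc_id not in by_id:
            raise FormatError(f"record {idx}: unknown doc_id {doc_id!r}")
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise FormatError(f"record {idx}: non-integer offsets") from exc
        text = by_id[doc_id].text
        if not (0 <= start < end <= len(text)):
            raise FormatError(
                f"record {idx}: span ({start}, {end}) outside document "
                f"{doc_id!r} of length {len(text)}"
            )
        surface = text[start:end]
        if len(parts) >= 5 and parts[4] and parts[4] != surface:
            raise FormatError(
                f"record {idx}: surface {parts[4]!r} does not match document "
                f"slice {surface!r}"
            )
        mentions.append(Mention(doc_id, start, end, entity_type, surface))
    return sorted(mentions)


def write_standoff(mentions: Iterable[Mention], path: str | Path) -> None:
    lines = [
        f"{m.doc_id}\t{m.start}\t{m.end}\t{m.entity_type}\t{m.surface}"
        for m in sorted(mentions)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), "utf-8")


# ---------------------------------------------------------------------------
# lexicons


def read_lexicons(path: str | Path) -> dict[str, Lexicon]:
    """Read a 2-column TSV (entity_type, term) into one Lexicon per type."""
    file = Path(path)
    if not file.is_file():
        raise InputError(f"lexicon file not found: {file}")
    terms: dict[str, set[str]] = {}
    for idx, line in enumerate(file.read_text(encoding="utf-8").splitlines()):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[1]:
            raise FormatError(f"lexicon record {idx}: expected 2 TSV fields")
        terms.setdefault(parts[0], set()).add(parts[1])
    return {
        etype: Lexicon(etype, frozenset(ts))
        for etype, ts in sorted(terms.items())
    }


def write_lexicons(lexicons: Iterable[Lexicon], path: str | Path) -> None:
    lines = []
    for lex in sorted(lexicons, key=lambda l: l.entity_type):
        lines.extend(f"{lex.entity_type}\t{t}" for t in sorted(lex.terms))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), "utf-8")


# ---------------------------------------------------------------------------
# affix resources


def read_affix_resource(path: str | Path) -> AffixResource:
    """Read a 3-column TSV (affix_kind, affix, count); resource name is the
    file stem."""
    file = Path(path)
    if not file.is_file():
        raise InputError(f"affix resource not found: {file}")
    counts: dict[tuple[str, str], int] = {}
    for idx, line in enumerate(file.read_text(encoding="utf-8").splitlines()):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"affix record {idx}: expected 3 TSV fields")
        kind, affix, count_s = parts
        try:
            count = int(count_s)
        except ValueError as exc:
            raise FormatError(f"affix record {idx}: bad count") from exc
        counts[(kind, affix)] = count
    return AffixResource(file.stem, counts)


def read_affix_resources(path: str | Path) -> list[AffixResource]:
    """Read every ``*.tsv`` under *path*, sorted by resource name."""
    root = Path(path)
    if not root.is_dir():
        raise InputError(f"affix resource directory not found: {root}")
    return [read_affix_resource(f) for f in sorted(root.glob("*.tsv"))]


def write_affix_resource(resource: AffixResource, path: str | Path) -> None:
    lines = [
        f"{kind}\t{affix}\t{count}"
        for (kind, affix), count in sorted(resource.counts.items())
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), "utf-8")


# ---------------------------------------------------------------------------
# embedding tables


def read_embedding_table(path: str | Path, name: str | None = None) -> EmbeddingTable:
    """Parse a word2vec text-format table: header line ``V D`` followed by
    ``V`` lines of ``word v1 ... vD``. Duplicate words: last wins (warned)."""
    file = Path(path)
    if not file.is_file():
        raise InputError(f"embedding table not found: {file}")
    lines = file.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FormatError(f"{file}: empty embedding table")
    header = lines[0].split()
    if len(header) != 2:
        raise FormatError(f"{file}: line 1: expected header 'V D'")
    n_words, dim = int(header[0]), int(header[1])
    vectors: dict[str, np.ndarray] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != dim + 1:
            raise FormatError(
                f"{file}: line {lineno}: expected {dim} values, "
                f"got {len(parts) - 1}"
            )
        word = parts[0]
        if word in vectors:
            logger.warning("duplicate word %r in %s; last occurrence wins", word, file)
        vectors[word] = np.asarray(parts[1:], dtype=np.float64)
    if len(vectors) != n_words:
        logger.warning(
            "%s: header declares %d words, found %d", file, n_words, len(vectors)
        )
    return EmbeddingTable(name or file.stem, dim, vectors)


def write_embedding_table(table: EmbeddingTable, path: str | Path) -> None:
    lines = [f"{len(table.vectors)} {table.dimension}"]
    for word in sorted(table.vectors):
        values = " ".join(repr(float(v)) for v in table.vectors[word])
        lines.append(f"{word} {values}")
    Path(path).write_text("\n".join(lines) + "\n", "utf-8")


# ---------------------------------------------------------------------------
# reports


def write_report(report: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
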