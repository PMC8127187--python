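"""Synthetic corpora with planted, single-cause class signal.

The generator emulates the statistical structure the candidate filter
relies on: a lexicon whose terms occur in running text, gold annotations
for the true entities, and decoy lexicon terms that produce the look-up's
false-positive candidates. Exactly one view carries the class signal,
selected by ``signal``:

* ``suffix_rule``    -- every positive term ends with a planted
  biomedical-style suffix (default ``-ase``, the classic enzyme marker);
  decoys never do, so only affix-derived features separate the classes;
* ``shape_rule``     -- positive terms carry a distinctive word shape
  (capitalized stem, dash, trailing digits, e.g. ``Abc-12``); decoys are
  plain lowercase words, so shape/orthographic/spectrum views separate;
* ``embedding_rule`` -- surfaces are statistically identical; the
  domain embedding table places positives and decoys around centers
  +delta/2 * u and -delta/2 * u with unit-variance noise;
* ``none``           -- no view is informative.

Everything is deterministic given the seed; the same config yields a
byte-identical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .io import (
    AFFIX_KINDS, AffixResource, Document, EmbeddingTable, Lexicon, Mention,
    write_affix_resource, write_documents, write_embedding_table,
    write_lexicons, write_standoff,
)

_CONSONANTS = "bcdfghjklmnprstvz"
_VOWELS = "aeiou"
PLANTED_SUFFIXES = ("ase", "ism")


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic corpus; ``seed`` is mandatory."""

    seed: int
    n_documents: int = 30
    entities_per_document: int = 4
    entity_type: str = "chebi"
    signal: str = "suffix_rule"  # suffix_rule | shape_rule | embedding_rule | none
    decoy_rate: float = 0.5
    embedding_dim: int = 8
    delta: float = 0.0
    # term lists are kept large relative to the embedding dimension so the
    # delta = 0 tables cannot act as term-identity memorizers (the view must
    # be genuinely uninformative at zero separation)
    n_positive_terms: int = 100
    n_decoy_terms: int = 100
    n_filler_words: int = 120
    planted_suffix: str = PLANTED_SUFFIXES[0]

    def __post_init__(self) -> None:
        if self.signal not in ("suffix_rule", "shape_rule", "embedding_rule", "none"):
            raise ConfigurationError(f"unknown signal {self.signal!r}")
        if not 0.0 <= self.decoy_rate <= 1.0:
            raise ConfigurationError("decoy_rate must be in [0, 1]")
        if self.delta < 0:
            raise ConfigurationError("delta must be >= 0")


def _syllable(rng: np.random.Generator) -> str:
    return _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[
        rng.integers(len(_VOWELS))
    ]


def _word(rng: np.random.Generator, n_syllables: tuple[int, int] = (2, 4)) -> str:
    n = int(rng.integers(n_syllables[0], n_syllables[1] + 1))
    return "".join(_syllable(rng) for _ in range(n))


def _unique_words(
    rng: np.random.Generator, n: int, taken: set[str], make
) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        w = make(rng)
        if w not in taken:
            taken.add(w)
            out.append(w)
    return out


def _cvc(rng: np.random.Generator) -> str:
    """A consonant-vowel-consonant ending; never equals a planted suffix
    (those are vowel-initial)."""
    return (
        _CONSONANTS[rng.integers(len(_CONSONANTS))]
        + _VOWELS[rng.integers(len(_VOWELS))]
        + _CONSONANTS[rng.integers(len(_CONSONANTS))]
    )


def _make_terms(config: FixtureConfig, rng: np.random.Generator):
    # positives and decoys share the stem + 3-char-ending construction, so
    # their length and shape distributions coincide; only the planted view
    # differs between the classes
    taken: set[str] = set()
    suffix = config.planted_suffix

    def plain(r: np.random.Generator) -> str:
        return _word(r, (2, 3)) + _cvc(r)

    if config.signal == "suffix_rule":
        positives = _unique_words(
            rng, config.n_positive_terms, taken,
            lambda r: _word(r, (2, 3)) + suffix,
        )
        decoys = _unique_words(rng, config.n_decoy_terms, taken, plain)
    elif config.signal == "shape_rule":
        def shaped(r: np.random.Generator) -> str:
            stem = _word(r, (2, 3))
            return stem.capitalize() + "-" + str(int(r.integers(1, 100)))

        positives = _unique_words(rng, config.n_positive_terms, taken, shaped)
        decoys = _unique_words(rng, config.n_decoy_terms, taken, plain)
    else:  # embedding_rule, none: identically distributed surfaces
        positives = _unique_words(rng, config.n_positive_terms, taken, plain)
        decoys = _unique_words(rng, config.n_decoy_terms, taken, plain)
    return positives, decoys, taken


def generate_corpus(
    config: FixtureConfig,
) -> tuple[list[Document], list[Mention], Lexicon, list[str]]:
    """Documents seeded with lexicon terms, gold mentions for the positive
    placements, the lexicon (positives plus decoys), and the decoy list."""
    rng = np.random.default_rng(config.seed)
    positives, decoys, taken = _make_terms(config, rng)
    fillers = _unique_words(rng, config.n_filler_words, taken, lambda r: _word(r))

    docs: list[Document] = []
    gold: list[Mention] = []
    for d in range(config.n_documents):
        doc_id = f"doc{d:03d}"
        pieces: list[str] = []
        offset = 0
        spans: list[tuple[int, int, str, bool]] = []
        for _ in range(config.entities_per_document):
            context = [fillers[rng.integers(len(fillers))] for _ in range(int(rng.integers(2, 5)))]
            is_decoy = bool(rng.random() < config.decoy_rate)
            term = (decoys if is_decoy else positives)[
                rng.integers(len(decoys) if is_decoy else len(positives))
            ]
            for w in context:
                pieces.append(w)
                offset += len(w) + 1
            pieces.append(term)
            spans.append((offset, offset + len(term), term, is_decoy))
            offset += len(term) + 1
        tail = [fillers[rng.integers(len(fillers))] for _ in range(2)]
        pieces.extend(tail)
        text = " ".join(pieces)
        docs.append(Document(doc_id, text))
        for start, end, term, is_decoy in spans:
            assert text[start:end] == term
            if not is_decoy:
                gold.append(Mention(doc_id, start, end, config.entity_type, term))
    lexicon = Lexicon(config.entity_type, frozenset(positives) | frozenset(decoys))
    return docs, sorted(gold), lexicon, sorted(decoys)


def generate_embedding_table(
    vocabulary: Sequence[str],
    dimension: int,
    delta: float,
    seed: int,
    positive_terms: Sequence[str] = (),
    name: str = "synthetic",
) -> EmbeddingTable:
    """Embedding table with controllable class separation: positive terms
    are drawn around +delta/2 along a fixed unit direction, all other words
    around -delta/2, with unit-variance isotropic noise."""
    if delta < 0:
        raise ConfigurationError("delta must be >= 0")
    rng = np.random.default_rng(seed)
    u = np.zeros(dimension)
    u[0] = 1.0
    pos = set(positive_terms)
    vectors = {}
    for word in sorted(set(vocabulary)):
        center = (delta / 2.0 if word in pos else -delta / 2.0) * u
        vectors[word] = center + rng.standard_normal(dimension)
    return EmbeddingTable(name, dimension, vectors)


def generate_affix_resources(
    terms: Sequence[str], seed: int, n_resources: int = 5
) -> list[AffixResource]:
    """Five affix-count resources built by counting the 2/3-character
    prefixes and suffixes over bootstrap samples of the term list, standing
    in for independent terminological resources that share the corpus's
    morphology."""
    rng = np.random.default_rng(seed)
    terms = sorted(terms)
    resources = []
    for r in range(n_resources):
        sample = [terms[i] for i in rng.integers(len(terms), size=len(terms))]
        counts: dict[tuple[str, str], int] = {}
        for term in sample:
            token = term.split()[0] if term.split() else ""
            last = term.split()[-1] if term.split() else ""
            for kind, affix in (
                ("prefix2", token[:2] if len(token) > 2 else None),
                ("prefix3", token[:3] if len(token) > 3 else None),
                ("suffix2", last[-2:] if len(last) > 2 else None),
                ("suffix3", last[-3:] if len(last) > 3 else None),
            ):
                if affix is not None:
                    counts[(kind, affix)] = counts.get((kind, affix), 0) + 1
        resources.append(AffixResource(f"resource_{r}", counts))
    return resources


@dataclass
class Fixture:
    """A complete synthetic study: corpus, lexicon, resources, embeddings."""

    config: FixtureConfig
    documents: list[Document]
    gold: list[Mention]
    lexicon: Lexicon
    decoy_terms: list[str]
    affix_resources: list[AffixResource] = field(default_factory=list)
    embed_domain: EmbeddingTable | None = None
    embed_general: EmbeddingTable | None = None

    def representation_config(self, include_embeddings: bool = True):
        from .representations import RepresentationConfig

        return RepresentationConfig(
            affix_resources=tuple(self.affix_resources),
            embedding_domain=self.embed_domain,
            embedding_general=self.embed_general,
            include_embeddings=include_embeddings,
        )

    def split(self, n_train: int):
        """First *n_train* documents for training, the rest for testing."""
        train_docs = self.documents[:n_train]
        test_docs = self.documents[n_train:]
        train_ids = {d.doc_id for d in train_docs}
        gold_train = [g for g in self.gold if g.doc_id in train_ids]
        gold_test = [g for g in self.gold if g.doc_id not in train_ids]
        return train_docs, test_docs, gold_train, gold_test


def generate_fixture(config: FixtureConfig) -> Fixture:
    """Generate the full study: corpus plus affix resources and the two
    embedding tables. The domain table carries the class separation
    ``delta`` only under the ``embedding_rule`` signal; the general table
    is always uninformative."""
    docs, gold, lexicon, decoys = generate_corpus(config)
    positives = sorted(lexicon.terms - set(decoys))
    vocab = sorted(lexicon.terms) + sorted(
        {w for d in docs for w in d.text.split() if w not in lexicon.terms}
    )
    domain_delta = config.delta if config.signal == "embedding_rule" else 0.0
    embed_domain = generate_embedding_table(
        vocab, config.embedding_dim, domain_delta, config.seed + 1,
        positive_terms=positives, name="embed_domain",
    )
    embed_general = generate_embedding_table(
        vocab, config.embedding_dim, 0.0, config.seed + 2,
        positive_terms=positives, name="embed_general",
    )
    resources = generate_affix_resources(sorted(lexicon.terms), config.seed + 3)
    return Fixture(
        config, docs, gold, lexicon, decoys, resources, embed_domain, embed_general
    )


def write_fixture(fixture: Fixture, out_dir: str | Path) -> None:
    """Materialize a fixture in the corpus_io on-disk layout."""
    root = Path(out_dir)
    (root / "docs").mkdir(parents=True, exist_ok=True)
    (root / "affixes").mkdir(exist_ok=True)
    write_documents(fixture.documents, root / "docs")
    write_standoff(fixture.gold, root / "gold.ann")
    write_lexicons([fixture.lexicon], root / "lexicon.tsv")
    for resource in fixture.affix_resources:
        write_affix_resource(resource, root / "affixes" / f"{resource.resource_name}.tsv")
    if fixture.embed_domain is not None:
        write_embedding_table(fixture.embed_domain, root / "embed_domain.txt")
    if fixture.embed_general is not None:
        write_embedding_table(fixture.embed_general, root / "embed_general.txt")
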