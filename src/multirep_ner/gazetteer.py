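"""Dictionary look-up stage: propose candidate mentions and label them.

The gazetteer scans each document for lexicon terms using leftmost-longest,
non-overlapping matching anchored on word boundaries (a boundary is the text
edge or a position adjacent to a non-alphanumeric character). Candidates that
coincide exactly (document, span, type) with a gold annotation are the
positive training examples; the remaining candidates — the look-up's false
positives — are the negatives. Gold mentions the dictionary never proposes
cannot reach the classifier at all; they are tallied separately and charged
as false negatives at evaluation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ConfigurationError
from .io import Document, Lexicon, Mention

_END = "\0"  # sentinel key marking a complete term inside the trie


def _fold(text: str) -> str:
    """Length-preserving per-character lowercasing for casefold matching."""
    return "".join(c.lower()[0] if c.lower() else c for c in text)


@dataclass
class Matcher:
    """A prefix-tree matcher over the terms of one lexicon."""

    entity_type: str
    case_mode: str = "exact"  # "exact" | "casefold"
    _trie: dict = field(default_factory=dict, repr=False)

    def add(self, term: str) -> None:
        node = self._trie
        for ch in term:
            node = node.setdefault(ch, {})
        node[_END] = True

    def longest_match(self, text: str, start: int) -> int | None:
        """Length of the longest lexicon term starting at *start* whose end
        falls on a word boundary, or None."""
        node = self._trie
        best = None
        i = start
        n = len(text)
        while True:
            if _END in node and (i == n or not text[i].isalnum()):
                best = i - start
            if i == n or text[i] not in node:
                return best
            node = node[text[i]]
            i += 1


def build_matcher(lexicon: Lexicon, case_mode: str = "exact") -> Matcher:
    """Compile a lexicon into a trie matcher.

    With ``case_mode="casefold"`` both terms and document text are folded
    character-by-character before matching, so "CAT" and "cat" collide.
    """
    if case_mode not in ("exact", "casefold"):
        raise ConfigurationError(f"unknown case_mode {case_mode!r}")
    if not lexicon.terms:
        raise ConfigurationError(
            f"empty lexicon for entity type {lexicon.entity_type!r}"
        )
    matcher = Matcher(lexicon.entity_type, case_mode)
    for term in lexicon.terms:
        if term:
            matcher.add(_fold(term) if case_mode == "casefold" else term)
    return matcher


def find_candidates(document: Document, matcher: Matcher) -> list[Mention]:
    """All leftmost-longest non-overlapping lexicon matches on word
    boundaries, sorted by start offset."""
    text = document.text
    haystack = _fold(text) if matcher.case_mode == "casefold" else text
    out = []
    i = 0
    n = len(text)
    while i < n:
        at_boundary = i == 0 or not haystack[i - 1].isalnum()
        if at_boundary:
            length = matcher.longest_match(haystack, i)
            if length:
                out.append(
                    Mention(
                        document.doc_id, i, i + length,
                        matcher.entity_type, text[i : i + length],
                    )
                )
                i += length
                continue
        i += 1
    return out


@dataclass(frozen=True)
class LabeledCandidate:
    mention: Mention
    label: int  # +1 positive, -1 negative


@dataclass
class LabelingResult:
    """Candidates with train labels plus the gold mentions the dictionary
    missed (they can never be retrieved downstream)."""

    labeled: list[LabeledCandidate]
    missed_gold: list[Mention]

    @property
    def n_missed(self) -> int:
        return len(self.missed_gold)


def label_candidates(
    candidates: Sequence[Mention], gold: Iterable[Mention]
) -> LabelingResult:
    """Label each candidate positive iff a gold mention matches it exactly
    (same document, span and entity type); record unfound gold mentions."""
    gold = list(gold)
    gold_keys = {g.key() for g in gold}
    cand_keys = {c.key() for c in candidates}
    labeled = [
        LabeledCandidate(c, +1 if c.key() in gold_keys else -1)
        for c in candidates
    ]
    missed = sorted(g for g in gold if g.key() not in cand_keys)
    return LabelingResult(labeled, missed)
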