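"""The base representations of candidate mentions.

Ten feature maps are computed per candidate, mixing hand-designed and
general-purpose views of the same surface string:

* ``orthographic``  -- 12 grammar features (counts of character classes,
  case flags, Greek letters, dashes, ...);
* ``affixes``       -- 20 features: the occurrence score of the candidate's
  2/3-character prefixes and suffixes in each of 5 terminological
  resources, max-rescaled into [0, 1];
* ``word_norm``     -- 16 word-shape features over the 4-symbol normalized
  token (classes a/A/0/-): per class the total count, longest and shortest
  run, and count in the run-compressed token;
* ``spectrum_1`` .. ``spectrum_5`` -- binary presence of every length-p
  substring of the compressed normalized token (p-spectrum maps, 4**p
  entries each);
* ``embed_domain``, ``embed_general`` -- mean word-embedding of the
  candidate's tokens from a domain-specific and a general-purpose table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import AlignmentError, ConfigurationError
from .io import AFFIX_KINDS, AffixResource, EmbeddingTable, Mention

NORM_ALPHABET = "aA0-"  # fixed order: lowercase, uppercase, digit, symbol

GREEK_NAMES = frozenset(
    "alpha beta gamma delta epsilon zeta eta theta iota kappa lambda mu nu "
    "xi omicron pi rho sigma tau upsilon phi chi psi omega".split()
)

ORTHOGRAPHIC_FEATURE_NAMES = (
    "num_characters", "is_all_uppercase", "is_all_lowercase",
    "contains_greek_letters", "num_dashes", "num_numbers", "ends_with_digit",
    "contains_capital_letters", "num_lowercase", "num_uppercase",
    "num_spaces", "num_symbols",
)

DEFAULT_SPECTRUM_ARITIES = (1, 2, 3, 4, 5)


def _is_greek_char(ch: str) -> bool:
    return "Ͱ" <= ch <= "Ͽ"


def _contains_greek(surface: str) -> bool:
    if any(_is_greek_char(c) for c in surface):
        return True
    token = []
    tokens = []
    for ch in surface:
        if ch.isalpha():
            token.append(ch)
        elif token:
            tokens.append("".join(token))
            token = []
    if token:
        tokens.append("".join(token))
    return any(t.lower() in GREEK_NAMES for t in tokens)


def orthographic_features(surface: str) -> np.ndarray:
    """12 grammar features describing the inner structure of the surface."""
    alpha = [c for c in surface if c.isalpha()]
    n_lower = sum(c.islower() for c in surface)
    n_upper = sum(c.isupper() for c in surface)
    n_digit = sum(c.isdigit() for c in surface)
    n_space = surface.count(" ")
    n_symbol = sum(not c.isalnum() and c != " " for c in surface)
    return np.array(
        [
            len(surface),
            float(bool(alpha) and all(c.isupper() for c in alpha)),
            float(bool(alpha) and all(c.islower() for c in alpha)),
            float(_contains_greek(surface)),
            surface.count("-"),
            n_digit,
            float(bool(surface) and surface[-1].isdigit()),
            float(n_upper > 0),
            n_lower,
            n_upper,
            n_space,
            n_symbol,
        ],
        dtype=np.float64,
    )


def _affixes_of(surface: str) -> dict[str, str | None]:
    """The candidate's own affixes; prefixes come from the first whitespace
    token, suffixes from the last. A length-k affix exists only when the
    token is strictly longer than k."""
    tokens = surface.split()
    first = tokens[0] if tokens else ""
    last = tokens[-1] if tokens else ""
    return {
        "prefix2": first[:2] if len(first) > 2 else None,
        "prefix3": first[:3] if len(first) > 3 else None,
        "suffix2": last[-2:] if len(last) > 2 else None,
        "suffix3": last[-3:] if len(last) > 3 else None,
    }


def affix_features(
    surface: str, resources: Sequence[AffixResource]
) -> np.ndarray:
    """Affix occurrence scores, one block of 4 per resource (resource-major,
    kind order prefix2, prefix3, suffix2, suffix3), each rescaled into
    [0, 1] by the maximum count of that (resource, kind) list."""
    affixes = _affixes_of(surface)
    values = []
    for resource in resources:
        maxima = {kind: 0 for kind in AFFIX_KINDS}
        for (kind, _), count in resource.counts.items():
            maxima[kind] = max(maxima[kind], count)
        for kind in AFFIX_KINDS:
            affix = affixes[kind]
            if affix is None or maxima[kind] == 0:
                values.append(0.0)
            else:
                values.append(
                    resource.counts.get((kind, affix), 0) / maxima[kind]
                )
    return np.asarray(values, dtype=np.float64)


def normalize_surface(surface: str) -> str:
    """Map every character to its class symbol: lowercase -> 'a', uppercase
    -> 'A', digit -> '0', anything else (including spaces) -> '-'."""
    out = []
    for ch in surface:
        if ch.islower():
            out.append("a")
        elif ch.isupper():
            out.append("A")
        elif ch.isdigit():
            out.append("0")
        else:
            out.append("-")
    return "".join(out)


def compress(normalized: str) -> str:
    """Collapse consecutive repetitions: 'AAa0aaa' -> 'Aa0a'."""
    out = []
    for ch in normalized:
        if not out or out[-1] != ch:
            out.append(ch)
    return "".join(out)


def _deduplicate(normalized: str) -> str:
    """Keep only the first occurrence of each symbol (the alternative,
    non-default reading of repetition removal)."""
    seen: list[str] = []
    for ch in normalized:
        if ch not in seen:
            seen.append(ch)
    return "".join(seen)


def _runs(s: str) -> list[tuple[str, int]]:
    runs: list[tuple[str, int]] = []
    for ch in s:
        if runs and runs[-1][0] == ch:
            runs[-1] = (ch, runs[-1][1] + 1)
        else:
            runs.append((ch, 1))
    return runs


def word_shape_features(surface: str) -> np.ndarray:
    """16 word-shape features: for each class symbol in 'aA0-' order, the
    total count, the longest and shortest consecutive run, and the count in
    the compressed token. All four are 0 for an absent class."""
    norm = normalize_surface(surface)
    comp = compress(norm)
    runs = _runs(norm)
    values = []
    for symbol in NORM_ALPHABET:
        lengths = [n for ch, n in runs if ch == symbol]
        values.extend(
            [
                norm.count(symbol),
                max(lengths) if lengths else 0,
                min(lengths) if lengths else 0,
                comp.count(symbol),
            ]
        )
    return np.asarray(values, dtype=np.float64)


def spectrum_features(
    surface: str, p: int, dedup: str = "runs"
) -> np.ndarray:
    """Binary p-spectrum of the compressed normalized surface.

    Entry for substring s (indexed lexicographically over the alphabet
    'a' < 'A' < '0' < '-') is 1 iff s occurs in the compacted token.
    ``dedup`` selects how repetitions are removed: ``"runs"`` collapses
    consecutive repeats (default), ``"global"`` keeps first occurrences only.
    """
    if p not in (1, 2, 3, 4, 5):
        raise ConfigurationError(f"spectrum arity must be in 1..5, got {p}")
    if dedup == "runs":
        token = compress(normalize_surface(surface))
    elif dedup == "global":
        token = _deduplicate(normalize_surface(surface))
    else:
        raise ConfigurationError(f"unknown dedup mode {dedup!r}")
    index = {ch: i for i, ch in enumerate(NORM_ALPHABET)}
    vec = np.zeros(4**p, dtype=np.float64)
    for start in range(len(token) - p + 1):
        code = 0
        for ch in token[start : start + p]:
            code = code * 4 + index[ch]
        vec[code] = 1.0
    return vec


def embedding_features(surface: str, table: EmbeddingTable) -> np.ndarray:
    """Mean embedding of the whitespace tokens of the surface; a token is
    looked up exactly, then casefolded; out-of-vocabulary tokens contribute
    zero vectors."""
    tokens = surface.split()
    if not tokens:
        return np.zeros(table.dimension)
    acc = np.zeros(table.dimension)
    for token in tokens:
        vec = table.vectors.get(token)
        if vec is None:
            vec = table.vectors.get(token.casefold())
        if vec is not None:
            acc += vec
    return acc / len(tokens)


# ---------------------------------------------------------------------------
# the bank


@dataclass(frozen=True)
class RepresentationConfig:
    """Resources and switches controlling which representations are built."""

    affix_resources: tuple[AffixResource, ...] = ()
    embedding_domain: EmbeddingTable | None = None
    embedding_general: EmbeddingTable | None = None
    include_embeddings: bool = True
    spectrum_arities: tuple[int, ...] = DEFAULT_SPECTRUM_ARITIES
    spectrum_dedup: str = "runs"


@dataclass
class RepresentationBank:
    """A named, row-aligned collection of per-candidate feature matrices."""

    names: list[str]
    matrices: dict[str, np.ndarray]
    ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in self.names:
            if self.matrices[name].shape[0] != n:
                raise AlignmentError(
                    f"representation {name!r} has "
                    f"{self.matrices[name].shape[0]} rows, expected {n}"
                )

    def __len__(self) -> int:
        return len(self.ids)

    def matrix(self, name: str) -> np.ndarray:
        return self.matrices[name]

    def widths(self) -> dict[str, int]:
        return {name: self.matrices[name].shape[1] for name in self.names}

    def concatenated(self) -> np.ndarray:
        """Column-concatenation of all representations in bank order."""
        return np.hstack([self.matrices[name] for name in self.names])

    def subset(self, indices: Sequence[int]) -> "RepresentationBank":
        idx = list(indices)
        return RepresentationBank(
            list(self.names),
            {n: self.matrices[n][idx] for n in self.names},
            [self.ids[i] for i in idx],
        )


def mention_id(mention: Mention) -> str:
    return f"{mention.doc_id}:{mention.start}-{mention.end}:{mention.entity_type}"


def build_representation_bank(
    candidates: Sequence[Mention], config: RepresentationConfig
) -> RepresentationBank:
    """Compute every configured representation for every candidate.

    The default configuration yields the 10-entry bank; disabling the
    embedding entries yields 8. Rows are aligned across entries and carry a
    candidate-id manifest used by all downstream kernel code.
    """
    if not config.affix_resources:
        raise ConfigurationError("affix representation requires resources")
    if config.include_embeddings:
        for attr in ("embedding_domain", "embedding_general"):
            if getattr(config, attr) is None:
                raise ConfigurationError(
                    f"embeddings enabled but {attr} table is missing"
                )

    surfaces = [c.surface for c in candidates]
    names: list[str] = ["orthographic", "affixes", "word_norm"]
    matrices: dict[str, np.ndarray] = {
        "orthographic": _stack([orthographic_features(s) for s in surfaces], 12),
        "affixes": _stack(
            [affix_features(s, config.affix_resources) for s in surfaces],
            4 * len(config.affix_resources),
        ),
        "word_norm": _stack([word_shape_features(s) for s in surfaces], 16),
    }
    for p in config.spectrum_arities:
        name = f"spectrum_{p}"
        names.append(name)
        matrices[name] = _stack(
            [spectrum_features(s, p, config.spectrum_dedup) for s in surfaces],
            4**p,
        )
    if config.include_embeddings:
        for name, table in (
            ("embed_domain", config.embedding_domain),
            ("embed_general", config.embedding_general),
        ):
            names.append(name)
            matrices[name] = _stack(
                [embedding_features(s, table) for s in surfaces],
                table.dimension,
            )
    return RepresentationBank(names, matrices, [mention_id(c) for c in candidates])


def _stack(rows: list[np.ndarray], width: int) -> np.ndarray:
    if not rows:
        return np.zeros((0, width))
    return np.vstack(rows)
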