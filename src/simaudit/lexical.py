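"""Lexical normalization of SNOMED CT description terms.

Every description (fully specified name or synonym) is reduced to a *bag of
words*: a lowercase multiset with stop words removed and, by default, the
trailing semantic tag (e.g. ``(procedure)``) stripped.  Two concepts are
lexically similar when some pair of their bags differs by exactly one word on
each side — a symmetric single-word substitution.  Word order never matters,
because bags are multisets.

The comparison is deliberately literal: no stemming, no lemmatization, no
spelling normalization.  "computed" and "computer" are different words, and a
hyphenated token such as "non-surgical" is one word that differs from
"surgical".
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "DEFAULT_STOP_WORDS",
    "NormalizationConfig",
    "TokenBag",
    "WordBag",
    "bag_key",
    "eligible",
    "is_one_word_apart",
    "load_config",
    "normalize_term",
    "semantic_tag",
    "word_difference",
]

#: Word multiset; values are occurrence counts.
WordBag = Counter

#: Minimal stop-word list under which every documented worked example
#: normalizes correctly.  Configurable via :class:`NormalizationConfig`.
DEFAULT_STOP_WORDS = frozenset(
    {"a", "an", "the", "of", "with", "as", "for", "using",
     "to", "from", "by", "in", "on", "and", "or"}
)

_SEMANTIC_TAG_RE = re.compile(r"\s*\([^()]*\)\s*$")
_EDGE_PUNCT = ",.:;"


@dataclass(frozen=True)
class NormalizationConfig:
    """Tunable knobs of term normalization and concept eligibility.

    Parameters
    ----------
    stop_words:
        Lowercase words dropped from every bag.
    min_words:
        Minimum post-stop-word token count of a concept's FSN for the concept
        to take part in similarity-set formation (the five-word rule).
    strip_semantic_tag:
        Remove the trailing parenthesized semantic tag before bagging, so an
        FSN can match a synonym without the tag getting in the way.
    count_tag_for_threshold:
        Count the semantic tag as one word toward ``min_words`` even when it
        is stripped from the comparison bag.
    """

    stop_words: frozenset = DEFAULT_STOP_WORDS
    min_words: int = 5
    strip_semantic_tag: bool = True
    count_tag_for_threshold: bool = True

    def __post_init__(self) -> None:
        if self.min_words < 1:
            raise ValueError("min_words must be >= 1")
        bad = [w for w in self.stop_words if w != w.lower()]
        if bad:
            raise ValueError(f"stop words must be lowercase: {bad}")
        object.__setattr__(self, "stop_words", frozenset(self.stop_words))


DEFAULT_CONFIG = NormalizationConfig()


def load_config(path: str | Path) -> NormalizationConfig:
    """Read a YAML/JSON config file into a :class:`NormalizationConfig`.

    Recognized keys: ``stop_words`` (list), ``min_words``,
    ``strip_semantic_tag``, ``count_tag_for_threshold``.  Missing keys keep
    their defaults.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    kwargs: dict = {}
    if "stop_words" in raw:
        kwargs["stop_words"] = frozenset(str(w).lower() for w in raw["stop_words"])
    for key in ("min_words", "strip_semantic_tag", "count_tag_for_threshold"):
        if key in raw:
            kwargs[key] = raw[key]
    return NormalizationConfig(**kwargs)


def semantic_tag(term: str) -> str | None:
    """Return the trailing semantic tag of *term* without parentheses, if any."""
    m = _SEMANTIC_TAG_RE.search(term)
    if m is None:
        return None
    return m.group(0).strip()[1:-1].strip() or None


def normalize_term(term: str, config: NormalizationConfig = DEFAULT_CONFIG) -> WordBag:
    """Normalize one description term into a word multiset.

    Lowercases, optionally strips the trailing semantic tag, splits on
    whitespace, trims ``,.:;`` from token edges, removes parenthesis
    characters, and drops stop words.  Hyphenated words stay single tokens;
    duplicates are preserved.  A term that reduces to nothing yields an empty
    bag, not an error.
    """
    text = term.strip()
    if config.strip_semantic_tag:
        text = _SEMANTIC_TAG_RE.sub("", text)
    bag: WordBag = Counter()
    for raw in text.lower().split():
        tok = raw.strip(_EDGE_PUNCT).replace("(", "").replace(")", "")
        if tok and tok not in config.stop_words:
            bag[tok] += 1
    return bag


def word_difference(bag_a: WordBag, bag_b: WordBag) -> tuple[WordBag, WordBag]:
    """Two-sided multiset difference ``(a \\ b, b \\ a)``.

    Shared words cancel with multiplicity, so ``{x, x, y} \\ {x, y}`` leaves
    one ``x``.
    """
    return bag_a - bag_b, bag_b - bag_a


def is_one_word_apart(bag_a: WordBag, bag_b: WordBag) -> bool:
    """True iff the bags differ by exactly one word on each side.

    A strict-subset relation (one side empty, the other one word) does not
    qualify: similarity is a single-word *substitution*, which entails equal
    bag sizes.
    """
    a_only, b_only = word_difference(bag_a, bag_b)
    return a_only.total() == 1 and b_only.total() == 1


def eligible(fsn_term: str, config: NormalizationConfig = DEFAULT_CONFIG) -> bool:
    """Five-word rule: does this FSN qualify its concept for set formation?

    Counts the FSN's post-stop-word tokens; the semantic tag contributes one
    word when ``count_tag_for_threshold`` is set and the tag is not already
    part of the bag.
    """
    bag = normalize_term(fsn_term, config)
    n = bag.total()
    if (
        config.count_tag_for_threshold
        and config.strip_semantic_tag
        and semantic_tag(fsn_term) is not None
    ):
        n += 1
    return n >= config.min_words


def bag_key(bag: WordBag) -> tuple[str, ...]:
    """Canonical hashable form of a word bag: sorted tuple with multiplicity."""
    return tuple(sorted(bag.elements()))


@dataclass(frozen=True)
class TokenBag:
    """A normalized description of one concept, ready for comparison.

    ``tokens`` is the canonical sorted tuple (see :func:`bag_key`); use
    :meth:`bag` for the Counter view.
    """

    concept_id: str
    description_id: str
    kind: str  # "FSN" or "SYNONYM"
    tokens: tuple[str, ...]

    @classmethod
    def from_term(
        cls,
        concept_id: str,
        description_id: str,
        kind: str,
        term: str,
        config: NormalizationConfig = DEFAULT_CONFIG,
    ) -> "TokenBag":
        return cls(concept_id, description_id, kind, bag_key(normalize_term(term, config)))

    def bag(self) -> WordBag:
        return Counter(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)
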