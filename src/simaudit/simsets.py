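"""Building similarity sets from normalized token bags.

A similarity set is two or more concepts whose descriptions differ pairwise
by exactly one word.  Sets are found with a shared-template index: every bag
of n words is filed n times, once under each (n-1)-word sub-multiset obtained
by removing one occurrence of one distinct word.  Two bags share an index key
exactly when they are one single-word substitution apart, so every key with
two or more distinct concepts (carrying distinct substituted words) is a
similarity set — and the pairwise property holds within the set by
construction, sidestepping the non-transitivity of "one word apart".

``pairwise_oracle`` is the brute-force O(n^2) reference used in tests; it is
independent of the index.
"""

from __future__ import annotations

import hashlib
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .lexical import TokenBag, WordBag, bag_key, is_one_word_apart

__all__ = [
    "SimilaritySet",
    "build_sets",
    "build_template_index",
    "form_sets",
    "pairs_in_sets",
    "pairwise_oracle",
    "set_digest",
]

#: Index key: (canonical template tuple, full bag size).
TemplateKey = tuple[tuple[str, ...], int]

#: Index entry: (concept_id, description_id, kind, substituted word).
Entry = tuple[str, str, str, str]


def set_digest(member_ids: Iterable[str]) -> str:
    """Stable set identifier: digest of the sorted member ids joined with '|'."""
    joined = "|".join(sorted(member_ids))
    return hashlib.sha1(joined.encode("utf-8")).hexdigest()[:16]


@dataclass(frozen=True)
class SimilaritySet:
    """A deduplicated group of concepts pairwise one word apart.

    ``template`` is the shared word multiset (canonical sorted tuple); each
    member's evidence bag equals template + its differing word.  ``evidence``
    maps a member to the (description_id, kind) of the matched description.
    """

    set_id: str
    member_ids: frozenset
    template: tuple[str, ...]
    differing: Mapping[str, str]      # concept_id -> substituted word
    evidence: Mapping[str, tuple]     # concept_id -> (description_id, kind)

    @property
    def size(self) -> int:
        return len(self.member_ids)

    def member_bag(self, concept_id: str) -> WordBag:
        bag = Counter(self.template)
        bag[self.differing[concept_id]] += 1
        return bag

    def sorted_members(self) -> list[str]:
        return sorted(self.member_ids, key=_id_order)


def _id_order(identifier: str):
    # Numeric-aware ordering for digit-string SCTIDs; falls back to lexicographic.
    return (len(identifier), identifier)


def build_template_index(bags: Iterable[TokenBag]) -> dict:
    """File every bag under each one-word-removed template.

    A bag of n distinct words produces n entries.  Only bags of eligible
    concepts should be passed in; the index itself applies no threshold.
    """
    index: dict[TemplateKey, list[Entry]] = defaultdict(list)
    for tb in bags:
        bag = tb.bag()
        size = bag.total()
        for word in sorted(bag):
            template = bag.copy()
            template[word] -= 1
            key = (bag_key(template), size)
            index[key].append((tb.concept_id, tb.description_id, tb.kind, word))
    return dict(index)


def _entry_rank(entry: Entry):
    # Evidence tie-break: FSN first, then smallest description id.
    _, description_id, kind, _ = entry
    return (0 if kind == "FSN" else 1, _id_order(description_id))


def form_sets(index: Mapping[TemplateKey, Sequence[Entry]]) -> list[SimilaritySet]:
    """Emit deduplicated similarity sets from a template index.

    Per key: one evidence entry per concept (FSN preferred, then smallest
    description id); at most one concept per substituted word (smallest
    concept id wins if two concepts carry identical bags); the key yields a
    set when >= 2 concepts with >= 2 distinct substituted words remain.  A
    candidate whose member set duplicates an earlier emission is dropped, so
    a pair similar via both FSNs and synonyms yields one set.  Keys are
    processed in canonical order, making the output independent of input
    ordering.
    """
    sets: list[SimilaritySet] = []
    seen_memberships: set[frozenset] = set()
    for key in sorted(index):
        template, _size = key
        entries = index[key]

        by_concept: dict[str, Entry] = {}
        for entry in sorted(entries, key=_entry_rank):
            by_concept.setdefault(entry[0], entry)

        by_word: dict[str, Entry] = {}
        for concept_id in sorted(by_concept, key=_id_order):
            entry = by_concept[concept_id]
            word = entry[3]
            if word not in by_word:
                by_word[word] = entry

        if len(by_word) < 2:
            continue
        members = frozenset(entry[0] for entry in by_word.values())
        if len(members) < 2 or members in seen_memberships:
            continue
        seen_memberships.add(members)
        differing = {entry[0]: word for word, entry in by_word.items()}
        evidence = {entry[0]: (entry[1], entry[2]) for entry in by_word.values()}
        sets.append(
            SimilaritySet(
                set_id=set_digest(members),
                member_ids=members,
                template=template,
                differing=differing,
                evidence=evidence,
            )
        )
    return sets


def build_sets(bags: Iterable[TokenBag]) -> list[SimilaritySet]:
    """Convenience: index the bags and form sets in one call."""
    return form_sets(build_template_index(bags))


def pairwise_oracle(bags: Sequence[TokenBag]) -> set[tuple[str, str]]:
    """Exhaustive cross-concept search for one-word-apart pairs.

    Quadratic; intended for small test instances (<= ~500 bags).  Returns
    sorted (concept_a, concept_b) tuples with a < b in canonical id order.
    """
    pairs: set[tuple[str, str]] = set()
    counters = [(tb.concept_id, tb.bag()) for tb in bags]
    for i, (cid_a, bag_a) in enumerate(counters):
        for cid_b, bag_b in counters[i + 1:]:
            if cid_a == cid_b:
                continue
            if is_one_word_apart(bag_a, bag_b):
                pairs.add(tuple(sorted((cid_a, cid_b), key=_id_order)))
    return pairs


def pairs_in_sets(sets: Iterable[SimilaritySet]) -> set[tuple[str, str]]:
    """All unordered member pairs occurring together in at least one set."""
    pairs: set[tuple[str, str]] = set()
    for s in sets:
        members = s.sorted_members()
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                pairs.add((a, b))
    return pairs
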