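# Methods

## The model

`simaudit` operationalizes one assumption: concepts whose descriptions are
nearly identical should be structurally modeled nearly identically. The
unit of analysis is the *similarity set* — two or more concepts in one
hierarchy whose normalized descriptions differ pairwise by exactly one
word — and the screen compares, within each set, three per-concept counts:
parents (active is-a relationships), attributes (active non-is-a
relationships) and role groups (distinct nonzero relationship-group
numbers). Count disagreement anywhere in a set makes it a Diff_Set, a
candidate for manual audit; agreement makes it a Same_Set. The comparison
is deliberately count-based only: two members can both have, say, two
attributes of entirely different types and still classify as Same. Value-
level discrepancies are visible to the auditor in the report rows but do
not enter classification, and the tool never renders an inconsistency
verdict — the report's verdict column is emitted empty.

## Normalization rules

A term becomes a lowercase word **multiset**: the trailing semantic tag
`(...)` is removed (configurable), the text splits on whitespace, `,.;:`
are trimmed from token edges, parenthesis characters are deleted, stop
words are dropped, hyphenated words stay single tokens, and duplicate
words keep their multiplicity. Multisets make word order irrelevant by
construction, which is what lets "Surgical biopsy of gastrointestinal
tract" match "Non-surgical gastrointestinal tract biopsy" up to one word.

Deliberate non-features: no stemming, lemmatization or spelling
normalization ("computed" ≠ "computer" — collapsing them would merge pairs
the method counts as three words apart), and numerals are ordinary tokens.

*Stop words.* The default list is the minimal one under which every
documented example behaves correctly:
`a an the of with as for using to from by in on and or`. It is
configurable (`stop_words` in the YAML config) and the effective list is
written to the run log, since the set membership of borderline pairs can
depend on it.

*Parentheses.* Only a trailing `(...)` is treated as a semantic tag;
mid-term parentheses are not removed as a group, but the bracket characters
themselves are deleted from tokens so no token ever contains one.

*One word apart* means exactly one exclusive word on **each** side (equal
bag sizes follow). A strict subset — one description merely adding a word
to another — does not qualify; the relation is a substitution, which is
symmetric and matches every documented pair.

*Eligibility.* Only concepts whose FSN has ≥ `min_words` (default 5)
post-stop-word tokens participate, with the semantic tag counted as one
token toward the threshold (both switches configurable). The tag-counting
choice is what admits 4-content-word FSNs such as "Referral to young
disabled service (procedure)". Eligibility gates the whole concept: an
ineligible FSN also withholds the concept's synonyms, since the threshold
is defined on fully specified terms.

## Set formation

Each n-word bag is filed under its n one-word-removed templates, keyed by
(template multiset, bag size). Sharing a key is *equivalent* to being one
substitution apart, so any key holding ≥ 2 distinct concepts with ≥ 2
distinct substituted words is a similarity set, and pairwise similarity
inside a set holds by construction — the set semantics is "one set per
shared template", which keeps the non-transitivity of the pairwise relation
from ever producing an invalid set. Clique-style merging of overlapping
pairs was considered and rejected as underdetermined: it can join concepts
that are two words apart.

Determinism and dedup rules:

- evidence tie-break per concept at a key: FSN before synonym, then the
  smallest description id;
- if two concepts present identical bags at one key (same substituted
  word), the smallest concept id represents that word — identical bags are
  zero words apart, so they cannot co-occupy a set;
- candidates whose membership duplicates an earlier set are dropped (one
  set per concept group, however many description pairs support it); keys
  are processed in canonical sorted order, so output is independent of
  input ordering;
- `set_id` is a SHA-1 digest prefix of the sorted member ids joined with
  `|` — stable across runs and machines.

A concept may belong to several distinct sets; coverage statistics count it
once. FSN-vs-synonym matches are allowed (tags stripped), so a pair whose
FSNs differ by three words can still set through synonyms.

The brute-force `pairwise_oracle` (all cross-concept bag pairs tested
directly) is kept in the package as the independent reference; tests assert
exact agreement between its pair list and the pairs inside formed sets on
generated releases.

## Structural profiling

Only outgoing rows are profiled (the screen compares parents, not
children). Group 0 is the RF2 "ungrouped" convention and never counts as a
role group; each distinct nonzero group number counts once, and each
attribute row counts individually toward the attribute count. Which
relationship file to feed — stated or inferred — is the caller's choice and
is recorded in the run log; the tool is agnostic.

## Sampling and reporting

The audit sample is a uniform draw without replacement from Diff_Sets of
2–4 members (both bounds configurable), driven by a single integer seed
recorded in the run log. Percentages in summaries are printed to 0
decimals (half rounded up). The full report bundle — per-member CSV,
sampled-set CSV, JSON-lines sets, classifications, summary, run log —
contains no timestamps and is written in canonical order, so a rerun with
identical inputs, config and seed is byte-identical; tests assert this
file-for-file.

## The synthetic release generator

Real releases cannot ship, so `simaudit.fixtures` generates structurally
valid RF2 snapshot triples with known ground truth:

- **Template families** (default 30 per release): 2–4 concepts sharing an
  (n−1)-word template with unique substituted words — each family must
  surface as exactly one set. Family sizes default to 60/25/15 % for
  2/3/4 members, matching the audit's 2–4 size window.
- **Synonym-only families** (default 5 % of families): member FSNs two
  words apart, synonyms one word apart — the set must form with synonym
  evidence, emulating the pelvis/pancreas shape.
- **Structural planting:** per family, independent Diff-Par/Diff-Rel/
  Diff-Grp flags with default rates 0.52/0.34/0.16, realized by giving one
  member an extra parent, an extra attribute, or a regrouping at equal
  attribute count. The defaults put the expected Diff share near 73 % with
  subtype prevalence ordered Par > Rel > Grp; under independent flags the
  conditional subtype shares cannot simultaneously be matched, and the
  marginal split was preferred. A family with no flag drawn is a Same
  family.
- **Decoys:** sub-threshold FSN pairs (3 content words + tag, one word
  apart but ineligible) and eligible pairs exactly two words apart. Neither
  may appear in any set.
- **Inactive rows** (a concept, a description, a relationship) that the
  pipeline must ignore.

The separation guarantee — that planted sets are the *only* sets — comes
from giving every family and every two-word decoy concept two words drawn
from a reserved, non-reused slice of the vocabulary: bags from different
families are then always ≥ 2 words apart, so recall and precision against
the manifest are exactly 1.0 by design and any deviation is a pipeline
bug. A spec whose family count exceeds the reserved-word budget fails fast
("vocabulary exhausted"). The bundled vocabulary (30 clinical prefixes ×
12 suffixes plus ~70 modifier words) supports up to ~170 families; it is
configurable.

What the generator does not emulate: realistic word-frequency
distributions (real descriptions share much more vocabulary, which the
template index handles but the fixtures do not stress), description
inactivation history, multi-hierarchy attributes, and concepts whose FSNs
collide across hierarchies. Passing on fixtures therefore demonstrates
algorithmic correctness of set formation and classification, not the
release-scale prevalence of inconsistencies; release-level magnitudes
(set counts, 73/27 splits, synonym contribution) require a licensed
release and are computed by the same code paths when one is supplied.

Synthetic identifiers are digit strings from a reserved range and are not
valid SCTIDs (no check digit); no licensed content is redistributed beyond
a handful of concept names quoted in the published literature, which the
`paper_examples_fixture` re-creates with synthetic ids and hand-assigned
profile shapes matching their described modeling.

## Problem sizes

Defaults were chosen at desk scale: releases of ~100 concepts for unit
fixtures and a 120-family (~430-concept) release for the end-to-end
reproduction script, where the quadratic oracle and repeated pipeline runs
stay comfortable. The template index itself is linear in total bag words
and handles release-scale hierarchies; only the test oracle is quadratic.

## Known limitations

- Count-based classification misses same-count modeling errors and flags
  legitimate asymmetries (some lexical neighbors *should* differ); the
  flagged sets are candidates, with precision established only by human
  audit.
- Concepts whose every description is under five words are invisible to
  the screen (about two-thirds of a real hierarchy, by the published
  account).
- Snapshot releases only; Full/Delta files, OWL conversion, ECL and
  description-logic classification are out of scope.
- The exact stop-word list of the original study is unrecoverable; results
  on real releases will vary slightly with this list, which is why it is
  logged.
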