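# simaudit

Contextual lexical auditing of SNOMED CT.

SNOMED CT is the standard clinical reference terminology used in electronic
health records. Its concepts are defined structurally — parent (is-a)
relationships, attribute relationships, and role groups that bundle
attributes — and modeling inconsistencies in those definitions degrade
queries and clinical decision support. Auditing half a million concepts one
by one is infeasible, so `simaudit` implements a *contextual* screen for
terminology quality-assurance teams: concepts that are worded almost
identically ought to be modeled almost identically, and places where they
are not are high-yield candidates for manual review.

## Method

1. **Normalization.** Every active description (fully specified name and
   synonyms) of every concept in the chosen hierarchy is reduced to a
   lowercase bag of words: the trailing semantic tag `(...)` is stripped,
   stop words (`a, an, the, of, with, …`) are removed, and word order is
   discarded. Only concepts whose FSN has ≥ 5 words after stop-word removal
   (semantic tag included) take part.
2. **Similarity sets.** Two concepts are lexically similar when some pair of
   their bags differs by exactly one word on each side — a single-word
   substitution, e.g. *tarsometatarsal* vs *midtarsal* arthrodesis. Groups
   of ≥ 2 pairwise-similar concepts form a *similarity set*, found
   efficiently by filing each n-word bag under its n one-word-removed
   templates; duplicate sets are suppressed. A pair may qualify through
   synonyms even when the FSNs differ by several words.
3. **Structural comparison.** Each concept is profiled by three counts:
   parents (active is-a rows), attributes (active non-is-a rows) and role
   groups (distinct nonzero relationship groups). Sets whose members share
   all three counts are **Same_Sets**; any mismatch makes a **Diff_Set**,
   flagged `Diff-Par` / `Diff-Rel` / `Diff-Grp` by the disagreeing count
   (flags may overlap).
4. **Audit sample.** A seeded uniform sample of Diff_Sets (default 50 sets
   of 2–4 concepts) is written to an auditor-ready report — members, matched
   terms, differing words, profile triples, flags — with the verdict column
   left empty: the tool nominates candidates, the human judges them.

Real SNOMED CT releases are license-restricted, so the package ships a
synthetic RF2 snapshot generator that plants similarity sets, structural
discrepancies and decoys with a ground-truth manifest; the entire pipeline
is tested against it, plus a fixture of published concept pairs.

## Worked example

```bash
simaudit fixtures --seed 9 --out release/        # synthetic RF2 snapshot
simaudit run \
  --concepts release/sct2_Concept_Snapshot.txt \
  --descriptions release/sct2_Description_Snapshot.txt \
  --relationships release/sct2_Relationship_Snapshot.txt \
  --root 9000001 --sample-size 50 --seed 4 --out out/
```

prints (for the default 30-family fixture):

```
Similarity sets: 30 (Diff_Sets 27 = 90%, Same_Sets 3 = 10%)
Concepts covered by at least one set: 71
  Diff-Par       sets=18     concepts=44     60% of all sets
  Diff-Rel       sets=12     concepts=29     40% of all sets
  Diff-Grp       sets=7      concepts=16     23% of all sets
  Diff overall   sets=27     concepts=64     90% of all sets
  Same overall   sets=3      concepts=7      10% of all sets
Sets enabled by synonyms: 2 (adding 4 concepts)
Audit sample: 27 sets -> out/
```

Reading: the tool found 30 similarity sets; 90 % of them contain at least
one member modeled with a different number of parents, attributes or role
groups than its lexical neighbors, and those Diff_Sets (here fewer than the
requested 50, so all 27) land in `out/audit_sample.csv` for manual review.
The same library API is available programmatically via
`simaudit.run_audit(...)`. On a licensed SNOMED CT release, point `--root`
at a hierarchy root (the Procedure hierarchy `71388002` is the default) to
reproduce release-scale statistics.

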