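"""Structural profiling of concepts and Same/Diff classification of sets.

The working assumption of contextual auditing: lexically similar concepts
should be modeled alike.  Each concept's outgoing modeling is summarized as
three counts — parents (active is-a rows), attributes (active non-is-a rows)
and role groups (distinct nonzero relationshipGroup values among the
attributes; group 0 means ungrouped).  A similarity set where all members
share the same triple is a Same_Set; any count mismatch makes it a Diff_Set,
flagged Diff-Par / Diff-Rel / Diff-Grp by which count disagrees (flags are
not mutually exclusive).

The comparison is count-based only.  Value-level discrepancies (different
attribute types or targets behind equal counts) are left for the human
auditor, who sees the full rows in the report.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from .rf2 import IS_A, RelationshipRecord
from .simsets import SimilaritySet

__all__ = ["StructuralProfile", "SetClassification", "profile", "build_profiles", "classify"]


@dataclass(frozen=True)
class StructuralProfile:
    concept_id: str
    parent_count: int
    attribute_count: int
    role_group_count: int

    @property
    def triple(self) -> tuple[int, int, int]:
        return (self.parent_count, self.attribute_count, self.role_group_count)


@dataclass(frozen=True)
class SetClassification:
    set_id: str
    kind: str  # "SAME" or "DIFF"
    diff_par: bool
    diff_rel: bool
    diff_grp: bool

    def flags(self) -> list[str]:
        out = []
        if self.diff_par:
            out.append("Diff-Par")
        if self.diff_rel:
            out.append("Diff-Rel")
        if self.diff_grp:
            out.append("Diff-Grp")
        return out


def profile(concept_id: str, relationships: Iterable[RelationshipRecord]) -> StructuralProfile:
    """Profile one concept from its active outgoing relationship rows."""
    parents = 0
    attributes = 0
    groups: set[int] = set()
    for rel in relationships:
        if not rel.active or rel.source_id != concept_id:
            continue
        if rel.type_id == IS_A:
            parents += 1
        else:
            attributes += 1
            if rel.relationship_group != 0:
                groups.add(rel.relationship_group)
    return StructuralProfile(concept_id, parents, attributes, len(groups))


def build_profiles(
    concept_ids: Iterable[str], relationships: Iterable[RelationshipRecord]
) -> dict[str, StructuralProfile]:
    """Profile many concepts in one pass; absent concepts get all-zero profiles."""
    wanted = set(concept_ids)
    parents: dict[str, int] = defaultdict(int)
    attributes: dict[str, int] = defaultdict(int)
    groups: dict[str, set[int]] = defaultdict(set)
    for rel in relationships:
        cid = rel.source_id
        if not rel.active or cid not in wanted:
            continue
        if rel.type_id == IS_A:
            parents[cid] += 1
        else:
            attributes[cid] += 1
            if rel.relationship_group != 0:
                groups[cid].add(rel.relationship_group)
    return {
        cid: StructuralProfile(cid, parents[cid], attributes[cid], len(groups[cid]))
        for cid in wanted
    }


def classify(
    simset: SimilaritySet, profiles: Mapping[str, StructuralProfile]
) -> SetClassification:
    """Classify one similarity set from its members' structural profiles."""
    missing = sorted(m for m in simset.member_ids if m not in profiles)
    if missing:
        raise ValueError(f"no structural profile for set {simset.set_id} members: {missing}")
    triples = [profiles[m].triple for m in simset.member_ids]
    diff_par = len({t[0] for t in triples}) > 1
    diff_rel = len({t[1] for t in triples}) > 1
    diff_grp = len({t[2] for t in triples}) > 1
    kind = "DIFF" if (diff_par or diff_rel or diff_grp) else "SAME"
    return SetClassification(simset.set_id, kind, diff_par, diff_rel, diff_grp)
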