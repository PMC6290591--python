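"""End-to-end audit pipeline: RF2 snapshot in, auditor report out.

Steps: read the three snapshot files; keep active rows; restrict to the
chosen hierarchy (descendants-or-self of the root over active is-a edges);
apply the five-word FSN eligibility rule; normalize every FSN and synonym of
the eligible concepts into word bags; build deduplicated similarity sets;
profile and classify each set as Same_Set or Diff_Set; summarize; draw the
seeded audit sample; write the report bundle.

A second, FSN-only set-formation pass quantifies what the synonyms buy: how
many sets exist only because of a synonym match, and how many concepts those
sets add to coverage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .audit import AuditSample, SummaryTable, sample_sets, summarize, write_report
from .lexical import DEFAULT_CONFIG, NormalizationConfig, TokenBag, eligible
from .rf2 import (
    PROCEDURE_ROOT,
    DescriptionType,
    hierarchy_members,
    read_concepts,
    read_descriptions,
    read_relationships,
)
from .simsets import SimilaritySet, build_sets, _id_order
from .structural import SetClassification, StructuralProfile, build_profiles, classify

__all__ = ["AuditRun", "prepare_bags", "run_audit"]


@dataclass
class AuditRun:
    """Everything a pipeline run produced, for programmatic use."""

    sets: list[SimilaritySet]
    classifications: dict[str, SetClassification]
    profiles: dict[str, StructuralProfile]
    summary: SummaryTable
    selected: list[str]
    fsn_terms: dict[str, str]
    counts: dict[str, int]
    report_paths: dict[str, Path] | None = None


def _config_hash(config: NormalizationConfig) -> str:
    canonical = json.dumps(
        {
            "stop_words": sorted(config.stop_words),
            "min_words": config.min_words,
            "strip_semantic_tag": config.strip_semantic_tag,
            "count_tag_for_threshold": config.count_tag_for_threshold,
        },
        sort_keys=True,
    )
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:12]


def prepare_bags(
    descriptions,
    members: set[str],
    config: NormalizationConfig = DEFAULT_CONFIG,
) -> tuple[list[TokenBag], dict[str, str], dict[str, str]]:
    """Select FSNs, apply the five-word rule, and normalize descriptions.

    Returns ``(bags, fsn_terms, term_lookup)``: the token bags of every
    eligible hierarchy member's active FSNs and synonyms, the FSN per member
    (smallest description id on duplicates), and raw terms by description id.
    Eligibility gates the whole concept — an ineligible FSN excludes the
    concept's synonyms too.
    """
    fsn_terms: dict[str, str] = {}
    for d in sorted(descriptions, key=lambda d: _id_order(d.description_id)):
        if (
            d.active
            and d.type is DescriptionType.FSN
            and d.concept_id in members
            and d.concept_id not in fsn_terms
        ):
            fsn_terms[d.concept_id] = d.term

    eligible_ids = {cid for cid, term in fsn_terms.items() if eligible(term, config)}

    bags: list[TokenBag] = []
    term_lookup: dict[str, str] = {}
    for d in descriptions:
        if not d.active or d.concept_id not in eligible_ids:
            continue
        if d.type is DescriptionType.FSN:
            kind = "FSN"
        elif d.type is DescriptionType.SYNONYM:
            kind = "SYNONYM"
        else:
            continue
        tb = TokenBag.from_term(d.concept_id, d.description_id, kind, d.term, config)
        if tb.tokens:
            bags.append(tb)
            term_lookup[d.description_id] = d.term
    return bags, fsn_terms, term_lookup


def run_audit(
    concepts_path: str | Path,
    descriptions_path: str | Path,
    relationships_path: str | Path,
    *,
    root_id: str = PROCEDURE_ROOT,
    config: NormalizationConfig = DEFAULT_CONFIG,
    sample: AuditSample | None = None,
    seed: int = 0,
    language: str | None = None,
    out_dir: str | Path | None = None,
) -> AuditRun:
    """Run the full contextual audit and optionally write the report bundle.

    ``seed`` drives the audit-sample draw (ignored if an explicit ``sample``
    is given).  ``language`` optionally restricts descriptions by
    languageCode.  Which relationship file to feed (stated or inferred) is
    the caller's choice and is recorded in the run log.
    """
    if sample is None:
        sample = AuditSample(seed=seed)

    concepts = read_concepts(concepts_path)
    descriptions = read_descriptions(descriptions_path, language_filter=language)
    relationships = read_relationships(relationships_path)

    active_concepts = [c for c in concepts if c.active]
    active_rels = [r for r in relationships if r.active]
    members = hierarchy_members(root_id, active_concepts, active_rels)

    bags, fsn_terms, term_lookup = prepare_bags(descriptions, members, config)
    eligible_ids = {cid for cid, term in fsn_terms.items() if eligible(term, config)}

    sets = build_sets(bags)

    # What did synonyms contribute?  Compare against an FSN-only pass.
    fsn_sets = build_sets([b for b in bags if b.kind == "FSN"])
    fsn_memberships = {s.member_ids for s in fsn_sets}
    synonym_enabled = sum(1 for s in sets if s.member_ids not in fsn_memberships)
    covered_full = set().union(*(s.member_ids for s in sets)) if sets else set()
    covered_fsn = set().union(*(s.member_ids for s in fsn_sets)) if fsn_sets else set()
    synonym_added_concepts = len(covered_full - covered_fsn)

    profiles = build_profiles(covered_full, active_rels)
    classifications = {s.set_id: classify(s, profiles) for s in sets}

    summary = summarize(
        sets,
        classifications,
        synonym_enabled_sets=synonym_enabled,
        synonym_added_concepts=synonym_added_concepts,
    )
    selected = sample_sets(classifications, sets, sample) if sets else []

    counts = {
        "concepts_read": len(concepts),
        "active_concepts": len(active_concepts),
        "hierarchy_members": len(members),
        "eligible_concepts": len(eligible_ids),
        "token_bags": len(bags),
        "similarity_sets": len(sets),
        "same_sets": summary.same_sets,
        "diff_sets": summary.diff_sets,
        "concepts_in_sets": summary.total_concepts,
        "synonym_enabled_sets": synonym_enabled,
        "synonym_added_concepts": synonym_added_concepts,
        "sample_selected": len(selected),
    }

    run = AuditRun(
        sets=sets,
        classifications=classifications,
        profiles=profiles,
        summary=summary,
        selected=selected,
        fsn_terms=fsn_terms,
        counts=counts,
    )

    if out_dir is not None:
        log_lines = [
            f"simaudit {__version__}",
            f"root_id: {root_id}",
            f"relationships_file: {Path(relationships_path).name}",
            f"config_hash: {_config_hash(config)}",
            f"stop_words: {' '.join(sorted(config.stop_words))}",
            f"min_words: {config.min_words}",
            f"strip_semantic_tag: {config.strip_semantic_tag}",
            f"count_tag_for_threshold: {config.count_tag_for_threshold}",
            f"sample: size={sample.sample_size} max_set_size={sample.max_set_size} "
            f"kind={sample.kind_filter} seed={sample.seed}",
        ] + [f"count {k}: {v}" for k, v in counts.items()]
        run.report_paths = write_report(
            out_dir,
            sets=sets,
            classifications=classifications,
            profiles=profiles,
            selected=selected,
            fsn_terms=fsn_terms,
            term_lookup=term_lookup,
            summary=summary,
            run_log_lines=log_lines,
        )
    return run
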