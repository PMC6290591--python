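"""Audit sampling, summary tables and report writing."""

import math

import pytest

from simaudit.audit import AuditSample, sample_sets, summarize, write_report
from simaudit.simsets import SimilaritySet, set_digest
from simaudit.structural import SetClassification, StructuralProfile


def _simset(*member_ids, template=("t1", "t2", "t3", "t4")):
    members = frozenset(member_ids)
    return SimilaritySet(
        set_id=set_digest(members),
        member_ids=members,
        template=template,
        differing={m: f"w{i}" for i, m in enumerate(sorted(members))},
        evidence={m: (f"d{m}", "FSN") for m in sorted(members)},
    )


def _cls(set_id, kind, par=False, rel=False, grp=False):
    if kind == "DIFF" and not (par or rel or grp):
        par = True
    return SetClassification(set_id, kind, par and kind == "DIFF", rel, grp)


def _pool(n_diff, n_same=0, size=2):
    sets, classifications = [], {}
    for i in range(n_diff + n_same):
        members = tuple(str(100 * i + j) for j in range(size))
        s = _simset(*members)
        sets.append(s)
        kind = "DIFF" if i < n_diff else "SAME"
        classifications[s.set_id] = _cls(s.set_id, kind)
    return sets, classifications


def test_small_pool_returns_everything():
    sets, classifications = _pool(3)
    selected = sample_sets(classifications, sets, AuditSample(sample_size=50, seed=1))
    assert sorted(selected) == sorted(s.set_id for s in sets)


def test_same_seed_same_selection():
    sets, classifications = _pool(200)
    plan = AuditSample(sample_size=50, seed=42)
    first = sample_sets(classifications, sets, plan)
    second = sample_sets(classifications, sets, plan)
    assert first == second
    assert len(first) == 50 and len(set(first)) == 50


def test_sample_respects_kind_and_size_constraints():
    sets, classifications = _pool(30, n_same=30)
    big = _simset(*(str(9000 + i) for i in range(5)))
    sets.append(big)
    classifications[big.set_id] = _cls(big.set_id, "DIFF")
    selected = sample_sets(classifications, sets, AuditSample(sample_size=100, seed=0))
    by_id = {s.set_id: s for s in sets}
    assert big.set_id not in selected
    for set_id in selected:
        assert classifications[set_id].kind == "DIFF"
        assert by_id[set_id].size <= 4
    assert len(selected) == 30


def test_empty_pool_warns_and_returns_nothing():
    sets, classifications = _pool(0, n_same=3)
    with pytest.warns(UserWarning, match="empty"):
        assert sample_sets(classifications, sets, AuditSample(seed=1)) == []


def test_sampling_is_uniform_over_seeds():
    """Choosing 5 of 20 across 2000 seeds: inclusion rate ~ 25% per set."""
    sets, classifications = _pool(20)
    counts = {s.set_id: 0 for s in sets}
    reps = 2000
    for seed in range(reps):
        for set_id in sample_sets(
            classifications, sets, AuditSample(sample_size=5, seed=seed)
        ):
            counts[set_id] += 1
    p = 5 / 20
    tolerance = 3 * math.sqrt(p * (1 - p) / reps)
    for set_id, hits in counts.items():
        assert abs(hits / reps - p) < tolerance


def test_summary_share_arithmetic():
    sets, classifications = _pool(6, n_same=2)
    table = summarize(sets, classifications)
    assert table.total_sets == 8
    assert table.diff_sets == 6 and table.same_sets == 2
    assert table.pct_diff == 75 and table.pct_same == 25
    assert table.total_concepts == 16  # disjoint pairs


def test_summary_counts_shared_concepts_once():
    a = _simset("1", "2")
    b = _simset("2", "3", template=("q1", "q2", "q3", "q4"))
    classifications = {s.set_id: _cls(s.set_id, "DIFF") for s in (a, b)}
    table = summarize([a, b], classifications)
    assert table.total_concepts == 3


def test_summary_zero_sets_degenerate():
    table = summarize([], {})
    assert table.total_sets == 0
    assert table.pct_diff == 0 and table.pct_same == 0
    assert all(r.n_sets == 0 for r in table.rows)


def test_summary_subtype_rows_match_planted_fixture(synthetic_release):
    from simaudit.pipeline import run_audit

    paths, manifest = synthetic_release
    run = run_audit(
        paths["concepts"], paths["descriptions"], paths["relationships"],
        root_id=manifest.root_id, seed=0,
    )
    by_label = {r.label: r for r in run.summary.rows}
    assert by_label["Diff-Par"].n_sets == manifest.counts["diff_par_sets"]
    assert by_label["Diff-Rel"].n_sets == manifest.counts["diff_rel_sets"]
    assert by_label["Diff-Grp"].n_sets == manifest.counts["diff_grp_sets"]
    assert by_label["Diff overall"].n_sets == manifest.counts["diff_sets"]
    assert run.summary.total_concepts == manifest.counts["concepts_in_sets"]


def _report_inputs(n_diff=3, n_same=1):
    sets, classifications = _pool(n_diff, n_same=n_same)
    profiles = {}
    fsn_terms = {}
    term_lookup = {}
    for s in sets:
        for m in s.member_ids:
            profiles[m] = StructuralProfile(m, 1, 2, 1)
            fsn_terms[m] = f"Concept {m} fully specified name (procedure)"
            term_lookup[f"d{m}"] = fsn_terms[m]
    summary = summarize(sets, classifications)
    return sets, classifications, profiles, fsn_terms, term_lookup, summary


def test_report_rows_and_flags(tmp_path):
    sets, classifications, profiles, fsn_terms, term_lookup, summary = _report_inputs()
    selected = sample_sets(classifications, sets, AuditSample(sample_size=2, seed=3))
    paths = write_report(
        tmp_path / "out",
        sets=sets, classifications=classifications, profiles=profiles,
        selected=selected, fsn_terms=fsn_terms, term_lookup=term_lookup,
        summary=summary, run_log_lines=["test run"],
    )
    import pandas as pd

    full = pd.read_csv(paths["similarity_sets"], keep_default_na=False)
    assert len(full) == sum(s.size for s in sets)
    for _, row in full.iterrows():
        if row["set_kind"] == "DIFF":
            assert row["flags"] != ""
        assert row["auditor_verdict"] == ""  # verdict left to the human auditor

    sample = pd.read_csv(paths["audit_sample"], keep_default_na=False)
    assert sorted(sample["set_id"].unique()) == sorted(selected)
    assert (tmp_path / "out" / "run.log").read_text() == "test run\n"


def test_report_is_byte_identical_across_runs(tmp_path):
    sets, classifications, profiles, fsn_terms, term_lookup, summary = _report_inputs()
    selected = sample_sets(classifications, sets, AuditSample(sample_size=2, seed=3))
    outputs = []
    for name in ("a", "b"):
        paths = write_report(
            tmp_path / name,
            sets=sets, classifications=classifications, profiles=profiles,
            selected=selected, fsn_terms=fsn_terms, term_lookup=term_lookup,
            summary=summary, run_log_lines=["log"],
        )
        outputs.append({k: p.read_bytes() for k, p in paths.items()})
    assert outputs[0] == outputs[1]
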