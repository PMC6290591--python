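"""RF2 snapshot readers and the is-a hierarchy closure."""

import pytest

from simaudit.rf2 import (
    IS_A,
    FSN_TYPE_ID,
    SYNONYM_TYPE_ID,
    DescriptionType,
    RF2FormatError,
    hierarchy_members,
    read_concepts,
    read_descriptions,
    read_relationships,
)

CONCEPT_HEADER = "id\teffectiveTime\tactive\tmoduleId\tdefinitionStatusId\n"
DESCRIPTION_HEADER = (
    "id\teffectiveTime\tactive\tmoduleId\tconceptId\tlanguageCode\ttypeId\tterm\tcaseSignificanceId\n"
)
RELATIONSHIP_HEADER = (
    "id\teffectiveTime\tactive\tmoduleId\tsourceId\tdestinationId\trelationshipGroup"
    "\ttypeId\tcharacteristicTypeId\tmodifierId\n"
)
MOD = "900000000000207008"


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


def test_read_concepts_counts_and_active_flag(tmp_path):
    path = _write(
        tmp_path, "c.txt",
        CONCEPT_HEADER
        + f"101\t20180131\t1\t{MOD}\tstat\n"
        + f"102\t20180131\t0\t{MOD}\tstat\n",
    )
    records = read_concepts(path)
    assert len(records) == 2
    assert records[0].active is True
    assert records[1].active is False


def test_read_concepts_wrong_column_count_reports_line(tmp_path):
    path = _write(tmp_path, "c.txt", CONCEPT_HEADER + "101\t20180131\t1\n")
    with pytest.raises(RF2FormatError, match=":2:"):
        read_concepts(path)


def test_read_concepts_missing_file():
    with pytest.raises(FileNotFoundError):
        read_concepts("/nonexistent/sct2_Concept.txt")


def test_read_concepts_rejects_nondigit_id(tmp_path):
    path = _write(tmp_path, "c.txt", CONCEPT_HEADER + f"10a\t20180131\t1\t{MOD}\ts\n")
    with pytest.raises(RF2FormatError, match="digits-only"):
        read_concepts(path)


def _desc_row(did, cid, type_id, term, active="1", lang="en"):
    return f"{did}\t20180131\t{active}\t{MOD}\t{cid}\t{lang}\t{type_id}\t{term}\tcase\n"


def test_read_descriptions_type_mapping_and_grouping(tmp_path):
    rows = [
        _desc_row(1, 101, FSN_TYPE_ID, "Fully specified (procedure)"),
        _desc_row(2, 101, SYNONYM_TYPE_ID, "A synonym"),
        _desc_row(3, 101, SYNONYM_TYPE_ID, "Another synonym"),
        _desc_row(4, 101, SYNONYM_TYPE_ID, "Third synonym"),
        _desc_row(5, 101, SYNONYM_TYPE_ID, "Fourth synonym"),
    ]
    path = _write(tmp_path, "d.txt", DESCRIPTION_HEADER + "".join(rows))
    records = read_descriptions(path)
    assert len(records) == 5
    assert {r.concept_id for r in records} == {"101"}
    assert records[0].type is DescriptionType.FSN
    assert all(r.type is DescriptionType.SYNONYM for r in records[1:])


def test_read_descriptions_unknown_type_warns_and_keeps_other(tmp_path):
    path = _write(
        tmp_path, "d.txt",
        DESCRIPTION_HEADER + _desc_row(1, 101, "900000000000550004", "Definition text"),
    )
    with pytest.warns(UserWarning, match="unknown description typeId"):
        records = read_descriptions(path)
    assert records[0].type is DescriptionType.OTHER


def test_read_descriptions_language_filter(tmp_path):
    rows = [
        _desc_row(1, 101, FSN_TYPE_ID, "English term (procedure)", lang="en"),
        _desc_row(2, 101, SYNONYM_TYPE_ID, "Termino espanol", lang="es"),
    ]
    path = _write(tmp_path, "d.txt", DESCRIPTION_HEADER + "".join(rows))
    assert len(read_descriptions(path, language_filter="en")) == 1


def _rel_row(rid, src, dst, group, type_id, active="1"):
    return f"{rid}\t20180131\t{active}\t{MOD}\t{src}\t{dst}\t{group}\t{type_id}\tchar\tmod\n"


def test_read_relationships_parses_group(tmp_path):
    path = _write(
        tmp_path, "r.txt",
        RELATIONSHIP_HEADER
        + _rel_row(1, 102, 101, 0, IS_A)
        + _rel_row(2, 102, 103, 2, "260686004"),
    )
    records = read_relationships(path)
    assert [r.relationship_group for r in records] == [0, 2]
    assert records[0].type_id == IS_A


def test_read_relationships_noninteger_group_reports_line(tmp_path):
    path = _write(
        tmp_path, "r.txt",
        RELATIONSHIP_HEADER + _rel_row(1, 102, 101, 0, IS_A) + _rel_row(2, 102, 103, "x", IS_A),
    )
    with pytest.raises(RF2FormatError, match=":3:"):
        read_relationships(path)


def test_read_relationships_rejects_self_is_a(tmp_path):
    path = _write(tmp_path, "r.txt", RELATIONSHIP_HEADER + _rel_row(1, 101, 101, 0, IS_A))
    with pytest.raises(RF2FormatError, match="source == destination"):
        read_relationships(path)


def _make_concepts(tmp_path, ids, inactive=()):
    rows = "".join(
        f"{i}\t20180131\t{'0' if i in inactive else '1'}\t{MOD}\tstat\n" for i in ids
    )
    return read_concepts(_write(tmp_path, "c.txt", CONCEPT_HEADER + rows))


def _make_rels(tmp_path, edges, inactive_edges=()):
    rows = []
    for n, (child, parent) in enumerate(edges, start=1):
        rows.append(_rel_row(n, child, parent, 0, IS_A))
    for n, (child, parent) in enumerate(inactive_edges, start=len(edges) + 1):
        rows.append(_rel_row(n, child, parent, 0, IS_A, active="0"))
    return read_relationships(_write(tmp_path, "r.txt", RELATIONSHIP_HEADER + "".join(rows)))


def test_hierarchy_root_with_no_children(tmp_path):
    concepts = _make_concepts(tmp_path, ["1"])
    assert hierarchy_members("1", concepts, []) == {"1"}


def test_hierarchy_transitive_chain(tmp_path):
    concepts = _make_concepts(tmp_path, ["1", "2", "3"])
    rels = _make_rels(tmp_path, [("3", "2"), ("2", "1")])
    assert hierarchy_members("1", concepts, rels) == {"1", "2", "3"}


def test_hierarchy_excludes_inactive_concepts_and_edges(tmp_path):
    concepts = _make_concepts(tmp_path, ["1", "2", "3", "4"], inactive={"2"})
    rels = _make_rels(tmp_path, [("2", "1"), ("3", "2")], inactive_edges=[("4", "1")])
    # inactive 2 neither appears nor transmits reachability; inactive edge ignored
    assert hierarchy_members("1", concepts, rels) == {"1"}


def test_hierarchy_absent_root_fatal(tmp_path):
    concepts = _make_concepts(tmp_path, ["1"])
    with pytest.raises(ValueError, match="root concept"):
        hierarchy_members("9", concepts, [])


def test_hierarchy_cycle_fatal(tmp_path):
    concepts = _make_concepts(tmp_path, ["1", "2", "3"])
    rels = _make_rels(tmp_path, [("2", "1"), ("3", "2"), ("2", "3")])
    with pytest.raises(RF2FormatError, match="cycle"):
        hierarchy_members("1", concepts, rels)


def _brute_force_members(root, concepts, relationships):
    """Independent fixed-point computation over the edge list."""
    active = {c.concept_id for c in concepts if c.active}
    members = {root}
    changed = True
    while changed:
        changed = False
        for r in relationships:
            if (
                r.active
                and r.type_id == IS_A
                and r.destination_id in members
                and r.source_id in active
                and r.source_id not in members
            ):
                members.add(r.source_id)
                changed = True
    return members


def test_hierarchy_matches_brute_force_on_synthetic_release(synthetic_release):
    paths, manifest = synthetic_release
    concepts = read_concepts(paths["concepts"])
    rels = read_relationships(paths["relationships"])
    members = hierarchy_members(manifest.root_id, concepts, rels)
    assert members == _brute_force_members(manifest.root_id, concepts, rels)
    assert members == set(manifest.hierarchy_members)


def test_removing_an_is_a_edge_never_grows_membership(synthetic_release):
    paths, manifest = synthetic_release
    concepts = read_concepts(paths["concepts"])
    rels = read_relationships(paths["relationships"])
    full = hierarchy_members(manifest.root_id, concepts, rels)
    isa_idx = [i for i, r in enumerate(rels) if r.active and r.type_id == IS_A]
    for i in isa_idx[::7]:  # spot-check a deterministic slice
        reduced = rels[:i] + rels[i + 1:]
        assert hierarchy_members(manifest.root_id, concepts, reduced) <= full


def test_round_trip_counts_match_manifest(synthetic_release):
    paths, manifest = synthetic_release
    assert len(read_concepts(paths["concepts"])) == manifest.row_counts["concepts"]
    assert len(read_descriptions(paths["descriptions"])) == manifest.row_counts["descriptions"]
    assert len(read_relationships(paths["relationships"])) == manifest.row_counts["relationships"]
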