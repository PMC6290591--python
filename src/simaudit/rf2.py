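"""Reading SNOMED CT RF2 snapshot files.

Only the Snapshot distribution is supported: one row per component carrying
its current state.  The three files of interest are the concept, description
and relationship snapshots — UTF-8, tab-separated, unquoted, first row the
standard RF2 header.  Readers return every row with the ``active`` flag
parsed; callers filter to active components (the pipeline does so
immediately).

Also provides the is-a transitive closure used to restrict an audit run to a
single hierarchy (by default SNOMED's Procedure hierarchy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "IS_A",
    "FSN_TYPE_ID",
    "SYNONYM_TYPE_ID",
    "PROCEDURE_ROOT",
    "ConceptRecord",
    "DescriptionRecord",
    "DescriptionType",
    "RelationshipRecord",
    "RF2FormatError",
    "hierarchy_members",
    "read_concepts",
    "read_descriptions",
    "read_relationships",
]

# Standard SNOMED CT metadata identifiers.
IS_A = "116680003"
FSN_TYPE_ID = "900000000000003001"
SYNONYM_TYPE_ID = "900000000000013009"
PROCEDURE_ROOT = "71388002"

CONCEPT_COLUMNS = ("id", "effectiveTime", "active", "moduleId", "definitionStatusId")
DESCRIPTION_COLUMNS = (
    "id", "effectiveTime", "active", "moduleId", "conceptId",
    "languageCode", "typeId", "term", "caseSignificanceId",
)
RELATIONSHIP_COLUMNS = (
    "id", "effectiveTime", "active", "moduleId", "sourceId", "destinationId",
    "relationshipGroup", "typeId", "characteristicTypeId", "modifierId",
)


class RF2FormatError(ValueError):
    """A structural problem in an RF2 file (wrong columns, bad values, cycles)."""


class DescriptionType(str, Enum):
    FSN = "FSN"
    SYNONYM = "SYNONYM"
    OTHER = "OTHER"


_TYPE_ID_MAP = {FSN_TYPE_ID: DescriptionType.FSN, SYNONYM_TYPE_ID: DescriptionType.SYNONYM}


@dataclass(frozen=True)
class ConceptRecord:
    concept_id: str
    effective_time: str
    active: bool
    module_id: str
    definition_status_id: str


@dataclass(frozen=True)
class DescriptionRecord:
    description_id: str
    concept_id: str
    type: DescriptionType
    term: str
    active: bool
    language_code: str


@dataclass(frozen=True)
class RelationshipRecord:
    relationship_id: str
    source_id: str
    destination_id: str
    type_id: str
    relationship_group: int
    active: bool
    characteristic_type_id: str


def _iter_rows(path: str | Path, columns: Sequence[str]):
    """Yield (1-based line number, fields) for each data row, validating shape.

    RF2 is unquoted TSV, so a plain tab split is exact.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"RF2 file not found: {path}")
    n = len(columns)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        header_line = fh.readline()
        if not header_line:
            raise RF2FormatError(f"{path}: empty file, expected RF2 header")
        header = header_line.rstrip("\r\n").split("\t")
        if len(header) != n:
            raise RF2FormatError(
                f"{path}:1: header has {len(header)} columns, expected {n} ({columns[0]} ...)"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n:
                raise RF2FormatError(
                    f"{path}:{lineno}: expected {n} columns, found {len(fields)}"
                )
            yield lineno, fields


def _parse_active(value: str, path, lineno: int) -> bool:
    if value not in ("0", "1"):
        raise RF2FormatError(f"{path}:{lineno}: active flag must be '0' or '1', got {value!r}")
    return value == "1"


def read_concepts(path: str | Path) -> list[ConceptRecord]:
    """Read a sct2_Concept snapshot file."""
    records = []
    for lineno, f in _iter_rows(path, CONCEPT_COLUMNS):
        cid = f[0]
        if not cid.isdigit():
            raise RF2FormatError(f"{path}:{lineno}: concept id must be digits-only, got {cid!r}")
        records.append(
            ConceptRecord(
                concept_id=cid,
                effective_time=f[1],
                active=_parse_active(f[2], path, lineno),
                module_id=f[3],
                definition_status_id=f[4],
            )
        )
    return records


def read_descriptions(
    path: str | Path, language_filter: str | None = None
) -> list[DescriptionRecord]:
    """Read a sct2_Description snapshot file.

    ``language_filter`` keeps only rows with that languageCode (e.g. "en").
    Unknown description typeIds are kept with ``type=OTHER`` and a warning.
    """
    records = []
    for lineno, f in _iter_rows(path, DESCRIPTION_COLUMNS):
        language = f[5]
        if language_filter is not None and language != language_filter:
            continue
        dtype = _TYPE_ID_MAP.get(f[6])
        if dtype is None:
            warnings.warn(
                f"{path}:{lineno}: unknown description typeId {f[6]!r}, keeping as OTHER",
                stacklevel=2,
            )
            dtype = DescriptionType.OTHER
        active = _parse_active(f[2], path, lineno)
        term = f[7]
        if active and not term:
            raise RF2FormatError(f"{path}:{lineno}: active description with empty term")
        records.append(
            DescriptionRecord(
                description_id=f[0],
                concept_id=f[4],
                type=dtype,
                term=term,
                active=active,
                language_code=language,
            )
        )
    return records


def read_relationships(path: str | Path) -> list[RelationshipRecord]:
    """Read a sct2_Relationship snapshot file (stated or inferred — caller's choice)."""
    records = []
    for lineno, f in _iter_rows(path, RELATIONSHIP_COLUMNS):
        try:
            group = int(f[6])
        except ValueError:
            raise RF2FormatError(
                f"{path}:{lineno}: relationshipGroup must be an integer, got {f[6]!r}"
            ) from None
        if group < 0:
            raise RF2FormatError(f"{path}:{lineno}: relationshipGroup must be >= 0")
        active = _parse_active(f[2], path, lineno)
        if active and f[7] == IS_A and f[4] == f[5]:
            raise RF2FormatError(f"{path}:{lineno}: active is-a relationship with source == destination")
        records.append(
            RelationshipRecord(
                relationship_id=f[0],
                source_id=f[4],
                destination_id=f[5],
                type_id=f[7],
                relationship_group=group,
                active=active,
                characteristic_type_id=f[8],
            )
        )
    return records


def hierarchy_members(
    root_id: str,
    concepts: Iterable[ConceptRecord],
    relationships: Iterable[RelationshipRecord],
) -> set[str]:
    """Descendants-or-self of *root_id* over active is-a edges.

    Only active concepts participate: an inactive concept neither appears in
    the result nor transmits reachability.  A cycle among active is-a edges is
    a fatal modeling error and is reported with the offending edge list.
    """
    active_ids = {c.concept_id for c in concepts if c.active}
    if root_id not in active_ids:
        raise ValueError(f"root concept {root_id} is not an active concept")

    # Parent -> child orientation: an is-a row points source (child) at
    # destination (parent), so reachability from the root follows reversed edges.
    graph: nx.DiGraph = nx.DiGraph()
    graph.add_nodes_from(active_ids)
    for rel in relationships:
        if rel.active and rel.type_id == IS_A:
            if rel.source_id in active_ids and rel.destination_id in active_ids:
                graph.add_edge(rel.destination_id, rel.source_id)

    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise RF2FormatError(f"cycle among is-a relationships: {cycle}")

    members = set(nx.descendants(graph, root_id))
    members.add(root_id)
    return members
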