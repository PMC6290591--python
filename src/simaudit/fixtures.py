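"""Synthetic RF2 snapshot releases with planted ground truth.

The real SNOMED CT releases are license-restricted, so the pipeline is
exercised on generated releases instead: structurally valid concept /
description / relationship snapshot triples containing

* *template families* — groups of 2-4 concepts sharing an (n-1)-word
  template and differing by one substituted word each, so they must surface
  as exactly one similarity set apiece;
* *synonym-only families* — members whose FSNs are two words apart but whose
  synonyms are one word apart, so the set forms only through synonyms;
* planted structural discrepancies (parent / attribute / role-group count
  mismatches) realizing the Diff-Par / Diff-Rel / Diff-Grp flags;
* *decoys* — concepts below the five-word eligibility threshold, and
  eligible pairs exactly two words apart, neither of which may appear in any
  emitted set;
* inactive concepts, descriptions and relationships, which must be ignored.

Every family's word material includes two words unique to that family, so
bags from different families are always at least two words apart and the
planted sets are exactly the sets the pipeline can find.  Generation is
fully driven by one seed and writes byte-identical files on repetition.

Synthetic identifiers come from a reserved numeric range and are NOT valid
SCTIDs (no check digit); the content is invented and carries no licensed
SNOMED material beyond standard metadata identifiers.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .rf2 import FSN_TYPE_ID, IS_A, SYNONYM_TYPE_ID

__all__ = [
    "DEFAULT_VOCABULARY",
    "FixtureSpec",
    "GroundTruthManifest",
    "PAPER_EXAMPLE_SETS",
    "generate_release",
    "paper_examples_fixture",
]

_EFFECTIVE_TIME = "20180131"
_MODULE = "900000000000207008"
_PRIMITIVE = "900000000000074008"
_CASE = "900000000000448009"
_INFERRED = "900000000000011006"
_MODIFIER = "900000000000451002"

#: Attribute-type identifiers cycled over when realizing attribute rows
#: (Method, Procedure site - Direct, Has intent, Procedure site).
_ATTRIBUTE_TYPES = ("260686004", "405813007", "363703001", "363704007")

_PREFIXES = (
    "angio", "arthro", "cardio", "cranio", "gastro", "hepato", "nephro",
    "neuro", "osteo", "thoraco", "dermato", "entero", "colono", "broncho",
    "laryngo", "rhino", "oto", "ophthalmo", "cysto", "uretero", "duodeno",
    "spleno", "thyro", "adeno", "myo", "phlebo", "lympho", "tracheo",
    "pleuro", "recto",
)
_SUFFIXES = (
    "plasty", "scopy", "tomy", "stomy", "ectomy", "centesis",
    "graphy", "pexy", "desis", "rrhaphy", "lysis", "clasis",
)
_MODIFIER_WORDS = (
    "anterior", "posterior", "lateral", "medial", "proximal", "distal",
    "superior", "inferior", "bilateral", "unilateral", "partial", "total",
    "radical", "simple", "open", "closed", "guided", "staged", "primary",
    "secondary", "revision", "diagnostic", "therapeutic", "elective",
    "emergency", "endoscopic", "percutaneous", "laparoscopic", "transverse",
    "longitudinal", "segmental", "subtotal", "wedge", "core", "needle",
    "incisional", "excisional", "left", "right", "upper", "lower", "deep",
    "superficial", "acute", "chronic", "repair", "removal", "insertion",
    "replacement", "reconstruction", "exploration", "drainage", "fixation",
    "release", "transfer", "graft", "implant", "lesion", "structure",
    "region", "margin", "wall", "tract", "duct", "vessel", "muscle",
    "tendon", "ligament", "joint", "membrane", "node", "lobe",
)

#: Default word list: family-unique compounds plus a shared modifier pool.
DEFAULT_VOCABULARY = tuple(p + s for p in _PREFIXES for s in _SUFFIXES) + _MODIFIER_WORDS


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic release.

    ``family_sizes`` is a distribution over set sizes 2-4 (the audit's
    size bound).  The diff-flag fractions are drawn independently per family;
    a family with no flag drawn is a Same family.  Defaults target roughly
    the 73%/27% Diff/Same split with Diff-Par the most and Diff-Grp the
    least common subtype.
    """

    seed: int = 0
    n_template_families: int = 30
    family_sizes: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.60, 3: 0.25, 4: 0.15}
    )
    fraction_synonym_only_matches: float = 0.05
    fraction_diff_par: float = 0.52
    fraction_diff_rel: float = 0.34
    fraction_diff_grp: float = 0.16
    n_decoys_below_threshold: int = 10
    n_decoys_two_words_apart: int = 10
    vocabulary: tuple = DEFAULT_VOCABULARY

    def __post_init__(self) -> None:
        for name in (
            "fraction_synonym_only_matches",
            "fraction_diff_par",
            "fraction_diff_rel",
            "fraction_diff_grp",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(size < 2 for size in self.family_sizes):
            raise ValueError("family sizes must be >= 2")
        if self.n_template_families < 0:
            raise ValueError("n_template_families must be >= 0")


@dataclass
class GroundTruthManifest:
    """What the generator planted, for exact comparison with pipeline output."""

    seed: int
    root_id: str
    expected_sets: list  # dicts: member_ids, template, differing, evidence_kind, classification
    hierarchy_members: list
    decoy_ids: list
    ineligible_ids: list
    row_counts: dict
    counts: dict

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "root_id": self.root_id,
            "expected_sets": self.expected_sets,
            "hierarchy_members": self.hierarchy_members,
            "decoy_ids": self.decoy_ids,
            "ineligible_ids": self.ineligible_ids,
            "row_counts": self.row_counts,
            "counts": self.counts,
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


class _ReleaseBuilder:
    """Accumulates RF2 rows and writes the snapshot triple."""

    def __init__(self) -> None:
        self.concept_rows: list[tuple] = []
        self.description_rows: list[tuple] = []
        self.relationship_rows: list[tuple] = []
        self._next_concept = 9000001
        self._next_description = 8100001
        self._next_relationship = 8200001

    def new_concept_id(self) -> str:
        cid = str(self._next_concept)
        self._next_concept += 1
        return cid

    def concept(self, cid: str | None = None, active: bool = True) -> str:
        if cid is None:
            cid = self.new_concept_id()
        self.concept_rows.append(
            (cid, _EFFECTIVE_TIME, "1" if active else "0", _MODULE, _PRIMITIVE)
        )
        return cid

    def description(
        self, concept_id: str, term: str, type_id: str = FSN_TYPE_ID,
        active: bool = True, language: str = "en",
    ) -> str:
        did = str(self._next_description)
        self._next_description += 1
        self.description_rows.append(
            (did, _EFFECTIVE_TIME, "1" if active else "0", _MODULE,
             concept_id, language, type_id, term, _CASE)
        )
        return did

    def relationship(
        self, source: str, destination: str, type_id: str,
        group: int = 0, active: bool = True,
    ) -> str:
        rid = str(self._next_relationship)
        self._next_relationship += 1
        self.relationship_rows.append(
            (rid, _EFFECTIVE_TIME, "1" if active else "0", _MODULE,
             source, destination, str(group), type_id, _INFERRED, _MODIFIER)
        )
        return rid

    def add_profile(
        self, cid: str, parents: Sequence[str], n_attributes: int, n_groups: int,
        value_ids: Sequence[str],
    ) -> None:
        """Realize a (parent, attribute, role-group) count triple as rows."""
        for parent in parents:
            self.relationship(cid, parent, IS_A)
        for i in range(n_attributes):
            group = (i % n_groups) + 1 if n_groups > 0 else 0
            self.relationship(
                cid,
                value_ids[i % len(value_ids)],
                _ATTRIBUTE_TYPES[i % len(_ATTRIBUTE_TYPES)],
                group=group,
            )

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        headers = {
            "concepts": ("id", "effectiveTime", "active", "moduleId", "definitionStatusId"),
            "descriptions": ("id", "effectiveTime", "active", "moduleId", "conceptId",
                             "languageCode", "typeId", "term", "caseSignificanceId"),
            "relationships": ("id", "effectiveTime", "active", "moduleId", "sourceId",
                              "destinationId", "relationshipGroup", "typeId",
                              "characteristicTypeId", "modifierId"),
        }
        names = {
            "concepts": "sct2_Concept_Snapshot.txt",
            "descriptions": "sct2_Description_Snapshot.txt",
            "relationships": "sct2_Relationship_Snapshot.txt",
        }
        rows = {
            "concepts": self.concept_rows,
            "descriptions": self.description_rows,
            "relationships": self.relationship_rows,
        }
        paths = {}
        for key in ("concepts", "descriptions", "relationships"):
            path = out / names[key]
            with open(path, "w", encoding="utf-8", newline="") as fh:
                fh.write("\t".join(headers[key]) + "\n")
                for row in rows[key]:
                    fh.write("\t".join(row) + "\n")
            paths[key] = path
        return paths


def _render_term(words: Sequence[str], rng: random.Random, tag: str | None) -> str:
    order = list(words)
    rng.shuffle(order)
    text = " ".join(order)
    text = text[0].upper() + text[1:]
    if tag:
        text += f" ({tag})"
    return text


def _scaffold(builder: _ReleaseBuilder, n_anchors: int = 5, n_values: int = 4):
    """Root, anchor parents and attribute-value concepts shared by all fixtures."""
    root = builder.concept()
    builder.description(root, "Synthetic procedure hierarchy (procedure)")
    anchors = []
    _NUM = ("one", "two", "three", "four", "five", "six")
    for i in range(n_anchors):
        cid = builder.concept()
        builder.description(cid, f"Anchor procedure {_NUM[i]} (procedure)")
        builder.relationship(cid, root, IS_A)
        anchors.append(cid)
    value_root = builder.concept()
    builder.description(value_root, "Synthetic value hierarchy (qualifier value)")
    values = []
    for i in range(n_values):
        cid = builder.concept()
        builder.description(cid, f"Target value {_NUM[i]} (qualifier value)")
        builder.relationship(cid, value_root, IS_A)
        values.append(cid)
    return root, anchors, values


def generate_release(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[dict[str, Path], GroundTruthManifest]:
    """Generate one synthetic snapshot release plus its ground-truth manifest.

    Raises ``ValueError`` when the vocabulary cannot supply the per-family
    unique words the guarantees require.
    """
    rng = random.Random(spec.seed)
    vocab = sorted(set(spec.vocabulary))
    rng.shuffle(vocab)
    n_unique = 2 * spec.n_template_families + 2 * spec.n_decoys_two_words_apart
    if n_unique + 24 > len(vocab):
        raise ValueError(
            f"vocabulary exhausted: need {n_unique} family-unique words plus a "
            f"shared pool, have {len(vocab)} words"
        )
    unique_pool = vocab[:n_unique]
    shared_pool = vocab[n_unique:]
    next_unique = iter(unique_pool)

    builder = _ReleaseBuilder()
    root, anchors, values = _scaffold(builder)
    hierarchy = {root, *anchors}
    expected_sets: list[dict] = []
    decoy_ids: list[str] = []
    ineligible_ids: list[str] = []

    sizes = sorted(spec.family_sizes)
    weights = [spec.family_sizes[s] for s in sizes]

    for _family in range(spec.n_template_families):
        m = rng.choices(sizes, weights=weights)[0]
        synonym_only = rng.random() < spec.fraction_synonym_only_matches
        diff_par = rng.random() < spec.fraction_diff_par
        diff_rel = rng.random() < spec.fraction_diff_rel
        diff_grp = rng.random() < spec.fraction_diff_grp

        k_shared = rng.randint(2, 4)
        draw = rng.sample(shared_pool, k_shared + 2 * m)
        template = sorted([next(next_unique), next(next_unique)] + draw[:k_shared])
        subs = draw[k_shared:k_shared + m]
        extras = draw[k_shared + m:]

        p = rng.randint(1, 3)
        a = rng.randint(2, 4)
        g = 1 if diff_grp else rng.randint(0, min(2, a))
        base = (p, a, g)
        variant = (
            p + (1 if diff_par else 0),
            a + (1 if diff_rel else 0),
            2 if diff_grp else g,
        )

        member_ids = []
        differing = {}
        for j in range(m):
            cid = builder.concept()
            member_ids.append(cid)
            hierarchy.add(cid)
            differing[cid] = subs[j]
            if synonym_only:
                fsn_words = template + [subs[j], extras[j]]
                builder.description(cid, _render_term(fsn_words, rng, "procedure"))
                builder.description(
                    cid,
                    _render_term(template + [subs[j]], rng, None),
                    type_id=SYNONYM_TYPE_ID,
                )
            else:
                builder.description(
                    cid, _render_term(template + [subs[j]], rng, "procedure")
                )
            pj, aj, gj = variant if j == m - 1 else base
            builder.add_profile(cid, anchors[:pj], aj, gj, values)

        kind = "DIFF" if (diff_par or diff_rel or diff_grp) else "SAME"
        expected_sets.append(
            {
                "member_ids": sorted(member_ids),
                "template": template,
                "differing": {cid: differing[cid] for cid in sorted(member_ids)},
                "evidence_kind": "SYNONYM" if synonym_only else "FSN",
                "classification": {
                    "kind": kind,
                    "diff_par": diff_par,
                    "diff_rel": diff_rel,
                    "diff_grp": diff_grp,
                },
            }
        )

    # Decoys below the five-word threshold: one-word-apart pairs whose FSNs
    # have only three content words (+ tag), so they are never eligible.
    for i in range(spec.n_decoys_below_threshold):
        if i % 2 == 0:
            base_words = rng.sample(shared_pool, 4)
        cid = builder.concept()
        words = base_words[:2] + [base_words[2 + (i % 2)]]
        builder.description(cid, _render_term(words, rng, "procedure"))
        builder.add_profile(cid, anchors[:1], 1, 0, values)
        hierarchy.add(cid)
        decoy_ids.append(cid)
        ineligible_ids.append(cid)

    # Decoys exactly two words apart: eligible, but no single-word substitution.
    for i in range(spec.n_decoys_two_words_apart):
        if i % 2 == 0:
            pair_base = rng.sample(shared_pool, 3)
        cid = builder.concept()
        words = pair_base + [next(next_unique), next(next_unique)]
        builder.description(cid, _render_term(words, rng, "procedure"))
        builder.add_profile(cid, anchors[:1], 1, 0, values)
        hierarchy.add(cid)
        decoy_ids.append(cid)

    # Inactive material the pipeline must ignore.
    inactive_cid = builder.concept(active=False)
    builder.description(inactive_cid, "Inactive decoy procedure concept record (procedure)")
    builder.relationship(inactive_cid, root, IS_A)
    if expected_sets:
        first_member = expected_sets[0]["member_ids"][0]
        builder.description(
            first_member, "Inactive synonym row", type_id=SYNONYM_TYPE_ID, active=False
        )
        builder.relationship(
            first_member, values[0], _ATTRIBUTE_TYPES[0], group=0, active=False
        )

    paths = builder.write(out_dir)

    n_diff = sum(1 for s in expected_sets if s["classification"]["kind"] == "DIFF")
    counts = {
        "expected_sets": len(expected_sets),
        "same_sets": len(expected_sets) - n_diff,
        "diff_sets": n_diff,
        "diff_par_sets": sum(1 for s in expected_sets if s["classification"]["diff_par"]),
        "diff_rel_sets": sum(1 for s in expected_sets if s["classification"]["diff_rel"]),
        "diff_grp_sets": sum(1 for s in expected_sets if s["classification"]["diff_grp"]),
        "synonym_only_sets": sum(
            1 for s in expected_sets if s["evidence_kind"] == "SYNONYM"
        ),
        "concepts_in_sets": sum(len(s["member_ids"]) for s in expected_sets),
    }
    manifest = GroundTruthManifest(
        seed=spec.seed,
        root_id=root,
        expected_sets=expected_sets,
        hierarchy_members=sorted(hierarchy),
        decoy_ids=decoy_ids,
        ineligible_ids=ineligible_ids,
        row_counts={
            "concepts": len(builder.concept_rows),
            "descriptions": len(builder.description_rows),
            "relationships": len(builder.relationship_rows),
        },
        counts=counts,
    )
    with open(Path(out_dir) / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths, manifest


# ---------------------------------------------------------------------------
# Documented worked examples: five concept pairs with their published wording,
# re-created here with synthetic identifiers and hand-assigned structural
# profiles matching the described modeling shapes.

_PAPER_ROOT = "9900001"
_PAPER_ANCHORS = ("9900011", "9900012", "9900013")
_PAPER_VALUES = ("9900021", "9900022")

_PAPER_CONCEPTS = (
    # (concept id, FSN, synonyms, (parents, attributes, role groups))
    ("9901001",
     "Tarsometatarsal arthrodesis, transverse, with osteotomy as for flatfoot correction (procedure)",
     (), (2, 4, 2)),
    ("9901002",
     "Midtarsal arthrodesis, transverse, with osteotomy as for flatfoot correction (procedure)",
     (), (2, 4, 2)),
    ("9902001",
     "Drainage of lesion of pelvis using computed tomography guidance (procedure)",
     ("CT guided drainage of lesion of pelvis",), (2, 4, 2)),
    ("9902002",
     "Computer tomography guided drainage of pancreatic lesion (procedure)",
     ("CT guided drainage of pancreatic lesion",), (3, 6, 2)),
    ("9903001", "Surgical biopsy of gastrointestinal tract (procedure)", (), (1, 2, 1)),
    ("9903002", "Non-surgical gastrointestinal tract biopsy (procedure)", (), (1, 2, 1)),
    ("9904001", "Gross operation repair of omphalocele, first stage (procedure)", (), (2, 2, 1)),
    ("9904002", "Gross operation repair of omphalocele, second stage (procedure)", (), (1, 2, 1)),
    ("9905001", "Referral to young disabled service (procedure)", (), (1, 1, 1)),
    ("9905002", "Discharge from young disabled service (procedure)", (), (1, 0, 0)),
)

#: Expected similarity sets in the worked-example fixture:
#: (member ids, evidence kind, classification flags).
PAPER_EXAMPLE_SETS = (
    (frozenset({"9901001", "9901002"}), "FSN",
     {"kind": "SAME", "diff_par": False, "diff_rel": False, "diff_grp": False}),
    (frozenset({"9902001", "9902002"}), "SYNONYM",
     {"kind": "DIFF", "diff_par": True, "diff_rel": True, "diff_grp": False}),
    (frozenset({"9903001", "9903002"}), "FSN",
     {"kind": "SAME", "diff_par": False, "diff_rel": False, "diff_grp": False}),
    (frozenset({"9904001", "9904002"}), "FSN",
     {"kind": "DIFF", "diff_par": True, "diff_rel": False, "diff_grp": False}),
    (frozenset({"9905001", "9905002"}), "FSN",
     {"kind": "DIFF", "diff_par": False, "diff_rel": True, "diff_grp": True}),
)

PAPER_FIXTURE_ROOT = _PAPER_ROOT


def paper_examples_fixture(out_dir: str | Path) -> dict[str, Path]:
    """Write the worked-example fixture; root concept id is ``PAPER_FIXTURE_ROOT``."""
    builder = _ReleaseBuilder()
    builder.concept(_PAPER_ROOT)
    builder.description(_PAPER_ROOT, "Procedure (procedure)")
    for i, cid in enumerate(_PAPER_ANCHORS):
        builder.concept(cid)
        builder.description(cid, f"Anchor parent {'one two three'.split()[i]} (procedure)")
        builder.relationship(cid, _PAPER_ROOT, IS_A)
    value_root = builder.concept("9900020")
    builder.description(value_root, "Example value hierarchy (qualifier value)")
    for cid in _PAPER_VALUES:
        builder.concept(cid)
        builder.description(cid, "Example target value (qualifier value)")
        builder.relationship(cid, value_root, IS_A)
    for cid, fsn, synonyms, (p, a, g) in _PAPER_CONCEPTS:
        builder.concept(cid)
        builder.description(cid, fsn)
        for syn in synonyms:
            builder.description(cid, syn, type_id=SYNONYM_TYPE_ID)
        builder.add_profile(cid, _PAPER_ANCHORS[:p], a, g, _PAPER_VALUES)
    return builder.write(out_dir)
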