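"""RF2 Snapshot terminology access.

SNOMED CT releases ship as tab-separated "Release Format 2" tables. The
Snapshot view holds the current state of every component: one row per
concept, description (name/synonym), and relationship, each carrying an
``active`` flag. This module loads those three tables into an indexed
in-memory graph and resolves human-readable concept names.

Only the columns named below are required; any extra RF2 columns
(moduleId, caseSignificanceId, ...) are preserved on write but otherwise
ignored. Identifiers are kept as verbatim strings — SNOMED CT ids exceed
what a 32-bit integer holds and must never be reformatted.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

#: Relationship type id of the subsumption (parent-child) edge.
IS_A_TYPE_ID = "116680003"

#: Description type ids distinguishing the Fully Specified Name from synonyms.
FSN_TYPE_ID = "900000000000003001"
SYNONYM_TYPE_ID = "900000000000013009"

FULLY_SPECIFIED_NAME = "fully_specified_name"
SYNONYM = "synonym"

# Semantic tags SNOMED appends to Fully Specified Names, e.g.
# "Lupus erythematosus (disorder)". Lower-case, compared case-insensitively.
SEMANTIC_TAGS = frozenset(
    {
        "disorder",
        "disease",
        "finding",
        "body structure",
        "morphologic abnormality",
        "attribute",
        "qualifier value",
        "procedure",
        "regime/therapy",
        "situation",
        "event",
        "observable entity",
        "organism",
        "substance",
        "product",
        "medicinal product",
        "physical object",
        "physical force",
        "person",
        "occupation",
        "environment",
        "geographic location",
        "social concept",
        "religion/philosophy",
        "ethnic group",
        "racial group",
        "life style",
        "link assertion",
        "linkage concept",
        "navigational concept",
        "namespace concept",
        "core metadata concept",
        "foundation metadata concept",
        "record artifact",
        "specimen",
        "staging scale",
        "assessment scale",
        "tumor staging",
        "cell",
        "cell structure",
        "environment / location",
    }
)

_TAG_RE = re.compile(r"^(?P<stem>.*\S)\s*\((?P<tag>[^()]+)\)\s*$")


class RF2FormatError(ValueError):
    """A release file is malformed (e.g. a required column is missing)."""


@dataclass(frozen=True)
class ConceptRecord:
    concept_id: str
    active: bool
    effective_time: str = ""


@dataclass(frozen=True)
class DescriptionRecord:
    description_id: str
    concept_id: str
    term: str
    description_type: str  # FULLY_SPECIFIED_NAME or SYNONYM
    active: bool
    effective_time: str = ""


@dataclass(frozen=True)
class RelationshipRecord:
    relationship_id: str
    source_id: str
    destination_id: str
    type_id: str
    relationship_group: int
    active: bool
    effective_time: str = ""


@dataclass
class TerminologyGraph:
    """Indexed view of one Snapshot load; indices hold active rows only."""

    concepts: dict[str, ConceptRecord] = field(default_factory=dict)
    names: dict[str, list[DescriptionRecord]] = field(default_factory=dict)
    outgoing: dict[str, list[RelationshipRecord]] = field(default_factory=dict)
    incoming: dict[str, list[RelationshipRecord]] = field(default_factory=dict)

    @property
    def incoming_isa(self) -> dict[str, list[RelationshipRecord]]:
        """Incoming subsumption edges only: destination id -> Is-A rows."""
        return {
            cid: [r for r in rels if r.type_id == IS_A_TYPE_ID]
            for cid, rels in self.incoming.items()
            if any(r.type_id == IS_A_TYPE_ID for r in rels)
        }

    def descriptions(self, concept_id: str) -> list[DescriptionRecord]:
        return self.names.get(concept_id, [])

    def fsn(self, concept_id: str) -> DescriptionRecord | None:
        for d in self.descriptions(concept_id):
            if d.description_type == FULLY_SPECIFIED_NAME:
                return d
        return None

    def semantic_tag(self, concept_id: str) -> str | None:
        """Lower-cased semantic tag of the concept's FSN, if recognised."""
        fsn = self.fsn(concept_id)
        if fsn is None:
            return None
        m = _TAG_RE.match(fsn.term)
        if m and m.group("tag").strip().lower() in SEMANTIC_TAGS:
            return m.group("tag").strip().lower()
        return None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TerminologyGraph):
            return NotImplemented
        return (
            self.concepts == other.concepts
            and {k: sorted(v, key=lambda d: d.description_id) for k, v in self.names.items()}
            == {k: sorted(v, key=lambda d: d.description_id) for k, v in other.names.items()}
            and {k: sorted(v, key=lambda r: r.relationship_id) for k, v in self.outgoing.items()}
            == {k: sorted(v, key=lambda r: r.relationship_id) for k, v in other.outgoing.items()}
        )


def clean_name(raw_term: str) -> str:
    """Strip a trailing parenthesised semantic tag from a concept name.

    FSNs carry tags such as "(disorder)" or "(body structure)" that add no
    information to narrative text. Interior parentheticals and trailing
    parentheticals that are not semantic tags are preserved.
    """
    term = raw_term.strip()
    while True:  # repeated stripping makes the cleaner a fixpoint
        m = _TAG_RE.match(term)
        if m and m.group("tag").strip().lower() in SEMANTIC_TAGS:
            term = m.group("stem").strip()
        else:
            return term


def _read_table(path: Path | str, required: dict[str, str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"RF2 file not found: {path}")
    df = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        quoting=csv.QUOTE_NONE,
        keep_default_na=False,
        encoding="utf-8",
    )
    for col in required:
        if col not in df.columns:
            raise RF2FormatError(f"{path.name}: missing required column '{col}'")
    return df


def load_rf2_snapshot(
    concept_path: Path | str,
    description_path: Path | str,
    relationship_path: Path | str,
) -> TerminologyGraph:
    """Load the three Snapshot tables into a :class:`TerminologyGraph`.

    Inactive rows are filtered out. Descriptions and relationships that
    reference a concept absent from the load (partial extracts) are dropped
    with a warning rather than aborting the load.
    """
    graph = TerminologyGraph()

    cdf = _read_table(Path(concept_path), {"id": "", "active": ""})
    n_active = 0
    for row in cdf.itertuples(index=False):
        rec = ConceptRecord(
            concept_id=row.id,
            active=row.active == "1",
            effective_time=getattr(row, "effectiveTime", ""),
        )
        if rec.active:
            graph.concepts[rec.concept_id] = rec
            n_active += 1
    logger.info("concepts: %d rows, %d active", len(cdf), n_active)

    ddf = _read_table(
        Path(description_path), {"id": "", "conceptId": "", "term": "", "typeId": "", "active": ""}
    )
    n_active = n_orphan = 0
    for row in ddf.itertuples(index=False):
        if row.active != "1":
            continue
        if row.conceptId not in graph.concepts:
            logger.warning("dropping description %s: unknown concept %s", row.id, row.conceptId)
            n_orphan += 1
            continue
        term = row.term.strip()
        if not term:
            raise RF2FormatError(f"description {row.id}: empty term")
        rec = DescriptionRecord(
            description_id=row.id,
            concept_id=row.conceptId,
            term=term,
            description_type=FULLY_SPECIFIED_NAME if row.typeId == FSN_TYPE_ID else SYNONYM,
            active=True,
            effective_time=getattr(row, "effectiveTime", ""),
        )
        graph.names.setdefault(rec.concept_id, []).append(rec)
        n_active += 1
    logger.info("descriptions: %d rows, %d active, %d orphaned", len(ddf), n_active, n_orphan)

    rdf = _read_table(
        Path(relationship_path),
        {"id": "", "sourceId": "", "destinationId": "", "typeId": "", "active": ""},
    )
    n_active = n_orphan = 0
    for row in rdf.itertuples(index=False):
        if row.active != "1":
            continue
        if row.sourceId not in graph.concepts or row.destinationId not in graph.concepts:
            logger.warning("dropping relationship %s: unknown endpoint", row.id)
            n_orphan += 1
            continue
        if row.typeId == IS_A_TYPE_ID and row.sourceId == row.destinationId:
            raise RF2FormatError(f"relationship {row.id}: Is-A self-loop on {row.sourceId}")
        rec = RelationshipRecord(
            relationship_id=row.id,
            source_id=row.sourceId,
            destination_id=row.destinationId,
            type_id=row.typeId,
            relationship_group=int(getattr(row, "relationshipGroup", "0") or 0),
            active=True,
            effective_time=getattr(row, "effectiveTime", ""),
        )
        graph.outgoing.setdefault(rec.source_id, []).append(rec)
        graph.incoming.setdefault(rec.destination_id, []).append(rec)
        n_active += 1
    logger.info("relationships: %d rows, %d active, %d orphaned", len(rdf), n_active, n_orphan)
    return graph


def load_rf2_dir(rf2_dir: Path | str) -> TerminologyGraph:
    """Locate the three Snapshot TSVs in a directory by filename prefix."""
    rf2_dir = Path(rf2_dir)

    def _find(prefix: str) -> Path:
        hits = sorted(rf2_dir.glob(f"{prefix}*.txt"))
        if not hits:
            raise FileNotFoundError(f"no {prefix}*.txt under {rf2_dir}")
        return hits[0]

    return load_rf2_snapshot(
        _find("sct2_Concept_Snapshot"),
        _find("sct2_Description_Snapshot"),
        _find("sct2_Relationship_Snapshot"),
    )


def display_name(graph: TerminologyGraph, concept_id: str) -> str:
    """One human-readable name for a concept.

    Policy: the shortest active non-FSN synonym (after tag stripping),
    ties broken alphabetically; the cleaned FSN only when the concept has
    no synonym at all.
    """
    if concept_id not in graph.concepts:
        raise KeyError(f"unknown concept id: {concept_id}")
    synonyms = [
        clean_name(d.term)
        for d in graph.descriptions(concept_id)
        if d.description_type == SYNONYM
    ]
    if synonyms:
        return min(synonyms, key=lambda s: (len(s), s.lower()))
    fsn = graph.fsn(concept_id)
    if fsn is not None:
        return clean_name(fsn.term)
    raise KeyError(f"concept {concept_id} has no active description")


def preferred_name(graph: TerminologyGraph, concept_id: str) -> str:
    """The concept's formal name: the FSN with its semantic tag removed."""
    if concept_id not in graph.concepts:
        raise KeyError(f"unknown concept id: {concept_id}")
    fsn = graph.fsn(concept_id)
    if fsn is not None:
        return clean_name(fsn.term)
    return display_name(graph, concept_id)


# --- writing ----------------------------------------------------------------

CONCEPT_HEADER = ["id", "effectiveTime", "active", "moduleId", "definitionStatusId"]
DESCRIPTION_HEADER = [
    "id",
    "effectiveTime",
    "active",
    "moduleId",
    "conceptId",
    "languageCode",
    "typeId",
    "term",
    "caseSignificanceId",
]
RELATIONSHIP_HEADER = [
    "id",
    "effectiveTime",
    "active",
    "moduleId",
    "sourceId",
    "destinationId",
    "relationshipGroup",
    "typeId",
    "characteristicTypeId",
    "modifierId",
]

_MODULE_ID = "900000000000207008"
_DEFINITION_STATUS = "900000000000074008"
_CASE_SIG = "900000000000448009"
_CHARACTERISTIC = "900000000000011006"
_MODIFIER = "900000000000451002"


def write_tsv(path: Path, header: list[str], rows: Iterable[list[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_rf2_snapshot(graph: TerminologyGraph, out_dir: Path | str, tag: str = "Export") -> Path:
    """Serialise a graph back to the three Snapshot TSVs (active rows only)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    concept_rows = [
        [c.concept_id, c.effective_time, "1", _MODULE_ID, _DEFINITION_STATUS]
        for c in sorted(graph.concepts.values(), key=lambda c: c.concept_id)
    ]
    desc_rows = [
        [
            d.description_id,
            d.effective_time,
            "1",
            _MODULE_ID,
            d.concept_id,
            "en",
            FSN_TYPE_ID if d.description_type == FULLY_SPECIFIED_NAME else SYNONYM_TYPE_ID,
            d.term,
            _CASE_SIG,
        ]
        for ds in graph.names.values()
        for d in ds
    ]
    desc_rows.sort(key=lambda r: r[0])
    rel_rows = [
        [
            r.relationship_id,
            r.effective_time,
            "1",
            _MODULE_ID,
            r.source_id,
            r.destination_id,
            str(r.relationship_group),
            r.type_id,
            _CHARACTERISTIC,
            _MODIFIER,
        ]
        for rels in graph.outgoing.values()
        for r in rels
    ]
    rel_rows.sort(key=lambda r: r[0])
    write_tsv(out_dir / f"sct2_Concept_Snapshot_{tag}.txt", CONCEPT_HEADER, concept_rows)
    write_tsv(out_dir / f"sct2_Description_Snapshot-en_{tag}.txt", DESCRIPTION_HEADER, desc_rows)
    write_tsv(out_dir / f"sct2_Relationship_Snapshot_{tag}.txt", RELATIONSHIP_HEADER, rel_rows)
    return out_dir
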