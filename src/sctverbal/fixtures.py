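"""Miniature RF2 terminologies for development, testing and demos.

Two generators are provided. :func:`build_lupus_fixture` writes the
small Lupus erythematosus subgraph used as the package's worked
example: one disease concept with its synonyms, four outgoing
attribute relationships, three subtypes and one incoming "due to"
edge. :func:`build_synthetic_fixture` writes seeded pseudo-disease
terminologies of configurable shape so every relationship type the
lexicon knows can be exercised without a real SNOMED CT release.

Synthetic concept identifiers live in a reserved ``88``-prefixed
numeric range; relationship type ids reuse the real SNOMED CT
attribute concept ids from the default lexicon, so fixtures run
through the production code path unchanged.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .lexicon import CHILDREN_KEY, OTHER_KEY, Lexicon, load_lexicon
from .terminology import (
    CONCEPT_HEADER,
    DESCRIPTION_HEADER,
    FSN_TYPE_ID,
    IS_A_TYPE_ID,
    RELATIONSHIP_HEADER,
    SYNONYM_TYPE_ID,
    write_tsv,
)

_EFFECTIVE_TIME = "20180301"
_MODULE_ID = "900000000000207008"
_DEFINITION_STATUS = "900000000000074008"
_CASE_SIG = "900000000000448009"
_CHARACTERISTIC = "900000000000011006"
_MODIFIER = "900000000000451002"

#: relationship type id deliberately absent from the lexicon ("other" routing)
UNMAPPED_TYPE_ID = "880000000999"

FINDING_SITE_TYPE_ID = "363698007"
PATHOLOGICAL_PROCESS_TYPE_ID = "370135005"
DUE_TO_TYPE_ID = "42752001"

MANIFEST_NAME = "diseases_manifest.tsv"

_SEMANTIC_TAG_BY_KEY = {
    "is_a": "disorder",
    "finding_site": "body structure",
    "has_definitional_manifestation": "finding",
    "associated_morphology": "morphologic abnormality",
    "pathological_process": "qualifier value",
    "causative_agent": "organism",
    "due_to": "disorder",
    "associated_with": "disorder",
    "occurrence": "qualifier value",
    "during_following_after": "qualifier value",
    "temporally_related": "qualifier value",
    "finding_method": "procedure",
    "finding_informer": "finding",
    "clinical_course": "qualifier value",
    "severity": "qualifier value",
    "episodicity": "qualifier value",
    "interprets": "observable entity",
    "has_interpretation": "qualifier value",
    OTHER_KEY: "finding",
}


class _Writer:
    """Accumulates RF2 rows and hands out sequential synthetic ids."""

    def __init__(self) -> None:
        self.concept_rows: list[list[str]] = []
        self.desc_rows: list[list[str]] = []
        self.rel_rows: list[list[str]] = []
        self._next = {"concept": 0, "desc": 0, "rel": 0}

    def next_id(self, kind: str, prefix: str) -> str:
        self._next[kind] += 1
        return f"{prefix}{self._next[kind]:08d}"

    def concept(self, concept_id: str, active: bool = True) -> str:
        self.concept_rows.append(
            [concept_id, _EFFECTIVE_TIME, "1" if active else "0", _MODULE_ID, _DEFINITION_STATUS]
        )
        return concept_id

    def description(self, concept_id: str, term: str, fsn: bool = False) -> None:
        self.desc_rows.append(
            [
                self.next_id("desc", "8810"),
                _EFFECTIVE_TIME,
                "1",
                _MODULE_ID,
                concept_id,
                "en",
                FSN_TYPE_ID if fsn else SYNONYM_TYPE_ID,
                term,
                _CASE_SIG,
            ]
        )

    def relationship(self, source: str, destination: str, type_id: str) -> None:
        self.rel_rows.append(
            [
                self.next_id("rel", "8820"),
                _EFFECTIVE_TIME,
                "1",
                _MODULE_ID,
                source,
                destination,
                "0",
                type_id,
                _CHARACTERISTIC,
                _MODIFIER,
            ]
        )

    def write(self, out_dir: Path, tag: str) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_tsv(out_dir / f"sct2_Concept_Snapshot_{tag}.txt", CONCEPT_HEADER, self.concept_rows)
        write_tsv(
            out_dir / f"sct2_Description_Snapshot-en_{tag}.txt", DESCRIPTION_HEADER, self.desc_rows
        )
        write_tsv(
            out_dir / f"sct2_Relationship_Snapshot_{tag}.txt", RELATIONSHIP_HEADER, self.rel_rows
        )
        return out_dir


def build_lupus_fixture(out_dir: Path | str) -> Path:
    """Write the Lupus erythematosus worked-example subgraph.

    Content: concept 200936003 with its four terms; outgoing Is-a edges
    to Disorder of connective tissue and Autoimmune disease, a Finding
    site edge to Connective tissue structure and a Pathological process
    edge to the Autoimmune qualifier; incoming Is-a edges from the
    Systemic, Drug-induced and Neonatal subtypes; and an incoming
    "Due to" edge from Discoid lupus erythematosus. Fully deterministic.
    """
    w = _Writer()
    lupus = w.concept("200936003")
    w.description(lupus, "Lupus erythematosus (disorder)", fsn=True)
    w.description(lupus, "Lupus erythematosus")
    w.description(lupus, "LE - Lupus erythematosus")
    w.description(lupus, "Lupus")

    ct_disorder = w.concept("105969002")
    w.description(ct_disorder, "Disorder of connective tissue (disorder)", fsn=True)
    w.description(ct_disorder, "Disorder of connective tissue")
    w.description(ct_disorder, "Connective tissue disease")

    autoimmune_disease = w.concept("85828009")
    w.description(autoimmune_disease, "Autoimmune disease (disorder)", fsn=True)
    w.description(autoimmune_disease, "Autoimmune disease")

    ct_structure = w.concept("21793004")
    w.description(ct_structure, "Connective tissue structure (body structure)", fsn=True)
    w.description(ct_structure, "Connective tissue structure")
    w.description(ct_structure, "Connective tissue")

    autoimmune_q = w.concept("263680009")
    w.description(autoimmune_q, "Autoimmune (qualifier value)", fsn=True)
    w.description(autoimmune_q, "AI - autoimmune")

    systemic = w.concept("55464009")
    w.description(systemic, "Systemic lupus erythematosus (disorder)", fsn=True)
    w.description(systemic, "Systemic lupus erythematosus")

    drug_induced = w.concept("80258006")
    w.description(drug_induced, "Drug-induced lupus erythematosus (disorder)", fsn=True)
    w.description(drug_induced, "Drug-induced lupus erythematosus")

    neonatal = w.concept("95408003")
    w.description(neonatal, "Neonatal lupus erythematosus (disorder)", fsn=True)
    w.description(neonatal, "Neonatal lupus erythematosus")

    discoid = w.concept("200938002")
    w.description(discoid, "Discoid lupus erythematosus (disorder)", fsn=True)
    w.description(discoid, "Discoid lupus erythematosus")

    w.relationship(lupus, ct_disorder, IS_A_TYPE_ID)
    w.relationship(lupus, autoimmune_disease, IS_A_TYPE_ID)
    w.relationship(lupus, ct_structure, FINDING_SITE_TYPE_ID)
    w.relationship(lupus, autoimmune_q, PATHOLOGICAL_PROCESS_TYPE_ID)
    w.relationship(systemic, lupus, IS_A_TYPE_ID)
    w.relationship(drug_induced, lupus, IS_A_TYPE_ID)
    w.relationship(neonatal, lupus, IS_A_TYPE_ID)
    w.relationship(discoid, lupus, DUE_TO_TYPE_ID)
    return w.write(Path(out_dir), "LupusFixture")


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of one synthetic terminology; the seed fixes every byte."""

    n_diseases: int
    children_per_disease: tuple[int, int] = (1, 3)
    relationship_types: tuple[str, ...] = ()
    synonyms_per_concept: tuple[int, int] = (1, 3)
    seed: int = 0

    def validate(self, lexicon: Lexicon) -> None:
        if self.n_diseases < 0:
            raise ValueError("n_diseases must be >= 0")
        if not self.relationship_types:
            raise ValueError("relationship_types must be non-empty")
        for lo, hi in (self.children_per_disease, self.synonyms_per_concept):
            if lo > hi or lo < 0:
                raise ValueError("ranges must be non-empty and non-negative")
        unknown = set(self.relationship_types) - set(lexicon.by_key)
        if unknown:
            raise ValueError(f"unknown relationship types: {sorted(unknown)}")


def default_fixture_spec(n_diseases: int = 10, seed: int = 0) -> FixtureSpec:
    """Full-coverage spec: every lexicon relationship type on every disease."""
    lexicon = load_lexicon()
    return FixtureSpec(
        n_diseases=n_diseases,
        relationship_types=tuple(e.key for e in lexicon),
        seed=seed,
    )


_CONSONANTS = "bdfglmnprstvz"
_VOWELS = "aeiou"
_SUFFIXES = ("osis", "itis", "emia", "opathy", "oma")
_RESERVED = {
    "some",
    "other",
    "clinical",
    "pathological",
    "example",
    "examples",
    "severity",
    "episodicity",
    "related",
    "concepts",
}


class _NameForge:
    """Unique pronounceable pseudo-names with substring-collision control.

    No registered name may contain or be contained in another (the only
    exception being a subtype name extending its own disease's name),
    so counting name occurrences in generated text is unambiguous.
    """

    def __init__(self, rng: random.Random) -> None:
        self.rng = rng
        self.names: list[str] = []

    def _word(self, n_syllables: int) -> str:
        return "".join(
            self.rng.choice(_CONSONANTS) + self.rng.choice(_VOWELS) for _ in range(n_syllables)
        )

    def _ok(self, candidate: str, allow_super_of: str | None) -> bool:
        low = candidate.lower()
        if low in _RESERVED:
            return False
        for existing in self.names:
            e = existing.lower()
            if e == allow_super_of:
                continue
            if low in e or e in low:
                return False
        return True

    def _register(self, make, allow_super_of: str | None = None) -> str:
        allow = allow_super_of.lower() if allow_super_of else None
        for _ in range(1000):
            candidate = make()
            if self._ok(candidate, allow):
                self.names.append(candidate)
                return candidate
        raise RuntimeError("could not forge a collision-free name")

    def disease(self) -> str:
        return self._register(
            lambda: (self._word(3) + self.rng.choice(_SUFFIXES)).capitalize()
        )

    def subtype(self, disease_name: str) -> str:
        return self._register(
            lambda: f"{self._word(2).capitalize()} {disease_name}",
            allow_super_of=disease_name,
        )

    def target(self) -> str:
        return self._register(lambda: self._word(3).capitalize())


def build_synthetic_fixture(spec: FixtureSpec, out_dir: Path | str) -> Path:
    """Write a seeded pseudo-disease terminology matching ``spec``.

    Every requested relationship type appears on every generated
    disease, so a full-coverage spec exercises each lexical pattern.
    A manifest TSV listing the top-level disease concept ids and names
    is written alongside the three RF2 tables.
    """
    lexicon = load_lexicon()
    spec.validate(lexicon)
    rng = random.Random(spec.seed)
    forge = _NameForge(rng)
    w = _Writer()

    def new_concept(name: str, tag: str) -> str:
        cid = w.concept(w.next_id("concept", "8800"))
        w.description(cid, f"{name} ({tag})", fsn=True)
        w.description(cid, name)
        return cid

    requested = [e.key for e in lexicon if e.key in set(spec.relationship_types)]
    manifest: list[tuple[str, str]] = []
    for _ in range(spec.n_diseases):
        name = forge.disease()
        disease = new_concept(name, "disorder")
        n_syn = rng.randint(*spec.synonyms_per_concept)
        for j in range(1, n_syn):
            w.description(disease, f"{name} type {j + 1}")
        manifest.append((disease, name))

        for key in requested:
            if key == CHILDREN_KEY:
                for _ in range(rng.randint(*spec.children_per_disease)):
                    child = new_concept(forge.subtype(name), "disorder")
                    w.relationship(child, disease, IS_A_TYPE_ID)
            elif key == "is_a":
                for _ in range(rng.randint(1, 2)):
                    parent = new_concept(forge.target(), _SEMANTIC_TAG_BY_KEY[key])
                    w.relationship(disease, parent, IS_A_TYPE_ID)
            elif key == OTHER_KEY:
                target = new_concept(forge.target(), _SEMANTIC_TAG_BY_KEY[key])
                w.relationship(disease, target, UNMAPPED_TYPE_ID)
            else:
                entry = lexicon.by_key[key]
                for _ in range(rng.randint(1, 2)):
                    target = new_concept(forge.target(), _SEMANTIC_TAG_BY_KEY[key])
                    w.relationship(disease, target, rng.choice(entry.type_ids))

    out = w.write(Path(out_dir), "SyntheticFixture")
    write_tsv(out / MANIFEST_NAME, ["conceptId", "name"], [list(m) for m in manifest])
    return out


def read_manifest(fixture_dir: Path | str) -> list[tuple[str, str]]:
    """Disease (concept id, name) pairs recorded by the synthetic generator."""
    lines = (Path(fixture_dir) / MANIFEST_NAME).read_text("utf-8").splitlines()
    return [tuple(line.split("\t")) for line in lines[1:]]
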