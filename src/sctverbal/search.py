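"""Concept search and random disease sampling.

Search is a case-insensitive exact match of the query against every
active description term (tag-stripped), as the original engine's local
lookup works; there is no fuzzy fallback. A hook for an external
terminology-analyzer service exists as an interface point only.
"""

from __future__ import annotations

import logging
import random
import re
from dataclasses import dataclass

from .terminology import SYNONYM, TerminologyGraph, clean_name, preferred_name

logger = logging.getLogger(__name__)

PREFERRED = "preferred"
SYNONYM_MATCH = "synonym"
NOT_FOUND = "not_found"

_WS = re.compile(r"\s+")


def _norm(term: str) -> str:
    return _WS.sub(" ", term.strip().lower())


@dataclass(frozen=True)
class SearchResult:
    concept_id: str | None
    matched_term: str
    match_kind: str  # PREFERRED, SYNONYM_MATCH or NOT_FOUND

    @property
    def found(self) -> bool:
        return self.match_kind != NOT_FOUND


def find_concept(graph: TerminologyGraph, term: str) -> SearchResult:
    """Resolve a user-entered term to a concept.

    Matches are exact after lower-casing, whitespace normalization and
    semantic-tag stripping. A hit on a concept's preferred name (its
    cleaned FSN) reports ``preferred``; any other description reports
    ``synonym``. Ambiguous terms prefer a preferred-name hit, then the
    lowest concept id, and log the ambiguity.
    """
    if not term.strip():
        raise ValueError("search term must be non-empty")
    query = _norm(clean_name(term))  # queries get the same tag-stripping as stored terms
    hits: list[tuple[str, str, bool]] = []  # (concept_id, stored term, is_preferred)
    for cid, descriptions in graph.names.items():
        pref = _norm(preferred_name(graph, cid))
        for d in descriptions:
            cleaned = clean_name(d.term)
            if _norm(cleaned) == query:
                hits.append((cid, cleaned, _norm(cleaned) == pref))
    if not hits:
        return SearchResult(None, term, NOT_FOUND)
    concept_ids = {cid for cid, _, _ in hits}
    if len(concept_ids) > 1:
        logger.warning("term %r is ambiguous across concepts %s", term, sorted(concept_ids))
    preferred_hits = sorted((h for h in hits if h[2]), key=lambda h: h[0])
    if preferred_hits:
        cid, matched, _ = preferred_hits[0]
        return SearchResult(cid, matched, PREFERRED)
    cid, matched, _ = sorted(hits, key=lambda h: h[0])[0]
    return SearchResult(cid, matched, SYNONYM_MATCH)


def nearest_terms(graph: TerminologyGraph, term: str, limit: int = 5) -> list[str]:
    """Stored terms containing the query as a substring, for not-found hints."""
    query = _norm(term)
    candidates = {
        clean_name(d.term)
        for descriptions in graph.names.values()
        for d in descriptions
        if query and query in _norm(clean_name(d.term))
    }
    return sorted(candidates, key=str.lower)[:limit]


def disease_concepts(graph: TerminologyGraph) -> list[str]:
    """Concept ids whose FSN carries the "(disorder)" semantic tag."""
    return sorted(cid for cid in graph.concepts if graph.semantic_tag(cid) == "disorder")


def sample_diseases(graph: TerminologyGraph, n: int, seed: int) -> list[str]:
    """Uniform sample of disease concepts without replacement, seeded."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = disease_concepts(graph)
    if n >= len(pool):
        if n > len(pool):
            logger.warning("requested %d diseases but only %d available", n, len(pool))
        return pool
    rng = random.Random(seed)
    return rng.sample(pool, n)


def analyzer_api_search(term: str):  # pragma: no cover - interface stub
    """Interface point for an external terminology-analyzer search service.

    Network lookup is intentionally unimplemented; local exact matching
    is the only supported search path.
    """
    raise NotImplementedError("external analyzer search is not implemented")
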