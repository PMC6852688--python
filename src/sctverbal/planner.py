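"""Document planning: retrieve a concept's relationship bundle and
aggregate it into an ordered message plan.

Planning follows three steps: group all target concepts sharing a
relationship type into one message; organise messages into rhetorical
groups (definition, causality, temporality, diagnosis, clinical
course, other); order messages within and across groups by the
lexicon's ranks. Incoming subsumption edges — the disease's subtypes —
become the "examples" of the description; other incoming relations and
unmapped relationship types are routed to the trailing
"other related concepts" bucket.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .lexicon import CHILDREN_KEY, OTHER_KEY, Lexicon, LexiconEntry
from .search import SearchResult
from .terminology import IS_A_TYPE_ID, TerminologyGraph, display_name, preferred_name

logger = logging.getLogger(__name__)

DEFAULT_MAX_OTHER_RELATED = 3

# With the default ordering the examples sentence follows the defining
# Is-A / finding-site sentence directly; the strict ordering leaves the
# children entry at its configured rank (after pathological process).
_CHILDREN_DEFAULT_RANK = 2.5


@dataclass
class DiseaseBundle:
    """Everything retrieved for one searched disease concept."""

    concept_id: str
    preferred_name: str
    searched_term: str
    #: relationship-type key -> target concept ids (outgoing rows)
    outgoing: dict[str, list[str]] = field(default_factory=dict)
    #: (source concept id, relationship-type key) for incoming rows
    children: list[tuple[str, str]] = field(default_factory=list)
    #: concept id -> display name, resolved at retrieval time
    names: dict[str, str] = field(default_factory=dict)


@dataclass
class MessagePlan:
    """Ordered, aggregated messages ready for surface realization."""

    disease_name: str
    messages: list[tuple[LexiconEntry, list[str]]] = field(default_factory=list)
    examples: list[str] = field(default_factory=list)
    other_related: list[str] = field(default_factory=list)
    strict_order: bool = False

    def effective_rank(self, entry: LexiconEntry) -> float:
        if entry.key == CHILDREN_KEY and not self.strict_order:
            return _CHILDREN_DEFAULT_RANK
        return float(entry.rank)


def retrieve_bundle(
    graph: TerminologyGraph, result: SearchResult, lexicon: Lexicon
) -> DiseaseBundle:
    """Collect the searched concept's outgoing and incoming relationships.

    Outgoing rows are keyed by relationship type through the lexicon
    (unmapped types key as "other"); incoming rows are kept as
    (source, type-key) pairs ordered by source concept id, so the
    bundle is invariant to the release file's row order.
    """
    if result.match_kind == "not_found" or result.concept_id is None:
        raise ValueError("cannot retrieve a bundle for an unresolved search")
    cid = result.concept_id
    if cid not in graph.concepts:
        raise KeyError(f"concept {cid} not in terminology graph")

    bundle = DiseaseBundle(
        concept_id=cid,
        preferred_name=preferred_name(graph, cid),
        searched_term=result.matched_term,
    )
    for rel in sorted(graph.outgoing.get(cid, []), key=lambda r: (r.type_id, r.destination_id)):
        key = lexicon.key_for_type(rel.type_id)
        targets = bundle.outgoing.setdefault(key, [])
        if rel.destination_id not in targets:
            targets.append(rel.destination_id)
            bundle.names[rel.destination_id] = display_name(graph, rel.destination_id)
    for rel in sorted(graph.incoming.get(cid, []), key=lambda r: (r.source_id, r.type_id)):
        if rel.source_id == cid:
            continue
        key = (
            CHILDREN_KEY
            if rel.type_id == IS_A_TYPE_ID
            else lexicon.key_for_type(rel.type_id)
        )
        bundle.children.append((rel.source_id, key))
        bundle.names[rel.source_id] = display_name(graph, rel.source_id)
    logger.info(
        "bundle for %s: %d outgoing types, %d incoming rows",
        cid,
        len(bundle.outgoing),
        len(bundle.children),
    )
    return bundle


def aggregate_messages(
    bundle: DiseaseBundle,
    lexicon: Lexicon,
    *,
    max_examples: int = 3,
    max_other_related: int = DEFAULT_MAX_OTHER_RELATED,
    strict_order: bool = False,
) -> MessagePlan:
    """Aggregate the bundle into one message per relationship type.

    Target lists are sorted alphabetically by display name (the
    documented tie-break). Subtypes pass through example selection; the
    overflow joins unmapped and non-subsumption incoming relations in
    ``other_related``, itself capped at ``max_other_related`` by the
    same largest-dissimilarity rule (dropped names are logged).
    """
    from .realize import split_examples  # local import: realizer builds on the plan type

    plan = MessagePlan(disease_name=bundle.preferred_name, strict_order=strict_order)
    other_pool: list[str] = []
    for entry in lexicon:
        if entry.key in (CHILDREN_KEY, OTHER_KEY):
            continue
        targets = bundle.outgoing.get(entry.key)
        if targets:
            names = sorted((bundle.names[t] for t in targets), key=str.lower)
            plan.messages.append((entry, names))
    other_pool.extend(bundle.names[t] for t in bundle.outgoing.get(OTHER_KEY, []))

    child_names = [bundle.names[c] for c, key in bundle.children if key == CHILDREN_KEY]
    plan.examples, leftover = split_examples(child_names, bundle.preferred_name, max_examples)
    other_pool.extend(leftover)
    other_pool.extend(bundle.names[c] for c, key in bundle.children if key != CHILDREN_KEY)

    seen: set[str] = set()
    others = [n for n in other_pool if not (n in seen or seen.add(n))]
    if len(others) > max_other_related:
        kept, dropped = split_examples(others, bundle.preferred_name, max_other_related)
        logger.info("other_related cap %d: dropping %s", max_other_related, dropped)
        others = kept
    plan.other_related = others
    return plan
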