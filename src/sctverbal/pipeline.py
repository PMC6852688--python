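"""End-to-end generation: search -> retrieve -> plan -> realize -> evaluate.

Also builds the "structured content" comparison arm: the concept's raw
terminology rows concatenated into one labelled block (ConceptID,
Terms, Relationships, Related concepts), the format a terminology
browser would show.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .config import RunConfig
from .lexicon import Lexicon, load_lexicon
from .metrics import compute_metrics
from .planner import aggregate_messages, retrieve_bundle
from .realize import GeneratedDescription, make_title, realize_description
from .search import SearchResult, find_concept, sample_diseases
from .terminology import SYNONYM, TerminologyGraph, load_rf2_dir, preferred_name

logger = logging.getLogger(__name__)


@dataclass
class Engine:
    """A loaded terminology plus configuration, ready to generate."""

    graph: TerminologyGraph
    lexicon: Lexicon
    config: RunConfig

    @classmethod
    def from_config(cls, config: RunConfig) -> "Engine":
        if config.rf2_dir is None:
            raise ValueError("config.rf2_dir is required")
        graph = load_rf2_dir(config.rf2_dir)
        lexicon = load_lexicon(config.lexicon_path)
        return cls(graph=graph, lexicon=lexicon, config=config)

    def generate(self, term: str) -> GeneratedDescription:
        """Generate a description for a user-entered disease term."""
        result = find_concept(self.graph, term)
        if not result.found:
            raise KeyError(f"term not found: {term!r}")
        return self.generate_for_result(result)

    def generate_for_concept(self, concept_id: str) -> GeneratedDescription:
        """Generate for a known concept id (batch mode: term = preferred name)."""
        name = preferred_name(self.graph, concept_id)
        return self.generate_for_result(SearchResult(concept_id, name, "preferred"))

    def generate_for_result(self, result: SearchResult) -> GeneratedDescription:
        bundle = retrieve_bundle(self.graph, result, self.lexicon)
        plan = aggregate_messages(
            bundle,
            self.lexicon,
            max_examples=self.config.max_examples,
            max_other_related=self.config.max_other_related,
            strict_order=self.config.strict_table1_order,
        )
        title = make_title(bundle.preferred_name, result.matched_term, self.config.jw_threshold)
        logger.info(
            "plan for %s: %d messages, %d examples, %d other",
            bundle.concept_id,
            len(plan.messages),
            len(plan.examples),
            len(plan.other_related),
        )
        return realize_description(title, plan, self.lexicon, use_article=self.config.use_article)

    def structured_content(self, concept_id: str) -> str:
        """The concept's terminology rows concatenated into one block."""
        graph = self.graph
        if concept_id not in graph.concepts:
            raise KeyError(f"unknown concept id: {concept_id}")
        # synonyms first (alphabetical), FSN last, as a terminology browser lists terms
        terms = [d.term for d in graph.descriptions(concept_id) if d.description_type == SYNONYM]
        terms.sort(key=str.lower)
        fsn = graph.fsn(concept_id)
        if fsn is not None:
            terms.append(fsn.term)

        def type_label(type_id: str) -> str:
            entry = self.lexicon.by_type_id.get(type_id)
            return entry.type_name if entry is not None else "Attribute"

        def fsn_term(cid: str) -> str:
            rec = graph.fsn(cid)
            return rec.term if rec is not None else preferred_name(graph, cid)

        parts = [f"ConceptID: {concept_id}.", "Terms: " + ", ".join(terms) + "."]
        rels = sorted(
            graph.outgoing.get(concept_id, []), key=lambda r: (r.type_id, r.destination_id)
        )
        if rels:
            parts.append(
                "Relationships: "
                + " ".join(
                    f"{fsn_term(r.destination_id)} = {type_label(r.type_id)} (attribute)."
                    for r in rels
                )
            )
        incoming = sorted(
            graph.incoming.get(concept_id, []), key=lambda r: (r.source_id, r.type_id)
        )
        if incoming:
            parts.append(
                "Related concepts: "
                + " ".join(
                    f"{fsn_term(r.source_id)} - {type_label(r.type_id)} (attribute)."
                    for r in incoming
                )
            )
        return " ".join(parts)

    def batch_report(self, n: int, seed: int | None = None) -> pd.DataFrame:
        """Sample ``n`` diseases and score generated vs structured texts.

        Returns one row per (disease, arm) plus a ``mean`` row per arm
        with the arithmetic means of the metric columns.
        """
        if not self.graph.concepts:
            raise ValueError("terminology is empty")
        seed = self.config.seed if seed is None else seed
        rows = []
        for cid in sample_diseases(self.graph, n, seed):
            generated = self.generate_for_concept(cid).full_text
            structured = self.structured_content(cid)
            for arm, text in (("generated", generated), ("structured", structured)):
                m = compute_metrics(text)
                rows.append(
                    {
                        "concept_id": cid,
                        "name": preferred_name(self.graph, cid),
                        "arm": arm,
                        "fk": m.fk_grade,
                        "ari": m.ari_grade,
                        "words": m.word_count,
                        "redundancy": m.redundancy,
                    }
                )
        df = pd.DataFrame(rows)
        means = (
            df.groupby("arm", as_index=False)[["fk", "ari", "words", "redundancy"]]
            .mean()
            .assign(concept_id="", name="mean")
        )
        return pd.concat([df, means], ignore_index=True)[
            ["concept_id", "name", "arm", "fk", "ari", "words", "redundancy"]
        ]
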