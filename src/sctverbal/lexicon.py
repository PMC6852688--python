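"""The verbalization lexicon: relationship types -> lexical patterns.

The lexicon is data, not code. Each entry maps one relationship type
(via its SNOMED CT attribute concept ids) to a rhetorical group, an
ordering rank, and a sentence template. The shipped default covers the
twenty relationship types the generator phrases; extending the engine
to a new attribute type means adding a YAML entry, not editing code.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

GROUPS = ("Definition", "Causality", "Temporality", "Diagnosis", "ClinicalCourse", "Other")

#: keys with no attribute-type ids: driven by graph structure, not rows
CHILDREN_KEY = "children"
OTHER_KEY = "other"


@dataclass(frozen=True)
class LexiconEntry:
    key: str
    group: str
    rank: int
    type_ids: tuple[str, ...]
    type_name: str
    pattern: str
    template: str
    template_singular: str | None = None


class Lexicon:
    """Ordered collection of entries with type-id and key lookup."""

    def __init__(self, entries: list[LexiconEntry]):
        ranks = [e.rank for e in entries]
        if len(set(ranks)) != len(ranks):
            raise ValueError("lexicon ranks must be unique")
        for e in entries:
            if e.group not in GROUPS:
                raise ValueError(f"unknown rhetorical group: {e.group}")
        self.entries: list[LexiconEntry] = sorted(entries, key=lambda e: e.rank)
        self.by_key: dict[str, LexiconEntry] = {e.key: e for e in self.entries}
        self.by_type_id: dict[str, LexiconEntry] = {}
        for e in self.entries:
            for tid in e.type_ids:
                if tid in self.by_type_id:
                    raise ValueError(f"type id {tid} mapped twice")
                self.by_type_id[tid] = e

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def key_for_type(self, type_id: str) -> str:
        """Relationship-type key for an attribute id; unmapped ids -> other."""
        entry = self.by_type_id.get(type_id)
        return entry.key if entry is not None else OTHER_KEY


def load_lexicon(path: Path | str | None = None) -> Lexicon:
    """Load a lexicon config; with no path, the shipped default."""
    if path is None:
        text = resources.files("sctverbal.data").joinpath("lexicon.yaml").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    raw = yaml.safe_load(text)
    entries = [
        LexiconEntry(
            key=item["key"],
            group=item["group"],
            rank=int(item["rank"]),
            type_ids=tuple(str(t) for t in item.get("type_ids", [])),
            type_name=item.get("type_name", item["key"]),
            pattern=item["pattern"],
            template=item["template"],
            template_singular=item.get("template_singular"),
        )
        for item in raw
    ]
    return Lexicon(entries)
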