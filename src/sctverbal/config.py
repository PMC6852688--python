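"""Run configuration shared by the CLI and the pipeline helpers."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .realize import DEFAULT_MAX_EXAMPLES, DEFAULT_TITLE_THRESHOLD


@dataclass
class RunConfig:
    rf2_dir: Path | None = None
    lexicon_path: Path | None = None
    #: Jaro-Winkler similarity below which the title appends "(also known as ...)"
    jw_threshold: float = DEFAULT_TITLE_THRESHOLD
    max_examples: int = DEFAULT_MAX_EXAMPLES
    max_other_related: int = 3
    #: emit the examples sentence at its configured lexicon rank instead of
    #: directly after the defining sentence
    strict_table1_order: bool = False
    #: prepend the article in "that affects the ..." sentences
    use_article: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.jw_threshold <= 1.0:
            raise ValueError("jw_threshold must lie in [0, 1]")
        if self.max_examples < 1:
            raise ValueError("max_examples must be >= 1")
        if self.max_other_related < 0:
            raise ValueError("max_other_related must be >= 0")

    @classmethod
    def from_yaml(cls, path: Path | str, **overrides) -> "RunConfig":
        """Load a flat key-value YAML config; explicit overrides win."""
        raw = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        if raw.get("rf2_dir"):
            raw["rf2_dir"] = Path(raw["rf2_dir"])
        if raw.get("lexicon_path"):
            raw["lexicon_path"] = Path(raw["lexicon_path"])
        return cls(**raw)
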