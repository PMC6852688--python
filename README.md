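# sctverbal

Narrative disease descriptions generated from SNOMED CT, with built-in
readability and redundancy evaluation.

Clinical terminologies define orders of magnitude more diseases — including
most rare ones — than any curated consumer-health resource describes, but
their content lives in structured concept/relationship tables that neither
patients nor most clinicians can read fluently. `sctverbal` is an ontology
verbalizer: it loads an RF2 Snapshot release (the tab-separated Concept,
Description and Relationship tables SNOMED CT ships), resolves a disease by
name or synonym, and renders its typed relationships as a short narrative
paragraph. The same toolkit scores any text with the two standard
school-grade readability formulas and a redundancy ratio, so generated
narratives can be compared against the raw structured content they replace.

## How it works

Generation is a four-stage template-based NLG pipeline:

1. **Search** — case-insensitive exact match of the query against all
   active, tag-stripped concept names and synonyms.
2. **Retrieve** — outgoing relationships of the concept plus incoming Is-A
   edges (the disease's subtypes).
3. **Plan** — one message per relationship type (targets aggregated),
   ordered by a configurable lexicon that maps each type to a rhetorical
   group and a lexical pattern, following the definition → causes →
   temporality → diagnosis → clinical course → other flow of reference
   texts.
4. **Realize** — coordinated lists ("A, B, and C"), a title that appends
   "(also known as <searched term>)" when the query differs significantly
   from the preferred name (Jaro-Winkler similarity below 0.90), fusion of
   the Is-A and finding-site facts into one defining sentence, and at most
   three subtype examples chosen by largest string dissimilarity.

Evaluation metrics:

    FK  = 0.39·(words/sentences) + 11.8·(syllables/words) − 15.59
    ARI = 4.71·(characters/words) + 0.5·(words/sentences) − 21.43
    redundancy = unique content words / total content words  (stopwords removed)

## Worked example

The repository can generate its own demo terminology — a small subgraph
around Lupus erythematosus — and verbalize it:

```bash
sctverbal fixtures --preset lupus --out demo_rf2
sctverbal --rf2-dir demo_rf2 generate --term Lupus
```

prints:

```
Lupus erythematosus (also known as Lupus) is a kind of Autoimmune disease and Connective tissue disease that affects Connective tissue. Some examples of Lupus erythematosus are Systemic lupus erythematosus, Drug-induced lupus erythematosus, and Neonatal lupus erythematosus. Pathological process associated with Lupus erythematosus is AI - autoimmune. Other related concepts include Discoid lupus erythematosus.
```

The first sentence fuses the two Is-A parents with the finding site; the
second names the three subtypes; the remaining sentences verbalize the
pathological-process attribute and the leftover related concepts. Scoring
this paragraph against the concept's raw structured content
(`ConceptID: 200936003. Terms: ... Relationships: ...`):

```python
from sctverbal import redundancy
redundancy(engine.generate("Lupus").full_text)       # 0.553
redundancy(engine.structured_content("200936003"))   # 0.475
```

the narrative repeats fewer content words than the structured block.
`sctverbal --rf2-dir DIR batch -n 20` extends the comparison to sampled
diseases (`--seed` makes runs reproducible), reporting FK, ARI, word count
and redundancy per text for both arms plus the per-arm means.

Library use mirrors the CLI:

```python
from sctverbal import Engine, RunConfig, build_lupus_fixture

engine = Engine.from_config(RunConfig(rf2_dir=build_lupus_fixture("demo_rf2")))
print(engine.generate("Lupus").full_text)
```

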