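# Methods

## The procedure

`sctverbal` verbalizes disease concepts from a SNOMED CT-style terminology in
four stages:

1. **Concept search and retrieval.** The user's term is matched, case- and
   whitespace-insensitively and after semantic-tag stripping, against every
   active description term in the loaded RF2 Snapshot. There is no fuzzy
   fallback: a hook for an external analyzer service exists as an interface
   point only. For the resolved concept the engine collects every outgoing
   relationship row and every incoming row; incoming Is-A sources are the
   disease's subtypes.
2. **Structuring and aggregation.** All targets sharing a relationship type
   are grouped into one message; messages are assigned to rhetorical groups
   (Definition, Causality, Temporality, Diagnosis, Clinical course, Other)
   and ordered by the lexicon's ranks, mirroring the flow of a disease
   entry in a medical reference text. This is a simplified, two-level
   application of rhetorical-structure-style document planning.
3. **Surface realization.** Target names are coordinated as "A and B" /
   "A, B, and C" (serial comma); each message's list is inserted into its
   lexical template; the Is-A and finding-site messages fuse into one
   defining sentence ("X is a kind of Y that affects Z"); subtype examples
   are capped and selected by string dissimilarity (below).
4. **Evaluation.** Generated narratives and the concatenated structured
   content are scored with Flesch-Kincaid grade, Automated Readability
   Index, word count and a stopword-filtered redundancy ratio.

## Name resolution

A concept's *preferred name* is its Fully Specified Name with the trailing
semantic tag ("(disorder)", "(body structure)", ...) removed. Relationship
*targets* are rendered with a different policy: the shortest active non-FSN
synonym, ties alphabetical, falling back to the cleaned FSN only when no
synonym exists. The short-synonym policy is a deliberate approximation —
terminologies do not record which surface form reads best in running text,
and the shortest synonym ("Connective tissue" rather than "Connective tissue
structure") is usually the most colloquial. Tag stripping is applied
repeatedly so the cleaner is idempotent even on names carrying stacked tags.

## Title construction

If the searched term differs significantly from the preferred name, the
title combines both: "Preferred (also known as Searched)". Significance is
judged by Jaro-Winkler similarity (prefix scale 0.1, prefix cap 4),
compared case-insensitively, with the *canonical stored term* rather than
the raw user input, so `lupus` and `Lupus` yield identical output. The
default threshold is **0.90**: similarity below it triggers the combined
form. The value was fixed from the two canonical positive pairs —
influenza/flu scores 0.778 and "Lupus erythematosus"/"Lupus" scores 0.8526,
so any threshold in (0.8526, 1.0) separates them from identical pairs; 0.90
sits comfortably inside that interval. It is configurable (`jw_threshold`).

## Example selection and caps

At most `max_examples` (default 3) subtypes are named. When the cap binds,
the subtypes with the largest dissimilarity `1 − JW(child, disease)` are
chosen — the most distinctive names carry the most information — with
alphabetical tie-breaks; below the cap the retrieval order (ascending
concept id, hence stable under file-row permutation) is preserved.
Unselected subtypes, incoming non-Is-A relations, and targets of
relationship types the lexicon does not know are pooled into a trailing
"Other related concepts" sentence, itself capped at `max_other_related`
(default 3) by the same dissimilarity rule. Capping deliberately trades
completeness for fluency; dropped names are logged at info level, and the
conservation guarantees in the test suite are therefore stated for bundles
within the caps.

## Ordering

The lexicon ships twenty entries with unique ranks. By default the examples
sentence is emitted directly after the defining Is-A/finding-site sentence
(effective rank 2.5), which reads better than holding all subtypes until
the end of the Definition group; `strict_table1_order: true` restores the
entry's configured rank. The defining sentence omits the article before the
finding site ("that affects Connective tissue") because site names are
typically mass nouns; `use_article: true` restores "that affects the ...".

## Metrics

- FK = 0.39·(words/sentences) + 11.8·(syllables/words) − 15.59
- ARI = 4.71·(characters/words) + 0.5·(words/sentences) − 21.43,
  characters counting letters and digits only.
- Redundancy = unique content words / total content words after removing a
  shipped ~130-word English stopword list (bundled so the ratio is
  reproducible across installs).

Sentences split at `. ! ?` followed by whitespace, with a guard list of
abbreviations ("e.g.", "i.e.", ...); words are maximal alphanumeric runs
with interior hyphens/apostrophes, so "drug-induced" is one word.
Syllables are estimated by counting contiguous vowel groups (y vocalic)
with a silent-final-e subtraction and a consonant-"le" guard. This is an
approximation of dictionary hyphenation: it is exact on short clinical
vocabulary ("flu" 1, "disease" 2, "erythematosus" 6) but can undercount
vowel-hiatus words ("autoimmune" scores 3, not 4). Grade scores are
therefore internally consistent and reproducible, but agreement with
hyphenation-based counters to the decimal is not promised.

## The synthetic generator

`build_synthetic_fixture` writes seeded miniature RF2 releases:
pseudo-worded diseases with a configurable number of subtypes, synonyms and
relationship types, plus one deliberately unmapped relationship type to
exercise the "other" routing. Names are pronounceable CV-syllable
pseudo-words with controlled shared-substring structure (subtype names
extend their disease's name), and the generator enforces that no two
registered names stand in a substring relation — so counting a name's
occurrences in output text is unambiguous and the dissimilarity ranking
over subtypes is non-trivial. Default conditions: 1–3 subtypes and 1–3
synonyms per concept, one or two targets per relationship type, all twenty
lexicon types present on every disease. The seed fixes every output byte.

What the generator does **not** emulate: SNOMED's scale and density (a real
disease concept averages far fewer attribute types), relationship role
groups (ignored by the planner as well), language/acceptability reference
sets, English morphology of real concept names, and inactive-row history.
Passing tests on synthetic fixtures therefore demonstrate the pipeline's
structural correctness — routing, ordering, conservation, determinism — not
the readability levels attainable on a real release, whose published-scale
grade averages additionally depend on the tokenizer of the scoring package
used and on the release content itself.

## Degenerate inputs and tie-breaks

- Empty message plan → a single fallback sentence "<title> is a clinical
  concept defined in the terminology."
- A plan without Is-A or finding-site messages is led by the same fallback
  sentence so the title always opens the text.
- Within a message, targets sort alphabetically (case-insensitive).
- Ambiguous search terms resolve to a preferred-name hit first, then the
  lowest concept id, and log a warning.
- Descriptions or relationships referencing concepts absent from the load
  are dropped with a warning, never fatal — partial extracts must load.

## Problem sizes

The shipped suites use a 9-concept worked-example fixture, a 3-disease
full-coverage fixture for pattern coverage, a 200-disease fixture for the
conservation/determinism suite, and 20 sampled diseases for the batch
comparison in `scripts/acceptance.py`; these sizes keep every property
check exhaustive over the generated content.

## Known limitations

- No recursive expansion of target concepts: each sentence names, but does
  not explain, its targets.
- Grade formulas presuppose natural English; on pseudo-worded synthetic
  fixtures their absolute values are not meaningful, only comparable
  between the two arms scored with identical tokenization.
- The external analyzer search and any web UI/API are out of scope.
- RF2 Full/Delta releases, OWL axiom refsets and description-logic
  classification are unsupported; the Snapshot view is the only dialect.
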