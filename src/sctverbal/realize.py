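"""Surface realization: turn an ordered message plan into narrative text.

The realizer owns every string-level decision: building an informative
title for the disease, coordinating target lists ("A, B, and C"),
selecting the most distinctive subtype examples by Jaro-Winkler
dissimilarity, filling the lexical templates, and fusing the
subsumption and finding-site facts into a single defining sentence
("X is a kind of Y that affects Z").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .lexicon import CHILDREN_KEY, OTHER_KEY, Lexicon, LexiconEntry
from .planner import MessagePlan

logger = logging.getLogger(__name__)

#: Similarity below which the searched term is considered "significantly
#: different" from the preferred concept name, triggering the
#: "(also known as ...)" title form.
DEFAULT_TITLE_THRESHOLD = 0.90

#: Maximum number of subtype examples named in one description.
DEFAULT_MAX_EXAMPLES = 3

FALLBACK_TEMPLATE = "{title} is a clinical concept defined in the terminology."


def jaro_winkler(a: str, b: str) -> float:
    """Jaro-Winkler similarity in [0, 1].

    Jaro similarity is the mean of the two match fractions and the
    transposition term; the Winkler variant boosts it by p * L * (1 - jaro)
    where L is the common-prefix length capped at 4 and p = 0.1.
    Symmetric in its arguments; two empty strings are identical (1.0).
    """
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    window = max(la, lb) // 2 - 1
    a_match = [False] * la
    b_match = [False] * lb
    m = 0
    for i, ch in enumerate(a):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        for j in range(lo, hi):
            if not b_match[j] and b[j] == ch:
                a_match[i] = b_match[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    # transpositions: matched characters out of order, counted pairwise
    b_matched = [b[j] for j in range(lb) if b_match[j]]
    t = sum(1 for ai, bi in zip((a[i] for i in range(la) if a_match[i]), b_matched) if ai != bi)
    t //= 2
    jaro = (m / la + m / lb + (m - t) / m) / 3.0
    prefix = 0
    for ca, cb in zip(a, b):
        if ca != cb or prefix == 4:
            break
        prefix += 1
    return jaro + prefix * 0.1 * (1.0 - jaro)


def make_title(
    preferred_name: str, searched_term: str, threshold: float = DEFAULT_TITLE_THRESHOLD
) -> str:
    """Title for the description's first sentence.

    When the searched term differs significantly from the concept's
    preferred name (Jaro-Winkler similarity below ``threshold``,
    compared case-insensitively), both are combined as
    "Preferred (also known as Searched)"; otherwise the preferred name
    stands alone.
    """
    if not preferred_name:
        raise ValueError("preferred_name must be non-empty")
    if not searched_term or searched_term.strip().lower() == preferred_name.strip().lower():
        return preferred_name
    sim = jaro_winkler(preferred_name.lower(), searched_term.lower())
    if sim < threshold:
        return f"{preferred_name} (also known as {searched_term})"
    return preferred_name


def concatenate_list(items: list[str]) -> str:
    """Coordinate a list: "A", "A and B", "A, B, and C" (serial comma)."""
    if not items:
        raise ValueError("cannot concatenate an empty list")
    if len(items) == 1:
        return items[0]
    if len(items) == 2:
        return f"{items[0]} and {items[1]}"
    return ", ".join(items[:-1]) + f", and {items[-1]}"


def split_examples(
    children: list[str], disease_name: str, k: int = DEFAULT_MAX_EXAMPLES
) -> tuple[list[str], list[str]]:
    """Partition subtype names into (selected examples, leftovers).

    At most ``k`` examples are kept, chosen by the largest string
    dissimilarity (1 - Jaro-Winkler) to the disease name so the most
    distinctive subtypes are shown; ties break alphabetically. When the
    cap is not exceeded the input order is preserved unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(children) <= k:
        return list(children), []
    scored = sorted(
        children,
        key=lambda c: (-(1.0 - jaro_winkler(c.lower(), disease_name.lower())), c.lower()),
    )
    selected = scored[:k]
    rest = [c for c in children if c not in selected]
    return selected, rest


def select_examples(
    children: list[str], disease_name: str, k: int = DEFAULT_MAX_EXAMPLES
) -> list[str]:
    """The examples half of :func:`split_examples`."""
    return split_examples(children, disease_name, k)[0]


@dataclass
class GeneratedDescription:
    title: str
    sentences: list[str] = field(default_factory=list)

    @property
    def full_text(self) -> str:
        return " ".join(self.sentences)


def _finish(sentence: str) -> str:
    sentence = sentence.strip()
    if not sentence.endswith("."):
        sentence += "."
    return sentence[0].upper() + sentence[1:]


def realize_description(
    title: str,
    plan: MessagePlan,
    lexicon: Lexicon,
    *,
    use_article: bool = False,
) -> GeneratedDescription:
    """Fill lexical templates with the plan's aggregated target lists.

    Sentences are emitted in the plan's rank order. The subsumption
    (Is-A) and finding-site messages, when both present, fuse into one
    defining sentence "<title> is a kind of <parents> that affects
    <sites>"; ``use_article`` restores the article before the site
    ("that affects the ..."). An empty plan yields a single fallback
    title sentence.
    """
    name = plan.disease_name
    items: list[tuple[float, LexiconEntry, list[str]]] = [
        (plan.effective_rank(entry), entry, targets) for entry, targets in plan.messages
    ]
    if plan.examples:
        entry = lexicon.by_key[CHILDREN_KEY]
        items.append((plan.effective_rank(entry), entry, list(plan.examples)))
    if plan.other_related:
        entry = lexicon.by_key[OTHER_KEY]
        items.append((plan.effective_rank(entry), entry, list(plan.other_related)))
    items.sort(key=lambda it: it[0])

    by_key = {entry.key: targets for _, entry, targets in items}
    the = " the" if use_article else ""

    sentences: list[str] = []
    fused_site = "is_a" in by_key and "finding_site" in by_key
    if not items:
        sentences.append(_finish(FALLBACK_TEMPLATE.format(title=title)))
    elif "is_a" not in by_key and "finding_site" not in by_key:
        # no defining fact: lead with the fallback so the title still opens the text
        sentences.append(_finish(FALLBACK_TEMPLATE.format(title=title)))

    for _, entry, targets in items:
        targets_text = concatenate_list(targets)
        if entry.key == "is_a":
            sentence = f"{title} is a kind of {targets_text}"
            if fused_site:
                site_text = concatenate_list(by_key["finding_site"])
                sentence += f" that affects{the} {site_text}"
            sentences.append(_finish(sentence))
        elif entry.key == "finding_site":
            if fused_site:
                continue  # consumed by the fused definition sentence
            sentences.append(_finish(f"{title} is a condition that affects{the} {targets_text}"))
        elif entry.key == CHILDREN_KEY:
            template = entry.template
            if len(targets) == 1 and entry.template_singular:
                template = entry.template_singular
            sentences.append(_finish(template.format(name=name, targets=targets_text)))
        else:
            sentences.append(
                _finish(entry.template.format(title=title, name=name, targets=targets_text))
            )
    logger.info("realized %d sentences for '%s'", len(sentences), name)
    return GeneratedDescription(title=title, sentences=sentences)
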