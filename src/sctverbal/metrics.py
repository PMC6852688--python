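"""Readability and redundancy metrics for generated and reference texts.

Two school-grade readability formulas are computed from surface counts:

    Flesch-Kincaid grade = 0.39*(words/sentences) + 11.8*(syllables/words) - 15.59
    Automated Readability Index = 4.71*(characters/words) + 0.5*(words/sentences) - 21.43

where characters counts letters and digits only. Redundancy is the
ratio of unique content words to total content words after stopword
removal — higher means less repetition.

Syllables are estimated by counting contiguous vowel groups (y
vocalic) with a silent-final-e subtraction and a consonant-"le" guard.
This is an approximation of dictionary hyphenation: grade scores are
reproducible within this package but not guaranteed to agree with
hyphenation-based counters to the decimal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

_WORD_RE = re.compile(r"[A-Za-z0-9]+(?:['’-][A-Za-z0-9]+)*")
_VOWEL_GROUPS = re.compile(r"[aeiouy]+")
_SENT_SPLIT = re.compile(r"(?<=[.!?])\s+")

# Periods inside these never end a sentence.
_ABBREVIATIONS = ("e.g.", "i.e.", "etc.", "vs.", "cf.", "Dr.", "St.", "No.")


def load_stopwords() -> frozenset[str]:
    text = resources.files("sctverbal.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


STOPWORDS = load_stopwords()


def tokenize(text: str) -> tuple[list[str], list[str]]:
    """Split text into sentences and lower-cased words.

    Sentences end at '.', '!' or '?' followed by whitespace, with known
    abbreviations protected. Words are maximal alphanumeric runs,
    allowing interior hyphens and apostrophes ("drug-induced" is one
    word).
    """
    if not text.strip():
        return [], []
    protected = text
    for i, abbr in enumerate(_ABBREVIATIONS):
        protected = protected.replace(abbr, f"\x00{i}\x00")
    sentences = []
    for chunk in _SENT_SPLIT.split(protected):
        chunk = chunk.strip()
        if not chunk:
            continue
        for i, abbr in enumerate(_ABBREVIATIONS):
            chunk = chunk.replace(f"\x00{i}\x00", abbr)
        sentences.append(chunk)
    words = [w.lower() for w in _WORD_RE.findall(text)]
    return sentences, words


def count_syllables(word: str) -> int:
    """Estimated syllable count, always at least 1."""
    w = re.sub(r"[^a-z]", "", word.lower())
    if not w:
        return 1
    groups = _VOWEL_GROUPS.findall(w)
    n = len(groups)
    if n == 0:
        return 1
    if (
        n > 1
        and w.endswith("e")
        and len(w) >= 2
        and w[-2] not in "aeiouy"
        and not (w.endswith("le") and len(w) >= 3 and w[-3] not in "aeiouy")
    ):
        n -= 1
    return max(n, 1)


def _counts(text: str) -> tuple[int, int, int, int]:
    sentences, words = tokenize(text)
    if not words or not sentences:
        raise ValueError("text must contain at least one word and one sentence")
    syllables = sum(count_syllables(w) for w in words)
    characters = sum(1 for w in words for ch in w if ch.isalnum())
    return len(sentences), len(words), syllables, characters


def fk_grade(text: str) -> float:
    """Flesch-Kincaid grade level (years of education)."""
    n_sent, n_words, n_syll, _ = _counts(text)
    return 0.39 * (n_words / n_sent) + 11.8 * (n_syll / n_words) - 15.59


def ari_grade(text: str) -> float:
    """Automated Readability Index (years of education)."""
    n_sent, n_words, _, n_chars = _counts(text)
    return 4.71 * (n_chars / n_words) + 0.5 * (n_words / n_sent) - 21.43


def redundancy(text: str, stopwords: frozenset[str] | None = None) -> float:
    """Unique content words / total content words, case-insensitive."""
    stopwords = STOPWORDS if stopwords is None else stopwords
    _, words = tokenize(text)
    content = [w for w in words if w not in stopwords]
    if not content:
        raise ValueError("text has no content words after stopword removal")
    return len(set(content)) / len(content)


@dataclass(frozen=True)
class TextMetrics:
    fk_grade: float
    ari_grade: float
    word_count: int
    redundancy: float


def compute_metrics(text: str, stopwords: frozenset[str] | None = None) -> TextMetrics:
    """All metrics for one text."""
    _, n_words, _, _ = _counts(text)
    return TextMetrics(
        fk_grade=fk_grade(text),
        ari_grade=ari_grade(text),
        word_count=n_words,
        redundancy=redundancy(text, stopwords),
    )
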