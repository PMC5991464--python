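"""Rule-based English noun pluralizer/singularizer.

Covers the regular inflection classes needed for medical vocabulary
("neuropathy" -> "neuropathies", "rash" -> "rashes") plus a handful of
guards: all-uppercase tokens (acronyms), very short tokens, Latin mass-noun
endings (-us, -is) and past-participle direction words (-ed) are left alone,
so dictionary expansion never invents forms like "ASTs" or "elevateds".
"""

from __future__ import annotations

_SIBILANT_STEMS = ("ch", "sh", "ss", "x", "z")
_VOWELS = "aeiou"


def _inflectable(word: str) -> bool:
    if len(word) < 3 or not word.isalpha():
        return False
    if word.isupper():  # acronym
        return False
    if word.lower().endswith("ed"):  # direction words: increased, elevated, ...
        return False
    return True


def _looks_plural(word: str) -> bool:
    w = word.lower()
    if w.endswith(("us", "is", "ss")):
        return False
    return w.endswith("s")


def pluralize(word: str) -> str:
    """Return the plural of ``word``, or ``word`` unchanged if none applies."""
    if not _inflectable(word) or _looks_plural(word):
        return word
    w = word.lower()
    if w.endswith(("us", "is")):  # pruritus, psoriasis: treated as uninflected
        return word
    if w.endswith("y") and len(w) > 1 and w[-2] not in _VOWELS:
        return word[:-1] + "ies"
    if w.endswith(_SIBILANT_STEMS):
        return word + "es"
    return word + "s"


def singularize(word: str) -> str:
    """Return the singular of ``word``, or ``word`` unchanged if none applies."""
    if not _inflectable(word):
        return word
    w = word.lower()
    if w.endswith(("us", "is", "ss")):
        return word
    if w.endswith("ies") and len(w) > 4:
        return word[:-3] + "y"
    if w.endswith("es") and w[:-2].endswith(_SIBILANT_STEMS):
        return word[:-2]
    if w.endswith("s"):
        return word[:-1]
    return word


def number_variants(word: str) -> set[str]:
    """All grammatical-number variants of ``word``, itself included."""
    return {word, pluralize(word), singularize(word)}
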