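"""Dictionary- and rule-based ADR mention tagging and normalization.

The tagger scans each section left to right over token boundaries and takes
the longest dictionary match starting at each position (so "peripheral
neuropathies" wins over any embedded shorter term). Matches intersecting a
section or table header are removed to cut false positives, and surviving
mentions are normalized to preferred-term ids and pooled into per-drug
profiles (a drug may have several labels — one per brand).

No negation or speculation handling is attempted: an ADR mentioned in a
drug's label is taken to be associated with that drug.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .labelio import HeaderSpan, LabelDocument
from .termdict import TermDictionary, tokenize


@dataclass(frozen=True)
class Mention:
    """One tagged span; ``term_ids`` keeps ambiguity as a multi-id set."""

    section_id: str
    start: int
    length: int
    surface: str
    term_ids: frozenset[str]

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class DrugAdrProfile:
    """Normalized per-drug ADR set with mention counts."""

    drug_name: str
    mention_count: Mapping[str, int]

    @property
    def adr_terms(self) -> frozenset[str]:
        return frozenset(t for t, c in self.mention_count.items() if c > 0)


def tag_document(doc: LabelDocument, dictionary: TermDictionary) -> list[Mention]:
    """Leftmost-longest dictionary matching over every section of a label."""
    if not dictionary.compiled:
        raise ValueError("dictionary must be compiled (see compile_dictionary)")
    mentions: list[Mention] = []
    for sec in doc.sections:
        tokens = tokenize(sec.text)
        i = 0
        n = len(tokens)
        while i < n:
            match_ids: frozenset[str] = frozenset()
            match_k = 0
            for k in range(min(dictionary.max_tokens, n - i), 0, -1):
                seq = tuple(t[2] for t in tokens[i : i + k])
                ids = dictionary.lookup_tokens(seq)
                if ids:
                    match_ids, match_k = ids, k
                    break
            if match_k:
                start = tokens[i][0]
                end = tokens[i + match_k - 1][1]
                mentions.append(
                    Mention(
                        section_id=sec.section_id,
                        start=start,
                        length=end - start,
                        surface=sec.text[start:end],
                        term_ids=match_ids,
                    )
                )
                i += match_k
            else:
                i += 1
    mentions.sort(key=lambda m: (m.section_id, m.start))
    return mentions


def filter_headers(
    mentions: Iterable[Mention], headers: Iterable[HeaderSpan]
) -> list[Mention]:
    """Drop every mention whose span intersects any header span."""
    headers = list(headers)
    kept = []
    for m in mentions:
        hit = any(
            h.section_id == m.section_id and m.start < h.end and h.start < m.end
            for h in headers
        )
        if not hit:
            kept.append(m)
    return kept


def normalize_to_profile(
    drug_name: str, mentions: Iterable[Mention]
) -> DrugAdrProfile:
    """Pool mentions from all of a drug's labels into one PT-level profile.

    Ambiguous mentions (several matched ids) count toward every matched id.
    """
    counts: Counter[str] = Counter()
    for m in mentions:
        for term_id in m.term_ids:
            counts[term_id] += 1
    return DrugAdrProfile(drug_name=drug_name, mention_count=dict(counts))


def tag_and_filter(doc: LabelDocument, dictionary: TermDictionary) -> list[Mention]:
    """Convenience: tag a document and apply header exclusion."""
    from .labelio import detect_headers

    return filter_headers(tag_document(doc, dictionary), detect_headers(doc))
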