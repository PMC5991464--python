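"""Term dictionary: loading, expansion rules, and compilation.

An ADR vocabulary is a set of :class:`TermEntry` records (preferred term,
synonyms, abbreviations). Before tagging, the vocabulary is *compiled*: every
name is run through the expansion rules — grammatical-number variants of the
head noun ("peripheral neuropathy" -> "peripheral neuropathies") and
laboratory-test variant grammar ("Aspartate aminotransferase increased" ->
"increased AST", "AST elevated", "high AST") — and the resulting surface forms
are indexed for leftmost-longest matching.

Matching case policy: surface forms at least ``min_acronym_len`` characters
long are matched case-insensitively; shorter forms (acronym territory) are
matched case-sensitively, and a stoplist suppresses known ambiguous acronyms
such as "all" (which would otherwise map everyday text onto acute lymphocytic
leukaemia).
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .errors import CycleError, DuplicateIdError, ParseError

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)

#: Direction-word synonym groups for the lab-variant grammar. Any direction
#: word expands across its whole group, in both prefix and postfix order.
DEFAULT_DIRECTION_GROUPS: tuple[frozenset[str], ...] = (
    frozenset({"increased", "elevated", "high", "raised"}),
    frozenset({"decreased", "reduced", "low", "lowered"}),
)

DEFAULT_STOPLIST: frozenset[str] = frozenset({"all", "aids"})


def tokenize(text: str) -> list[tuple[int, int, str]]:
    """Split ``text`` into word tokens, returned as (start, end, token)."""
    return [(m.start(), m.end(), m.group()) for m in _TOKEN_RE.finditer(text)]


def normalize_surface(text: str) -> str:
    """NFC-normalize, strip boundary punctuation, collapse whitespace."""
    text = unicodedata.normalize("NFC", text)
    return " ".join(tok for _, _, tok in tokenize(text))


@dataclass(frozen=True)
class TermEntry:
    """One vocabulary entry: id, preferred name, synonyms, abbreviations.

    ``abbreviations`` holds (long_form, short_form) pairs, e.g.
    ("aspartate aminotransferase", "AST").
    """

    term_id: str
    preferred_name: str
    synonyms: frozenset[str] = frozenset()
    abbreviations: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self):
        pn = normalize_surface(self.preferred_name)
        if not self.term_id.strip():
            raise ValueError("term_id must be non-empty")
        if not pn:
            raise ValueError(f"{self.term_id}: preferred_name must be non-empty")
        syns = frozenset(s for s in (normalize_surface(x) for x in self.synonyms) if s)
        if pn in syns:
            raise ValueError(f"{self.term_id}: preferred_name duplicated in synonyms")
        abbrevs = frozenset(
            (normalize_surface(a), normalize_surface(b)) for a, b in self.abbreviations
        )
        if any(not a or not b for a, b in abbrevs):
            raise ValueError(f"{self.term_id}: empty abbreviation form")
        object.__setattr__(self, "preferred_name", pn)
        object.__setattr__(self, "synonyms", syns)
        object.__setattr__(self, "abbreviations", abbrevs)

    @property
    def names(self) -> frozenset[str]:
        return self.synonyms | {self.preferred_name}


@dataclass(frozen=True)
class ExpansionConfig:
    """Tunable knobs of the expansion/matching rules."""

    direction_groups: tuple[frozenset[str], ...] = DEFAULT_DIRECTION_GROUPS
    min_acronym_len: int = 5
    stoplist: frozenset[str] = DEFAULT_STOPLIST
    case_policy: str = "fold_long_only"  # or "fold_all"

    def __post_init__(self):
        if self.case_policy not in ("fold_long_only", "fold_all"):
            raise ValueError(f"unknown case_policy {self.case_policy!r}")
        if self.min_acronym_len < 1:
            raise ValueError("min_acronym_len must be positive")

    def direction_group(self, word: str) -> frozenset[str] | None:
        wl = word.casefold()
        for group in self.direction_groups:
            if wl in group:
                return group
        return None


def expand_number(term: str) -> set[str]:
    """Grammatical-number variants of ``term``'s head (last) noun.

    Always contains ``term`` itself (after surface normalization); closed
    under re-expansion: expanding any returned form yields a subset of the
    same set union its own identity forms.
    """
    from . import _inflect

    term = normalize_surface(term)
    if not term:
        raise ValueError("term must be non-empty")
    tokens = term.split(" ")
    out = set()
    for head in _inflect.number_variants(tokens[-1]):
        out.add(" ".join(tokens[:-1] + [head]))
    return out


def _lab_variants(
    name: str, abbreviations: Iterable[tuple[str, str]], config: ExpansionConfig
) -> set[str]:
    """Lab-test variant grammar for one name; empty set if pattern unmatched.

    The pattern is "<analyte phrase> <direction word>" (direction word last,
    as in MedDRA lab PTs). Output covers {analyte, its abbreviation short
    forms} x {direction-word synonym group} x {prefix, postfix order}.
    """
    name = normalize_surface(name)
    tokens = name.split(" ")
    if len(tokens) < 2:
        return set()
    group = config.direction_group(tokens[-1])
    if group is None:
        return set()
    analyte = " ".join(tokens[:-1])
    analytes = {analyte.lower()}
    for long_form, short_form in abbreviations:
        if long_form.casefold() == analyte.casefold():
            analytes.add(short_form)
    out = set()
    for a in analytes:
        for d in sorted(group):
            out.add(f"{d} {a}")
            out.add(f"{a} {d}")
    return out


def generate_lab_variants(
    entry: TermEntry, config: ExpansionConfig | None = None
) -> set[str]:
    """All lab-variant surface forms of an entry's preferred name.

    Entries whose preferred name does not match the "<analyte> <direction>"
    pattern return just ``{preferred_name}``.
    """
    config = config or ExpansionConfig()
    variants = _lab_variants(entry.preferred_name, entry.abbreviations, config)
    return variants | {entry.preferred_name} if variants else {entry.preferred_name}


@dataclass
class TermDictionary:
    """A vocabulary, optionally compiled into a matchable surface index.

    After :func:`compile_dictionary`:

    * ``surface_index`` maps every generated surface form to the set of term
      ids it normalizes to (ambiguity preserved as multi-id sets);
    * private token-tuple indexes (case-folded and case-sensitive) drive the
      tagger's leftmost-longest scan.
    """

    entries: dict[str, TermEntry] = field(default_factory=dict)
    config: ExpansionConfig = field(default_factory=ExpansionConfig)
    surface_index: dict[str, frozenset[str]] = field(default_factory=dict)
    _ci_index: dict[tuple[str, ...], frozenset[str]] = field(default_factory=dict)
    _cs_index: dict[tuple[str, ...], frozenset[str]] = field(default_factory=dict)
    max_tokens: int = 0

    @property
    def compiled(self) -> bool:
        return bool(self.surface_index) or not self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def lookup_tokens(self, tokens: tuple[str, ...]) -> frozenset[str]:
        """Term ids matching a token sequence under the case policy."""
        ids = set(self._cs_index.get(tokens, ()))
        ids |= self._ci_index.get(tuple(t.casefold() for t in tokens), frozenset())
        return frozenset(ids)


def _entry_surfaces(entry: TermEntry, config: ExpansionConfig) -> set[tuple[str, bool]]:
    """(surface, is_bare_abbreviation) pairs for one entry, rules composed."""
    base: set[str] = set()
    for name in entry.names:
        base.add(name)
        base |= _lab_variants(name, entry.abbreviations, config)
    surfaces: set[str] = set()
    for s in base:
        surfaces |= expand_number(s)
    out = {(s, False) for s in surfaces}
    for _, short_form in entry.abbreviations:
        out.add((short_form, True))
    return out


def compile_dictionary(
    entries: Iterable[TermEntry] | Mapping[str, TermEntry] | TermDictionary,
    config: ExpansionConfig | None = None,
) -> TermDictionary:
    """Apply all expansion rules and build the matchable surface index."""
    if isinstance(entries, TermDictionary):
        config = config or entries.config
        entry_list = list(entries.entries.values())
    elif isinstance(entries, Mapping):
        entry_list = list(entries.values())
    else:
        entry_list = list(entries)
    config = config or ExpansionConfig()

    by_id: dict[str, TermEntry] = {}
    for e in sorted(entry_list, key=lambda e: e.term_id):
        if e.term_id in by_id:
            raise DuplicateIdError(f"duplicate term_id {e.term_id!r}")
        by_id[e.term_id] = e

    surface_map: dict[str, set[str]] = {}
    ci: dict[tuple[str, ...], set[str]] = {}
    cs: dict[tuple[str, ...], set[str]] = {}
    max_tokens = 0
    for term_id, entry in by_id.items():
        for surface, is_abbrev in sorted(_entry_surfaces(entry, config)):
            if surface.casefold() in config.stoplist:
                continue
            short = len(surface) < config.min_acronym_len
            if short and surface.isupper() and not is_abbrev:
                continue  # acronym-like short form not licensed by an abbreviation
            toks = tuple(surface.split(" "))
            fold = config.case_policy == "fold_all" or not short
            target = ci if fold else cs
            key = tuple(t.casefold() for t in toks) if fold else toks
            target.setdefault(key, set()).add(term_id)
            surface_map.setdefault(surface, set()).add(term_id)
            max_tokens = max(max_tokens, len(toks))

    return TermDictionary(
        entries=by_id,
        config=config,
        surface_index={s: frozenset(ids) for s, ids in sorted(surface_map.items())},
        _ci_index={k: frozenset(v) for k, v in ci.items()},
        _cs_index={k: frozenset(v) for k, v in cs.items()},
        max_tokens=max_tokens,
    )


def load_term_table(path) -> TermDictionary:
    """Load an uncompiled dictionary from a TSV term table.

    Columns: term_id, preferred_name, synonyms (pipe-separated),
    abbreviations (pipe-separated ``long=short`` pairs).
    """
    entries: dict[str, TermEntry] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["term_id", "preferred_name"]:
            raise ParseError(f"{path}: missing or malformed header row")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}:{lineno}: expected >= 2 columns, got {len(row)}")
            term_id = row[0].strip()
            preferred = row[1].strip()
            synonyms = [s for s in (row[2].split("|") if len(row) > 2 else []) if s.strip()]
            abbrevs = []
            for pair in row[3].split("|") if len(row) > 3 else []:
                if not pair.strip():
                    continue
                if "=" not in pair:
                    raise ParseError(
                        f"{path}:{lineno}: abbreviation {pair!r} is not long=short"
                    )
                long_form, short_form = pair.split("=", 1)
                abbrevs.append((long_form.strip(), short_form.strip()))
            if term_id in entries:
                raise DuplicateIdError(f"{path}:{lineno}: duplicate term_id {term_id!r}")
            try:
                entries[term_id] = TermEntry(
                    term_id=term_id,
                    preferred_name=preferred,
                    synonyms=frozenset(synonyms),
                    abbreviations=frozenset(abbrevs),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return TermDictionary(entries=entries)


class Ontology:
    """An is-a hierarchy: a DAG over (id, name) terms, child -> parent."""

    def __init__(self, terms: Mapping[str, str], is_a: Iterable[tuple[str, str]]):
        self._names = dict(terms)
        g = nx.DiGraph()
        g.add_nodes_from(self._names)
        for child, parent in is_a:
            if child not in self._names or parent not in self._names:
                raise ParseError(f"is_a edge ({child}, {parent}) references unknown id")
            g.add_edge(child, parent)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            raise CycleError([e[0] for e in cycle] + [cycle[-1][1]])
        self._graph = g

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(self._names)

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(n for n in self._graph if self._graph.out_degree(n) == 0)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._names

    def __len__(self) -> int:
        return len(self._names)

    def name(self, term_id: str) -> str:
        return self._names[term_id]

    def parents(self, term_id: str) -> frozenset[str]:
        return frozenset(self._graph.successors(term_id))

    def children(self, term_id: str) -> frozenset[str]:
        return frozenset(self._graph.predecessors(term_id))

    def ancestors(self, term_id: str, include_self: bool = False) -> frozenset[str]:
        """All terms reachable from ``term_id`` by following is_a upward."""
        anc = nx.descendants(self._graph, term_id)  # edges point child -> parent
        if include_self:
            anc = anc | {term_id}
        return frozenset(anc)

    def descendants(self, term_id: str, include_self: bool = False) -> frozenset[str]:
        """All terms below ``term_id`` in the is_a hierarchy."""
        desc = nx.ancestors(self._graph, term_id)  # edges point child -> parent
        if include_self:
            desc = desc | {term_id}
        return frozenset(desc)

    def is_a_edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._graph.edges())

    def to_obo_str(self, header_comment: str = "") -> str:
        lines = ["format-version: 1.2"]
        if header_comment:
            lines.append(f"remark: {header_comment}")
        for term_id in sorted(self._names):
            lines += ["", "[Term]", f"id: {term_id}", f"name: {self._names[term_id]}"]
            for parent in sorted(self.parents(term_id)):
                lines.append(f"is_a: {parent} ! {self._names[parent]}")
        return "\n".join(lines) + "\n"


def load_obo(path) -> Ontology:
    """Load an OBO 1.2 ontology (is_a edges only; obsolete terms skipped)."""
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except CycleError:
        raise
    except Exception as exc:  # malformed stanza, missing id, ...
        raise ParseError(f"{path}: {exc}") from exc
    terms = {}
    edges = []
    for node, data in graph.nodes(data=True):
        terms[node] = data.get("name", node)
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            edges.append((child, parent))
    return Ontology(terms, edges)
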