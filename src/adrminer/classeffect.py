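"""Ontology-based drug class effects on adverse events.

Drugs are placed into chemical classes by taking every is-a ancestor of
their chemical term. For a class and an ADR, the proportional class-level
ratio (PCR) is the fraction of the class's drugs whose ADR profile contains
that ADR; PCR = 1 defines a drug class effect (every drug of the class shares
the AE). The shared ADRs of a class can then be viewed hierarchically by
extracting the sub-ontology spanned by those terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .errors import EmptyClassError, UnknownTermError
from .network import DrugAdrTable
from .termdict import Ontology


@dataclass(frozen=True)
class ClassAssignment:
    """drug name -> set of ontology class ids (ancestor-closed)."""

    classes: Mapping[str, frozenset[str]]

    def members(self, class_id: str) -> frozenset[str]:
        return frozenset(d for d, cs in self.classes.items() if class_id in cs)

    def all_classes(self) -> frozenset[str]:
        out: set[str] = set()
        for cs in self.classes.values():
            out |= cs
        return frozenset(out)


@dataclass(frozen=True)
class ClassEffectResult:
    class_id: str
    adr_term_id: str
    n_class_drugs: int
    n_with_adr: int

    @property
    def pcr(self) -> float:
        return self.n_with_adr / self.n_class_drugs

    @property
    def class_effect(self) -> bool:
        return self.n_with_adr == self.n_class_drugs


def assign_classes(drug_terms: Mapping[str, str], ontology: Ontology) -> ClassAssignment:
    """Assign each drug every is-a ancestor of its chemical term."""
    classes = {}
    for drug, term_id in drug_terms.items():
        if term_id not in ontology:
            raise UnknownTermError(f"drug {drug!r}: term {term_id!r} not in ontology")
        classes[drug] = ontology.ancestors(term_id)
    return ClassAssignment(classes=classes)


def _class_members_in_table(
    class_id: str, assignment: ClassAssignment, table: DrugAdrTable
) -> list[str]:
    members = sorted(d for d in assignment.members(class_id) if d in table.profiles)
    if not members:
        raise EmptyClassError(f"class {class_id!r} has no member drug with a profile")
    return members


def compute_pcr(
    class_id: str,
    adr_term_id: str,
    assignment: ClassAssignment,
    table: DrugAdrTable,
) -> ClassEffectResult:
    """PCR of one (class, ADR) pair: fraction of class drugs with the ADR."""
    members = _class_members_in_table(class_id, assignment, table)
    n_with = sum(1 for d in members if adr_term_id in table.profiles[d])
    return ClassEffectResult(
        class_id=class_id,
        adr_term_id=adr_term_id,
        n_class_drugs=len(members),
        n_with_adr=n_with,
    )


def shared_adrs(
    class_id: str, assignment: ClassAssignment, table: DrugAdrTable
) -> frozenset[str]:
    """ADRs present in every member drug's profile (the PCR = 1 set)."""
    members = _class_members_in_table(class_id, assignment, table)
    shared = set(table.profiles[members[0]])
    for d in members[1:]:
        shared &= table.profiles[d]
    return frozenset(shared)


def pcr_table(
    assignment: ClassAssignment,
    table: DrugAdrTable,
    min_class_size: int = 2,
) -> list[ClassEffectResult]:
    """PCR for every (class, ADR) pair over classes with enough members."""
    results = []
    for class_id in sorted(assignment.all_classes()):
        members = sorted(d for d in assignment.members(class_id) if d in table.profiles)
        if len(members) < min_class_size:
            continue
        adrs = sorted(set().union(*(table.profiles[d] for d in members)))
        for adr in adrs:
            results.append(compute_pcr(class_id, adr, assignment, table))
    return results


@dataclass(frozen=True)
class SubOntology:
    """An extracted slice of an ontology: selected terms plus connecting ones."""

    terms: Mapping[str, str]  # id -> name
    edges: frozenset[tuple[str, str]]  # child -> parent, transitively reduced
    selected: frozenset[str]
    inclusion_mode: str

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(self.terms)

    def to_ontology(self) -> Ontology:
        return Ontology(dict(self.terms), sorted(self.edges))

    def to_obo_str(self) -> str:
        return self.to_ontology().to_obo_str(
            header_comment=f"extracted sub-ontology ({self.inclusion_mode})"
        )


def extract_subtree(
    ontology: Ontology,
    selected: Iterable[str],
    mode: str = "computed_intermediate",
) -> SubOntology:
    """Extract the hierarchy slice spanned by ``selected`` terms.

    ``computed_intermediate``: include every term lying on an is-a path
    between two selected terms, then connect each top-most included term to
    a root by a deterministic shortest path. ``ancestors_all``: include all
    ancestors of every selected term.
    """
    selected = frozenset(selected)
    unknown = selected - ontology.ids
    if unknown:
        raise UnknownTermError(f"selected terms not in ontology: {sorted(unknown)}")
    if mode not in ("computed_intermediate", "ancestors_all"):
        raise ValueError(f"unknown inclusion mode {mode!r}")

    if mode == "ancestors_all":
        included = set(selected)
        for t in selected:
            included |= ontology.ancestors(t)
    else:
        included = _computed_intermediates(ontology, selected)
        for s in sorted(selected):
            included |= set(_cheapest_root_path(ontology, s, included))

    sub_edges = sorted(
        (c, p) for c, p in ontology.is_a_edges() if c in included and p in included
    )
    g = nx.DiGraph()
    g.add_nodes_from(sorted(included))
    g.add_edges_from(sub_edges)
    red = nx.transitive_reduction(g)
    return SubOntology(
        terms={t: ontology.name(t) for t in sorted(included)},
        edges=frozenset(red.edges()),
        selected=selected,
        inclusion_mode=mode,
    )


def _computed_intermediates(ontology: Ontology, selected: frozenset[str]) -> set[str]:
    """Selected terms, convergence points, and directed between-path terms.

    A term is included when it is an ancestor(-or-self) of at least two
    selected terms (a merging point of their lineages), or when it lies on a
    directed is-a path between two selected terms.
    """
    ancestor_hits: dict[str, int] = {}
    for s in selected:
        for v in ontology.ancestors(s, include_self=True):
            ancestor_hits[v] = ancestor_hits.get(v, 0) + 1
    below_selected: set[str] = set()
    for t in selected:
        below_selected |= ontology.descendants(t, include_self=True)
    included = {v for v, hits in ancestor_hits.items() if hits >= 2}
    included |= {v for v in ancestor_hits if v in below_selected}
    return included | set(selected)


def _cheapest_root_path(ontology: Ontology, start: str, included: set[str]) -> list[str]:
    """Path from ``start`` to a root preferring already-included terms.

    Cost of a path is (number of newly added terms, hop count); ties broken
    by root id, so the result is deterministic.
    """
    g = nx.DiGraph()
    big = len(ontology) + 1
    for child, parent in sorted(ontology.is_a_edges()):
        g.add_edge(child, parent, weight=(big if parent not in included else 0) + 1)
    if start not in g:
        return [start]  # isolated term is its own root
    costs = nx.single_source_dijkstra_path_length(g, start)
    reachable_roots = sorted(
        (cost, r) for r, cost in costs.items() if r in ontology.roots
    )
    if not reachable_roots:
        return [start]
    _, root = reachable_roots[0]
    return nx.dijkstra_path(g, start, root)


def write_pcr_table(results: Iterable[ClassEffectResult], path) -> None:
    """Per-(class, ADR) PCR table as TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("class_id\tadr_term_id\tn_class_drugs\tn_with_adr\tpcr\tclass_effect\n")
        for r in results:
            fh.write(
                f"{r.class_id}\t{r.adr_term_id}\t{r.n_class_drugs}\t"
                f"{r.n_with_adr}\t{r.pcr:.6f}\t{int(r.class_effect)}\n"
            )
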