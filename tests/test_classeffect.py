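"""Class assignment, PCR computation, shared ADRs, and sub-ontology extraction."""

import random

import networkx as nx
import pytest

from adrminer.classeffect import (
    assign_classes,
    compute_pcr,
    extract_subtree,
    pcr_table,
    shared_adrs,
)
from adrminer.errors import EmptyClassError, UnknownTermError
from adrminer.network import DrugAdrTable
from adrminer.termdict import Ontology


@pytest.fixture()
def chain_ontology():
    # drug terms -> benzimidazole-like group -> organics -> root
    terms = {
        "root": "chemical entity",
        "org": "organic compound",
        "benz": "benzimidazoles",
        "d1": "drug one",
        "d2": "drug two",
        "d3": "drug three",
    }
    edges = [("org", "root"), ("benz", "org"), ("d1", "benz"), ("d2", "benz"), ("d3", "benz")]
    return Ontology(terms, edges)


@pytest.fixture()
def three_drug_table():
    return DrugAdrTable(
        {
            "one": frozenset({"a", "b", "c"}),
            "two": frozenset({"b", "c"}),
            "three": frozenset({"b", "c", "d"}),
        }
    )


@pytest.fixture()
def assignment(chain_ontology):
    return assign_classes({"one": "d1", "two": "d2", "three": "d3"}, chain_ontology)


class TestAssignClasses:
    def test_chain_closure(self, chain_ontology):
        asg = assign_classes({"one": "d1"}, chain_ontology)
        assert asg.classes["one"] == {"benz", "org", "root"}

    def test_shared_parent_membership(self, assignment):
        assert assignment.members("benz") == {"one", "two", "three"}

    def test_unknown_term_names_drug(self, chain_ontology):
        with pytest.raises(UnknownTermError, match="mystery"):
            assign_classes({"mystery": "nope"}, chain_ontology)

    def test_multi_parent_matches_bfs_oracle(self):
        rng = random.Random(3)
        for _ in range(20):
            g = nx.gnp_random_graph(12, 0.25, seed=rng.randint(0, 10**6), directed=True)
            dag = nx.DiGraph((f"t{u}", f"t{v}") for u, v in g.edges if u < v)
            dag.add_nodes_from(f"t{i}" for i in range(12))
            ont = Ontology({n: n for n in dag}, list(dag.edges))
            asg = assign_classes({"drug": "t0"}, ont)
            # independent BFS oracle over the parent relation
            seen, frontier = set(), ["t0"]
            while frontier:
                nxt = []
                for node in frontier:
                    for p in dag.successors(node):
                        if p not in seen:
                            seen.add(p)
                            nxt.append(p)
                frontier = nxt
            assert asg.classes["drug"] == seen


class TestPcr:
    def test_full_class_effect(self, assignment, three_drug_table):
        r = compute_pcr("benz", "b", assignment, three_drug_table)
        assert r.pcr == 1.0 and r.class_effect

    def test_partial_ratio(self, assignment, three_drug_table):
        r = compute_pcr("benz", "a", assignment, three_drug_table)
        assert r.pcr == pytest.approx(1 / 3) and not r.class_effect

    def test_absent_adr_zero(self, assignment, three_drug_table):
        assert compute_pcr("benz", "zzz", assignment, three_drug_table).pcr == 0.0

    def test_empty_class_rejected(self, assignment):
        table = DrugAdrTable({"unrelated": frozenset({"a"})})
        with pytest.raises(EmptyClassError):
            compute_pcr("benz", "a", assignment, table)

    def test_monotonicity_under_membership_growth(self, chain_ontology):
        ont = chain_ontology
        base = {"one": "d1", "two": "d2"}
        profiles = {"one": frozenset({"a"}), "two": frozenset({"a"})}
        r0 = compute_pcr("benz", "a", assign_classes(base, ont), DrugAdrTable(profiles))
        # adding a member lacking the ADR strictly decreases pcr
        with_lacker = dict(profiles, three=frozenset({"z"}))
        r1 = compute_pcr(
            "benz", "a", assign_classes(dict(base, three="d3"), ont),
            DrugAdrTable(with_lacker),
        )
        assert r1.pcr < r0.pcr
        # adding one having it never decreases pcr
        with_haver = dict(profiles, three=frozenset({"a", "z"}))
        r2 = compute_pcr(
            "benz", "a", assign_classes(dict(base, three="d3"), ont),
            DrugAdrTable(with_haver),
        )
        assert r2.pcr >= r0.pcr


class TestSharedAdrs:
    def test_intersection(self, assignment, three_drug_table):
        assert shared_adrs("benz", assignment, three_drug_table) == {"b", "c"}

    def test_single_member_class_full_profile(self, chain_ontology):
        asg = assign_classes({"one": "d1"}, chain_ontology)
        table = DrugAdrTable({"one": frozenset({"a", "b"})})
        assert shared_adrs("benz", asg, table) == {"a", "b"}

    def test_equals_pcr_one_set(self, assignment, three_drug_table):
        """Cross-check the two code paths on every class."""
        for class_id in sorted(assignment.all_classes()):
            shared = shared_adrs(class_id, assignment, three_drug_table)
            all_adrs = set().union(*three_drug_table.profiles.values())
            by_pcr = {
                a
                for a in all_adrs
                if compute_pcr(class_id, a, assignment, three_drug_table).class_effect
            }
            assert shared == by_pcr

    def test_planted_43_recovered(self, clean_universe):
        asg = assign_classes(clean_universe.drug_terms, clean_universe.drug_ontology)
        table = DrugAdrTable(clean_universe.profiles)
        planted = clean_universe.planted_classes[0]
        shared = shared_adrs(planted, asg, table)
        assert shared == clean_universe.shared_by_class[planted]
        assert len(shared) == 43

    def test_no_false_class_effects(self, clean_universe):
        asg = assign_classes(clean_universe.drug_terms, clean_universe.drug_ontology)
        table = DrugAdrTable(clean_universe.profiles)
        effects = {}
        for r in pcr_table(asg, table, min_class_size=2):
            if r.class_effect:
                effects.setdefault(r.class_id, set()).add(r.adr_term_id)
        expected = {
            c: set(s) for c, s in clean_universe.shared_by_class.items() if s
        }
        assert effects == expected


class TestExtractSubtree:
    def test_common_parent_included_with_root_path(self, chain_ontology):
        sub = extract_subtree(chain_ontology, ["d1", "d2"])
        assert sub.ids == {"d1", "d2", "benz", "org", "root"}

    def test_single_root_singleton(self, chain_ontology):
        sub = extract_subtree(chain_ontology, ["root"])
        assert sub.ids == {"root"}

    def test_unknown_selection_rejected(self, chain_ontology):
        with pytest.raises(UnknownTermError):
            extract_subtree(chain_ontology, ["ghost"])

    def test_ancestors_all_mode(self, chain_ontology):
        sub = extract_subtree(chain_ontology, ["d1"], mode="ancestors_all")
        assert sub.ids == {"d1", "benz", "org", "root"}

    def test_edges_transitively_reduced(self, chain_ontology):
        sub = extract_subtree(chain_ontology, ["d1", "d2"])
        assert ("d1", "benz") in sub.edges and ("d1", "org") not in sub.edges

    def test_idempotent_on_extracted_ontology(self, clean_universe):
        ont = clean_universe.adr_ontology
        planted = clean_universe.planted_classes[0]
        selected = sorted(clean_universe.shared_by_class[planted])
        sub1 = extract_subtree(ont, selected)
        sub2 = extract_subtree(sub1.to_ontology(), selected)
        assert sub2.ids == sub1.ids

    def test_matches_path_enumeration_oracle(self):
        """Convergence points agree with brute-force path enumeration on DAGs."""
        rng = random.Random(7)
        for _ in range(25):
            n = rng.randint(5, 14)
            dag = nx.DiGraph()
            dag.add_nodes_from(f"t{i}" for i in range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.25:
                        dag.add_edge(f"t{i}", f"t{j}")  # child -> parent, acyclic
            ont = Ontology({x: x for x in dag}, list(dag.edges))
            selected = rng.sample(sorted(dag.nodes), rng.randint(1, min(4, n)))
            sub = extract_subtree(ont, selected)
            # Oracle: v is a computed intermediate iff it is ancestor-or-self
            # of >= 2 selected terms or lies on a directed path between two.
            up = {s: ont.ancestors(s, include_self=True) for s in selected}
            must_have = set(selected)
            for v in ont.ids:
                hits = sum(v in anc for anc in up.values())
                on_path = any(v in up[s] for s in selected) and any(
                    t in ont.ancestors(v, include_self=True) for t in selected
                )
                if hits >= 2 or on_path:
                    must_have.add(v)
            assert must_have <= sub.ids
            # everything beyond must_have is on a root-connection path
            for extra in sub.ids - must_have:
                assert ont.ancestors(extra) | {extra}  # reachable upward chain exists
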