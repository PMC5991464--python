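"""Dictionary loading, expansion rules, compilation, and OBO ontologies."""

import pytest
from hypothesis import given, settings, strategies as st

from adrminer import termdict
from adrminer.errors import CycleError, DuplicateIdError, ParseError
from adrminer.termdict import (
    ExpansionConfig,
    TermEntry,
    compile_dictionary,
    expand_number,
    generate_lab_variants,
    load_obo,
    load_term_table,
)


class TestLoadTermTable:
    def test_row_with_abbreviation(self, tmp_path):
        p = tmp_path / "dict.tsv"
        p.write_text(
            "term_id\tpreferred_name\tsynonyms\tabbreviations\n"
            "10003481\tAspartate aminotransferase increased\t\t"
            "aspartate aminotransferase=AST\n"
        )
        d = load_term_table(p)
        assert len(d) == 1
        e = d.entries["10003481"]
        assert e.preferred_name == "Aspartate aminotransferase increased"
        assert e.synonyms == frozenset()
        assert e.abbreviations == frozenset([("aspartate aminotransferase", "AST")])

    def test_header_only_file(self, tmp_path):
        p = tmp_path / "dict.tsv"
        p.write_text("term_id\tpreferred_name\tsynonyms\tabbreviations\n")
        assert len(load_term_table(p)) == 0

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dict.tsv"
        p.write_text(
            "term_id\tpreferred_name\n1\theadache\n1\tnausea\n"
        )
        with pytest.raises(DuplicateIdError):
            load_term_table(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "dict.tsv"
        p.write_text(
            "term_id\tpreferred_name\tsynonyms\tabbreviations\n"
            "1\theadache\t\tnot-a-pair\n"
        )
        with pytest.raises(ParseError, match=":2"):
            load_term_table(p)


class TestExpandNumber:
    @pytest.mark.parametrize(
        "term,expected_member",
        [
            ("peripheral neuropathy", "peripheral neuropathies"),
            ("rash", "rashes"),
            ("renal ulcer", "renal ulcers"),
        ],
    )
    def test_contains_plural(self, term, expected_member):
        out = expand_number(term)
        assert term in out and expected_member in out

    def test_mass_noun_identity(self):
        assert "pruritus" in expand_number("pruritus")
        assert not any(v.endswith("es") for v in expand_number("pruritus"))

    @given(
        st.sampled_from(
            ["peripheral neuropathy", "rash", "pruritus", "renal ulcers",
             "focal spasm", "AST elevated", "swelling", "decreased blood glucose"]
        )
    )
    @settings(derandomize=True)
    def test_idempotent_closure(self, term):
        """Expanding any expansion output adds nothing new."""
        first = expand_number(term)
        closure = set()
        for v in first:
            closure |= expand_number(v)
        assert closure == first


class TestLabVariants:
    def test_printed_ast_variants(self, ast_entry):
        v = generate_lab_variants(ast_entry)
        for s in ("increased AST", "AST elevated", "high AST"):
            assert s in v

    def test_non_lab_entry_passthrough(self):
        e = TermEntry("1", "headache")
        assert generate_lab_variants(e) == {"headache"}

    def test_direction_group_enumeration(self):
        # Hand enumeration: analyte 'blood glucose' x directions
        # {decreased, reduced, low, lowered} x both orders = 8 variants.
        e = TermEntry("2", "Blood glucose decreased")
        v = generate_lab_variants(e)
        expected = {
            f"{d} blood glucose" for d in ("decreased", "reduced", "low", "lowered")
        } | {
            f"blood glucose {d}" for d in ("decreased", "reduced", "low", "lowered")
        }
        assert expected <= v
        for s in ("decreased blood glucose", "blood glucose reduced", "low blood glucose"):
            assert s in v


class TestCompileDictionary:
    def test_plural_and_singular_indexed_to_same_id(self):
        d = compile_dictionary([TermEntry("1", "peripheral neuropathy")])
        assert d.surface_index["peripheral neuropathy"] == frozenset({"1"})
        assert d.surface_index["peripheral neuropathies"] == frozenset({"1"})

    def test_empty_dictionary(self):
        d = compile_dictionary([])
        assert d.surface_index == {} and d.compiled

    def test_shared_synonym_keeps_ambiguity(self):
        a = TermEntry("1", "alpha syndrome", synonyms=frozenset(["AST increased"]))
        b = TermEntry("2", "beta syndrome", synonyms=frozenset(["AST increased"]))
        d = compile_dictionary([a, b])
        assert d.surface_index["AST increased"] == frozenset({"1", "2"})

    def test_duplicate_entries_rejected(self):
        with pytest.raises(DuplicateIdError):
            compile_dictionary([TermEntry("1", "x y"), TermEntry("1", "z w")])

    def test_expansion_closure_invariant(self, ast_entry):
        d = compile_dictionary([ast_entry, TermEntry("1", "peripheral neuropathy")])
        for surface in d.surface_index:
            for v in expand_number(surface):
                assert v in d.surface_index, (surface, v)

    def test_compilation_deterministic(self, clean_universe):
        d1 = compile_dictionary(clean_universe.entries)
        d2 = compile_dictionary(clean_universe.entries)
        assert d1.surface_index == d2.surface_index

    def test_every_term_id_indexed(self, clean_universe):
        d = compile_dictionary(clean_universe.entries)
        indexed = set().union(*d.surface_index.values())
        assert indexed == set(d.entries)

    def test_stoplist_suppresses_ambiguous_acronym(self):
        e = TermEntry(
            "L1", "acute lymphoid leukopathy",
            abbreviations=frozenset([("acute lymphoid leukopathy", "ALL")]),
        )
        d = compile_dictionary([e])
        assert "ALL" not in d.surface_index and "all" not in d.surface_index
        assert not d.lookup_tokens(("ALL",)) and not d.lookup_tokens(("all",))

    def test_short_abbreviation_case_sensitive(self, ast_entry):
        d = compile_dictionary([ast_entry])
        assert d.lookup_tokens(("AST",)) == frozenset({"10003481"})
        assert d.lookup_tokens(("ast",)) == frozenset()


class TestOntology:
    def _write(self, tmp_path, body):
        p = tmp_path / "ont.obo"
        p.write_text("format-version: 1.2\n\n" + body)
        return p

    def test_chain_roots(self, tmp_path):
        p = self._write(
            tmp_path,
            "[Term]\nid: a\nname: A\nis_a: b\n\n"
            "[Term]\nid: b\nname: B\nis_a: c\n\n"
            "[Term]\nid: c\nname: C\n",
        )
        ont = load_obo(p)
        assert ont.roots == {"c"}
        assert ont.ancestors("a") == {"b", "c"}

    def test_multi_parent_dag(self, tmp_path):
        p = self._write(
            tmp_path,
            "[Term]\nid: a\nname: A\nis_a: b\nis_a: c\n\n"
            "[Term]\nid: b\nname: B\n\n[Term]\nid: c\nname: C\n",
        )
        ont = load_obo(p)
        assert ont.parents("a") == {"b", "c"}

    def test_cycle_rejected(self, tmp_path):
        p = self._write(
            tmp_path,
            "[Term]\nid: a\nname: A\nis_a: b\n\n[Term]\nid: b\nname: B\nis_a: a\n",
        )
        with pytest.raises(CycleError):
            load_obo(p)

    def test_obsolete_terms_skipped(self, tmp_path):
        p = self._write(
            tmp_path,
            "[Term]\nid: a\nname: A\n\n"
            "[Term]\nid: old\nname: Old\nis_obsolete: true\n",
        )
        ont = load_obo(p)
        assert "old" not in ont and "a" in ont

    def test_obo_round_trip(self, clean_universe, tmp_path):
        p = tmp_path / "adr.obo"
        p.write_text(clean_universe.adr_ontology.to_obo_str())
        ont = load_obo(p)
        assert ont.ids == clean_universe.adr_ontology.ids
        assert ont.is_a_edges() == clean_universe.adr_ontology.is_a_edges()


class TestCaseFoldPolicy:
    def test_long_surface_case_insensitive(self):
        d = compile_dictionary([TermEntry("1", "peripheral neuropathy")])
        assert d.lookup_tokens(("PERIPHERAL", "NEUROPATHY")) == frozenset({"1"})

    def test_fold_all_folds_short_forms(self, ast_entry):
        d = compile_dictionary([ast_entry], ExpansionConfig(case_policy="fold_all"))
        assert d.lookup_tokens(("ast",)) == frozenset({"10003481"})
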