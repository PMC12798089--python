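"""Parsing, canonicalization, role reassignment, dedup, and chunked ingestion."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nocgraph.core_model import IntegrityError, ReactionRoles, ValidationError
from nocgraph.ingestion import (
    IngestionConfig,
    assign_roles,
    build_graph_elements,
    canonical_reaction_string,
    canonicalize_molecule,
    ingest,
    parse_reaction_string,
)

ESTER = "CCO.CC(=O)O>>CCOC(C)=O"


class TestParse:
    def test_two_sided(self):
        roles = parse_reaction_string(ESTER)
        assert roles.reactants == ["CCO", "CC(=O)O"]
        assert roles.agents == []
        assert roles.products == ["CCOC(C)=O"]

    def test_three_role_form(self):
        roles = parse_reaction_string("CCO>O>CC=O")
        assert (roles.reactants, roles.agents, roles.products) == (["CCO"], ["O"], ["CC=O"])

    @pytest.mark.parametrize("bad", ["CCO>CC=O", "CCO", "A>B>C>D"])
    def test_wrong_separator_count(self, bad):
        with pytest.raises(ValidationError):
            parse_reaction_string(bad)

    @pytest.mark.parametrize("bad,role", [(">>CC=O", "reactants"), ("CCO>>", "products")])
    def test_empty_mandatory_role_named(self, bad, role):
        with pytest.raises(ValidationError, match=role):
            parse_reaction_string(bad)

    def test_whitespace_stripped(self):
        roles = parse_reaction_string("  CCO . O >> CC=O ")
        assert roles.reactants == ["CCO", "O"]
        assert roles.products == ["CC=O"]


class TestCanonicalize:
    def test_equivalent_writings_converge(self):
        assert canonicalize_molecule("OCC") == canonicalize_molecule("CCO")

    def test_fixed_point(self):
        once = canonicalize_molecule("C(C)(=O)O")
        assert canonicalize_molecule(once) == once

    def test_atom_maps_stripped_stereo_kept(self):
        assert canonicalize_molecule("[CH3:1][CH2:2]O") == canonicalize_molecule("CCO")
        stereo = canonicalize_molecule("C/C=C/C")
        assert stereo != canonicalize_molecule("C/C=C\\C")

    @pytest.mark.parametrize("bad", ["C(", "not-a-molecule", ""])
    def test_unparseable_rejected(self, bad):
        with pytest.raises(ValidationError):
            canonicalize_molecule(bad)


class TestAssignRoles:
    def test_both_sides_species_moved_to_agents(self):
        roles = assign_roles(ReactionRoles(["CCO", "O"], [], ["CC=O", "O"]))
        assert roles.reactants == ["CCO"]
        assert roles.agents == ["O"]
        assert roles.products == ["CC=O"]

    def test_no_overlap_unchanged(self):
        roles = assign_roles(ReactionRoles(["CCO"], [], ["CC=O"]))
        assert (roles.reactants, roles.agents, roles.products) == (["CCO"], [], ["CC=O"])

    def test_degenerate_reaction_rejected(self):
        with pytest.raises(ValidationError):
            assign_roles(ReactionRoles(["O"], [], ["O"]))

    def test_within_role_duplicates_collapsed(self):
        roles = assign_roles(ReactionRoles(["C", "C"], [], ["CC"]))
        assert roles.reactants == ["C"]


class TestCanonicalReactionString:
    def test_sorted_join(self):
        roles = ReactionRoles(["CC(=O)O", "CCO"], [], ["CCOC(C)=O"])
        assert canonical_reaction_string(roles) == ESTER.replace("CCO.CC(=O)O", "CC(=O)O.CCO")

    @settings(derandomize=True, max_examples=30)
    @given(st.permutations(["CCO", "CC(=O)O", "O=C=O"]))
    def test_reactant_order_invariance(self, perm):
        base = canonical_reaction_string(ReactionRoles(list(perm), [], ["CCOC(C)=O"]))
        ref = canonical_reaction_string(
            ReactionRoles(["CCO", "CC(=O)O", "O=C=O"], [], ["CCOC(C)=O"]))
        assert base == ref

    def test_differently_written_inputs_one_uid(self):
        g1, _ = ingest(["OCC.CC(=O)O>>CCOC(C)=O"])
        g2, _ = ingest([ESTER])
        assert set(g1.reactions) == set(g2.reactions)


class TestBuildElements:
    def test_counts(self):
        nodes, edges = build_graph_elements(parse_reaction_string(ESTER))
        kinds = [type(n).__name__ for n in nodes]
        assert kinds.count("ReactionNode") == 1
        assert kinds.count("MoleculeNode") == 3
        assert sum(e.kind.value == "REACTANT" for e in edges) == 2
        assert sum(e.kind.value == "PRODUCT" for e in edges) == 1

    def test_duplicate_reactant_species_deduplicated(self):
        nodes, edges = build_graph_elements(parse_reaction_string("C.C>>CC"))
        assert sum(e.kind.value == "REACTANT" for e in edges) == 1
        assert sum(type(n).__name__ == "MoleculeNode" for n in nodes) == 2


class TestIngest:
    ROWS = [ESTER, "CCO>O>CC=O", "OCC.CC(=O)O>>CCOC(C)=O", "N>>C=O"]

    @pytest.mark.parametrize("chunk_size", [1, 2, 3, 100])
    @pytest.mark.parametrize("workers", [1, 3])
    def test_chunking_invariance(self, chunk_size, workers):
        ref, _ = ingest(self.ROWS, IngestionConfig())
        got, _ = ingest(self.ROWS, IngestionConfig(chunk_size=chunk_size, n_workers=workers))
        assert got == ref

    def test_dedup_idempotence(self):
        once, _ = ingest(self.ROWS)
        twice, _ = ingest(self.ROWS + self.ROWS)
        assert once == twice

    def test_exact_duplicate_one_reaction_node(self):
        g, report = ingest([ESTER, ESTER])
        assert g.n_reactions == 1
        assert report.n_unique_reactions == 1

    def test_validate_false_dedups_by_exact_string_only(self):
        rows = [ESTER, "OCC.CC(=O)O>>CCOC(C)=O"]
        validated, _ = ingest(rows, IngestionConfig(validate=True))
        raw, _ = ingest(rows, IngestionConfig(validate=False))
        assert validated.n_reactions == 1
        assert raw.n_reactions == 2  # different raw strings stay distinct

    def test_validation_monotonicity(self):
        rows = self.ROWS * 2 + ["CC(O)C>>CC(C)O"]
        with_val, _ = ingest(rows, IngestionConfig(validate=True))
        without, _ = ingest(rows, IngestionConfig(validate=False))
        assert with_val.n_reactions <= without.n_reactions

    def test_failures_skipped_and_logged(self):
        g, report = ingest([ESTER, "garbage>>", "C(>>C"],
                           IngestionConfig(on_error="skip_and_log"))
        assert report.n_input_rows == 3
        assert report.n_failed == 2
        assert [row for row, _ in report.failures] == [1, 2]
        assert g.n_reactions == 1

    def test_fail_fast_raises_with_row(self):
        with pytest.raises(ValidationError, match="row 1"):
            ingest([ESTER, "C(>>C"], IngestionConfig(on_error="fail_fast"))

    def test_dataframe_input_and_missing_column(self):
        df = pd.DataFrame({"rxn": [ESTER]})
        g, _ = ingest(df, IngestionConfig(reaction_column="rxn"))
        assert g.n_reactions == 1
        with pytest.raises(IntegrityError, match="reaction"):
            ingest(df, IngestionConfig(reaction_column="reaction"))

    def test_report_totals_consistent(self):
        _, report = ingest(self.ROWS + ["bad"])
        assert report.n_unique_reactions <= report.n_input_rows - report.n_failed

    def test_agents_kept_as_property_not_in_graph(self):
        g, _ = ingest(["CCO>O>CC=O"])
        rxn = next(iter(g.reactions.values()))
        assert rxn.properties.get("agents") == "O"
        water_uid = [u for u, n in g.molecules.items() if n.smiles == "O"]
        assert not water_uid  # agent excluded from the bipartite core

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(min_value=1, max_value=9), st.randoms(use_true_random=False))
    def test_chunking_invariance_under_permutation(self, chunk_size, rnd):
        rows = list(self.ROWS)
        rnd.shuffle(rows)
        ref, _ = ingest(self.ROWS)
        got, _ = ingest(rows, IngestionConfig(chunk_size=chunk_size))
        assert got == ref
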