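"""Edge expansion dictionary, housekeeping rules and aggregation matrices."""

import numpy as np
import pytest

from netkin.compiler import (
    CompileError,
    Form,
    ReactionSystem,
    build_aggregation,
    compile_network,
)
from netkin.network import ActiveForm, ActiveModeTable, infer_active_modes

from conftest import make_net


def names(sys_):
    return {el.name for el in sys_.elements}


def reaction_set(sys_):
    """Human-readable (reactants, products) pairs for hand comparison."""
    by_name = {el.index: el.name for el in sys_.elements}
    return {
        (tuple(sorted(by_name[i] for i in r.reactants)),
         tuple(sorted(by_name[i] for i in r.products)))
        for r in sys_.reactions
    }


class TestExpandEdge:
    def test_binding_is_one_reversible_reaction(self):
        net = make_net([("A", "B", "binding", "activation")])
        sys_ = compile_network(net, housekeeping=False)
        assert sys_.n_reactions == 1
        r = sys_.reactions[0]
        assert r.reversible and sys_.n_parameters == 2
        assert (("A", "B"), ("A:B",)) in reaction_set(sys_)

    def test_lumped_phosphorylation_is_one_irreversible_reaction(self):
        net = make_net([("B", "A", "phosphorylation", "activation")])
        sys_ = compile_network(net, housekeeping=False)
        assert sys_.n_reactions == 1 and sys_.n_parameters == 1
        # enzyme B unmodified-active; substrate enters unphosphorylated
        assert (("A", "B"), ("A_p", "B")) in reaction_set(sys_)
        assert "A_p" in names(sys_)

    def test_detailed_dialect_splits_catalysis(self):
        net = make_net([("B", "A", "phosphorylation", "activation")])
        sys_ = compile_network(net, dialect="detailed", housekeeping=False)
        assert sys_.n_reactions == 2  # ES binding (reversible) + catalysis
        assert sys_.n_parameters == 3

    def test_enzyme_participates_in_its_active_form(self):
        # B is phosphorylated-active, so B_p carries out the catalysis on A
        net = make_net([("C", "B", "phosphorylation", "activation"),
                        ("B", "A", "phosphorylation", "activation")])
        sys_ = compile_network(net, housekeeping=False)
        assert (("A", "B_p"), ("A_p", "B_p")) in reaction_set(sys_)

    def test_dephosphorylation_consumes_the_phospho_form(self):
        net = make_net([("B", "A", "dephosphorylation", "activation")])
        sys_ = compile_network(net, housekeeping=False)
        assert (("A_p", "B"), ("A", "B")) in reaction_set(sys_)

    def test_transcriptional_activation_expansion(self):
        # hand enumeration: TF binding (2 slots), transcription from bound
        # DNA (1 slot), translation (1 slot)
        net = make_net([("A", "B", "transcriptional_regulation", "activation")])
        sys_ = compile_network(net, housekeeping=False)
        assert sys_.n_reactions == 3 and sys_.n_parameters == 4
        expected = {
            (("A", "DNA_B"), ("DNA_B:TF_A",)),
            (("DNA_B:TF_A",), ("DNA_B:TF_A", "RNA_B")),
            (("RNA_B",), ("B", "RNA_B")),
        }
        assert reaction_set(sys_) == expected

    def test_transcriptional_inhibition_sequesters_dna(self):
        net = make_net([("A", "B", "transcriptional_regulation", "inhibition")])
        sys_ = compile_network(net, housekeeping=False)
        expected = {
            (("A", "DNA_B"), ("DNA_B:TF_A",)),
            (("DNA_B",), ("DNA_B", "RNA_B")),   # transcription from FREE DNA
            (("RNA_B",), ("B", "RNA_B")),
        }
        assert reaction_set(sys_) == expected
        assert sys_.n_parameters == 4

    def test_unresolved_mode_is_a_hard_error_naming_the_gene(self):
        net = make_net([("B", "A", "phosphorylation", "activation")])
        modes = ActiveModeTable(modes={"B": ActiveForm.UNRESOLVED})
        with pytest.raises(CompileError, match="B"):
            compile_network(net, modes, housekeeping=False)


class TestCompile:
    def test_shared_substrate_merges_onto_one_element(self):
        # kinase and phosphatase acting on C must share a single C_p element
        net = make_net([("A", "C", "phosphorylation", "activation"),
                        ("B", "C", "dephosphorylation", "inhibition")])
        sys_ = compile_network(net, housekeeping=False)
        assert sum(el.name == "C_p" for el in sys_.elements) == 1

    def test_empty_network_is_housekeeping_only(self):
        net = make_net([], genes=["A"])
        sys_ = compile_network(net)
        assert reaction_set(sys_) == {((), ("A",)), (("A",), ())}

    def test_counts_match_hand_enumeration_one_of_each_mechanism(self):
        net = make_net([
            ("G0", "G1", "phosphorylation", "activation"),
            ("G1", "G2", "dephosphorylation", "activation"),
            ("G2", "G3", "ubiquitination", "activation"),
            ("G3", "G4", "binding", "activation"),
            ("G4", "G5", "transcriptional_regulation", "activation"),
        ])
        sys_ = compile_network(net)
        # elements: G0..G5 proteins (6), G1_p, G2_p (substrate of dephos),
        # G3_ub, G3:G4 complex, DNA_G5, DNA_G5:TF_G4, RNA_G5 -> 13
        assert sys_.n_elements == 13
        # reactions: 5 edges -> 1+1+1+1+3 = 7 core;
        # basal synthesis for G0..G4 (G5 is regulated) = 5;
        # degradation for all 11 non-DNA elements = 11
        assert sys_.n_reactions == 7 + 5 + 11
        # parameters: core 1+1+1+2+4 = 9, housekeeping 16
        assert sys_.n_parameters == 9 + 16

    def test_counts_invariant_under_edge_permutation(self):
        specs = [
            ("G0", "G1", "phosphorylation", "activation"),
            ("G1", "G2", "binding", "activation"),
            ("G2", "G0", "transcriptional_regulation", "inhibition"),
            ("G0", "G2", "ubiquitination", "activation"),
        ]
        ref = compile_network(make_net(specs))
        rng = np.random.default_rng(5)
        for _ in range(5):
            perm = list(rng.permutation(len(specs)))
            sys_ = compile_network(make_net([specs[i] for i in perm]))
            assert sys_.n_elements == ref.n_elements
            assert sys_.n_reactions == ref.n_reactions
            assert sys_.n_parameters == ref.n_parameters

    def test_deterministic_serialization(self):
        specs = [("A", "B", "phosphorylation", "activation"),
                 ("B", "C", "transcriptional_regulation", "activation")]
        a = compile_network(make_net(specs)).to_json()
        b = compile_network(make_net(specs[::-1])).to_json()
        assert a == b

    def test_every_parameter_slot_used_exactly_once(self):
        net = make_net([
            ("G0", "G1", "phosphorylation", "activation"),
            ("G1", "G2", "binding", "activation"),
            ("G2", "G0", "transcriptional_regulation", "activation"),
        ])
        sys_ = compile_network(net)
        used = []
        for r in sys_.reactions:
            used.append(r.kf_index)
            if r.kb_index is not None:
                used.append(r.kb_index)
        assert sorted(used) == list(range(sys_.n_parameters))

    def test_json_round_trip(self):
        net = make_net([("A", "B", "transcriptional_regulation", "inhibition")])
        sys_ = compile_network(net)
        again = ReactionSystem.from_json(sys_.to_json())
        assert again.to_json() == sys_.to_json()


class TestHousekeeping:
    def test_unregulated_gene_gets_synthesis_and_degradation(self):
        net = make_net([], genes=["A"])
        sys_ = compile_network(net)
        assert ((), ("A",)) in reaction_set(sys_)
        assert (("A",), ()) in reaction_set(sys_)

    def test_regulated_gene_has_no_basal_protein_synthesis(self):
        net = make_net([("A", "B", "transcriptional_regulation", "activation")])
        sys_ = compile_network(net)
        assert ((), ("B",)) not in reaction_set(sys_)
        # exactly one producer of protein B: the translation reaction
        producers = [r for r in sys_.reactions
                     if sys_.element_named("B").index in r.products
                     and sys_.element_named("B").index not in r.reactants]
        assert len(producers) == 1

    def test_complexes_are_degraded(self):
        net = make_net([("A", "B", "binding", "activation")])
        sys_ = compile_network(net)
        assert (("A:B",), ()) in reaction_set(sys_)

    def test_dna_elements_are_never_degraded(self):
        net = make_net([("A", "B", "transcriptional_regulation", "activation")])
        sys_ = compile_network(net)
        rs = reaction_set(sys_)
        assert (("DNA_B",), ()) not in rs
        assert (("DNA_B:TF_A",), ()) not in rs

    def test_measured_unregulated_rna_gets_basal_transcription(self):
        net = make_net([], genes=["A"])
        sys_ = compile_network(net, measured_rna={"A"})
        rs = reaction_set(sys_)
        assert ((), ("RNA_A",)) in rs and (("RNA_A",), ()) in rs


class TestAggregation:
    def test_protein_row_sums_all_protein_mass_forms(self):
        net = make_net([("B", "A", "phosphorylation", "activation"),
                        ("A", "B", "binding", "activation")])
        sys_ = compile_network(net)
        agg = build_aggregation(sys_, {"protein": ["A"], "phospho": ["A"],
                                       "rna": []})
        # A is present as A, A_p and the A_p:B complex (A is phospho-active)
        row = agg.C_P.toarray()[0]
        selected = {sys_.elements[i].name for i in np.flatnonzero(row)}
        assert selected == {"A", "A_p", "A_p:B"}
        ph_row = agg.C_Ph.toarray()[0]
        ph_selected = {sys_.elements[i].name for i in np.flatnonzero(ph_row)}
        assert ph_selected == {"A_p", "A_p:B"}

    def test_dna_bound_tf_counts_toward_protein_mass(self):
        net = make_net([("A", "B", "transcriptional_regulation", "activation")])
        sys_ = compile_network(net)
        agg = build_aggregation(sys_, {"protein": ["A"], "phospho": [], "rna": ["B"]})
        row = agg.C_P.toarray()[0]
        selected = {sys_.elements[i].name for i in np.flatnonzero(row)}
        assert "DNA_B:TF_A" in selected

    def test_rna_row_selects_only_the_mrna(self):
        net = make_net([("A", "B", "transcriptional_regulation", "activation")])
        sys_ = compile_network(net)
        agg = build_aggregation(sys_, {"protein": [], "phospho": [], "rna": ["B"]})
        row = agg.C_RNA.toarray()[0]
        assert {sys_.elements[i].name for i in np.flatnonzero(row)} == {"RNA_B"}

    def test_missing_biomolecule_is_a_hard_error(self):
        net = make_net([], genes=["A"])
        sys_ = compile_network(net)
        with pytest.raises(CompileError, match="rna.*A|A.*rna"):
            build_aggregation(sys_, {"protein": ["A"], "phospho": [], "rna": ["A"]})

    def test_disjoint_genes_give_block_diagonal_matrices(self):
        net = make_net([("A", "B", "binding", "activation"),
                        ("C", "D", "binding", "activation")],
                       genes=["A", "B", "C", "D"])
        sys_ = compile_network(net)
        agg = build_aggregation(
            sys_, {"protein": ["A", "B", "C", "D"], "phospho": [], "rna": []})
        C = agg.C_P.toarray()
        cols_ab = set(np.flatnonzero(C[0])) | set(np.flatnonzero(C[1]))
        cols_cd = set(np.flatnonzero(C[2])) | set(np.flatnonzero(C[3]))
        assert cols_ab.isdisjoint(cols_cd)
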