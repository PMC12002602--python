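import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oleoflux.gem_core import (
    GprParseError,
    MetabolicModel,
    Metabolite,
    ModelStructureError,
    Reaction,
    build_stoichiometric_matrix,
    gene_set,
    parse_gpr,
    slim_model,
    validate_model,
)
from oleoflux.synthetic_data import make_random_feasible_model


class TestStoichiometricMatrix:
    def test_chain_model_matrix(self, chain_model):
        smat = build_stoichiometric_matrix(chain_model)
        assert smat.shape == (2, 3)
        np.testing.assert_array_equal(
            smat.to_dense(), [[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]]
        )

    def test_empty_model(self):
        smat = build_stoichiometric_matrix(MetabolicModel())
        assert smat.shape == (0, 0)

    def test_random_model_dimensions_and_exchange_columns(self):
        model = make_random_feasible_model(20, 30, seed=1)
        smat = build_stoichiometric_matrix(model)
        assert smat.shape == (20, 30)
        dense = smat.to_dense()
        for j, rxn in enumerate(model.reactions):
            if rxn.kind in ("exchange", "demand"):
                assert np.count_nonzero(dense[:, j]) == 1

    def test_unresolved_metabolite_names_reaction(self, chain_model):
        chain_model.reactions[1].stoichiometry["ghost"] = 1.0
        with pytest.raises(ModelStructureError, match="R2"):
            build_stoichiometric_matrix(chain_model)

    def test_matrix_round_trips_stoichiometries(self, five_reaction_model):
        smat = build_stoichiometric_matrix(five_reaction_model)
        rebuilt = smat.reconstruct_stoichiometries()
        for rxn in five_reaction_model.reactions:
            assert rebuilt[rxn.id] == rxn.stoichiometry


class TestGprParsing:
    def test_and_or_tree(self):
        tree = parse_gpr("(g1 and g2) or g3")
        assert gene_set(tree) == {"g1", "g2", "g3"}
        assert tree.evaluate({"g3"})
        assert not tree.evaluate({"g1"})
        assert tree.evaluate({"g1", "g2"})

    def test_empty_expression(self):
        tree = parse_gpr("")
        assert gene_set(tree) == set()
        assert tree.evaluate(set())

    @pytest.mark.parametrize(
        "bad", ["g1 and (g2 or", "and g1", "g1 g2", "(g1))", "g1 or"]
    )
    def test_malformed_expressions_raise_with_position(self, bad):
        with pytest.raises(GprParseError, match="position"):
            parse_gpr(bad)

    def test_and_binds_tighter_than_or(self):
        tree = parse_gpr("g1 or g2 and g3")
        assert tree.evaluate({"g1"})
        assert not tree.evaluate({"g2"})

    def test_gene_set_invariant_under_distribution(self):
        factored = parse_gpr("g1 and (g2 or g3)")
        expanded = parse_gpr("(g1 and g2) or (g1 and g3)")
        assert gene_set(factored) == gene_set(expanded)
        for present in ({"g1"}, {"g1", "g2"}, {"g2", "g3"}, set()):
            assert factored.evaluate(present) == expanded.evaluate(present)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_random_trees_roundtrip_through_text(self, data):
        genes = [f"g{i}" for i in range(5)]

        def expr(depth: int) -> str:
            if depth == 0 or data.draw(st.booleans()):
                return data.draw(st.sampled_from(genes))
            op = data.draw(st.sampled_from([" and ", " or "]))
            return f"({expr(depth - 1)}{op}{expr(depth - 1)})"

        text = expr(3)
        tree = parse_gpr(text)
        present = set(data.draw(st.lists(st.sampled_from(genes), max_size=5)))
        assert parse_gpr(f"({text})").evaluate(present) == tree.evaluate(present)


class TestValidation:
    def test_chain_model_orphans(self, chain_model):
        report = validate_model(chain_model)
        # A and B each appear in two reactions: no orphans, nothing else.
        assert report.is_empty()

    def test_single_use_metabolite_is_orphan(self, chain_model):
        chain_model.metabolites.append(Metabolite("X", compartment="c"))
        chain_model.reactions.append(
            Reaction("R4", {"B": -1.0, "X": 1.0}, lower_bound=0.0)
        )
        report = validate_model(chain_model)
        assert report.orphan_metabolite_ids == ["X"]

    def test_inverted_bounds_reported(self, chain_model):
        chain_model.reactions[0].lower_bound = 5.0
        chain_model.reactions[0].upper_bound = -5.0
        assert validate_model(chain_model).invalid_bound_ids == ["R1"]

    def test_duplicate_reaction_id_is_hard_error(self):
        with pytest.raises(ModelStructureError, match="duplicate"):
            MetabolicModel(
                metabolites=[Metabolite("A")],
                reactions=[
                    Reaction("R", {"A": 1.0}),
                    Reaction("R", {"A": -1.0}),
                ],
            )


class TestSlimModel:
    def _with_dead_end(self, chain_model):
        chain_model.metabolites.append(Metabolite("D", compartment="c"))
        chain_model.reactions.append(
            Reaction("R4", {"B": -1.0, "D": 1.0}, lower_bound=0.0)
        )
        return chain_model

    def test_dead_end_removed(self, chain_model):
        slim = slim_model(self._with_dead_end(chain_model))
        assert slim.reaction_ids == ["R1", "R2", "R3"]
        assert "D" not in slim.metabolite_ids

    def test_no_orphans_is_identity(self, chain_model):
        slim = slim_model(chain_model)
        assert slim.reaction_ids == chain_model.reaction_ids
        assert slim.metabolite_ids == chain_model.metabolite_ids

    def test_cascade_reaches_fixed_point(self, chain_model):
        # B→D→C chain: removing C's dead end leaves D dead, and so on.
        chain_model.metabolites += [
            Metabolite("D", compartment="c"),
            Metabolite("C", compartment="c"),
        ]
        chain_model.reactions += [
            Reaction("R4", {"B": -1.0, "D": 1.0}, lower_bound=0.0),
            Reaction("R5", {"D": -1.0, "C": 1.0}, lower_bound=0.0),
        ]
        slim = slim_model(chain_model)
        # Fixed-point oracle: recompute participation counts exhaustively.
        counts = {m.id: 0 for m in slim.metabolites}
        for rxn in slim.reactions:
            for met in rxn.stoichiometry:
                counts[met] += 1
        assert all(c != 1 for c in counts.values())
        assert slim.reaction_ids == ["R1", "R2", "R3"]
        # Single-pass variant stops after one sweep and leaves D's dead end.
        one_pass = slim_model(chain_model, fixed_point=False)
        assert "R4" in one_pass.reaction_ids

    def test_idempotent(self, chain_model):
        model = self._with_dead_end(chain_model)
        once = slim_model(model)
        twice = slim_model(once)
        assert twice.reaction_ids == once.reaction_ids
        assert twice.metabolite_ids == once.metabolite_ids

    def test_refuses_to_remove_objective(self):
        model = MetabolicModel(
            metabolites=[Metabolite("A")],
            reactions=[Reaction("ONLY", {"A": 1.0}, kind="demand")],
            objective_reaction="ONLY",
        )
        with pytest.raises(ModelStructureError, match="objective"):
            slim_model(model)

    def test_input_model_untouched(self, chain_model):
        model = self._with_dead_end(chain_model)
        before = [r.id for r in model.reactions]
        slim_model(model)
        assert [r.id for r in model.reactions] == before
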