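import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oleoflux.fba_engine import FluxSolution
from oleoflux.model_io import PlateRow, PlateTable
from oleoflux.phenotype_screen import (
    MediumError,
    MediumSpec,
    biolog_majority_call,
    classify_reaction_activity,
    configure_medium,
    mean_active_reactions,
    screen_carbon_sources,
)
from oleoflux.synthetic_data import (
    PanelSpec,
    make_multisource_model,
    make_phenotype_panel,
)


class TestMajorityCall:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            ([True, True, False], True),
            ([True, True, True], True),
            ([True, False, False], False),
            ([False, False, False], False),
        ],
    )
    def test_two_of_three_rule(self, calls, expected):
        assert biolog_majority_call(calls) is expected

    def test_min_positive_is_configurable(self):
        assert biolog_majority_call([True, False, False], min_positive=1)

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError):
            biolog_majority_call([])


class TestConfigureMedium:
    def test_configured_carbon_source_supports_growth(self):
        model, yields = make_multisource_model(5, seed=0)
        from oleoflux.fba_engine import solve_fba

        medium = MediumSpec(free_exchange_ids=()).with_carbon("EX_src001_e")
        configured = configure_medium(model, medium)
        solution = solve_fba(configured)
        assert math.isclose(
            solution.objective_value, 10.0 * yields["src001"], rel_tol=1e-9
        )
        # Original model untouched: its exchange is still uptake-closed.
        assert model.reaction("EX_src001_e").lower_bound == 0.0

    def test_other_exchanges_are_uptake_closed(self):
        model, _ = make_multisource_model(3, seed=0)
        configured = configure_medium(
            model, MediumSpec(free_exchange_ids=()).with_carbon("EX_src001_e")
        )
        assert configured.reaction("EX_src002_e").lower_bound == 0.0
        assert configured.reaction("EX_src002_e").upper_bound > 0.0

    def test_absent_carbon_source_is_explicit_error(self):
        model, _ = make_multisource_model(3, seed=0)
        medium = MediumSpec(free_exchange_ids=()).with_carbon("EX_ghost_e")
        with pytest.raises(MediumError, match="transporter/exchange"):
            configure_medium(model, medium)

    def test_carbon_cannot_be_in_free_list(self):
        with pytest.raises(MediumError):
            MediumSpec(free_exchange_ids=("EX_x_e",)).with_carbon("EX_x_e")

    def test_closing_carbon_after_configuration_stops_growth(self):
        model, _ = make_multisource_model(3, seed=0)
        from oleoflux.fba_engine import solve_fba

        configured = configure_medium(
            model, MediumSpec(free_exchange_ids=()).with_carbon("EX_src001_e")
        )
        configured.reaction("EX_src001_e").lower_bound = 0.0
        assert abs(solve_fba(configured).objective_value) < 1e-9


class TestScreen:
    def test_planted_panel_counts_recovered(self):
        model, _ = make_multisource_model(60, seed=1)
        plate, truth = make_phenotype_panel(model, PanelSpec(seed=1))
        concordance, solutions = screen_carbon_sources(
            model, plate, MediumSpec(free_exchange_ids=())
        )
        assert concordance.counts == (41, 36, 8, 10)
        assert math.isclose(concordance.agreement_percent, 81.05, abs_tol=0.01)
        # Screen calls match the planted ground truth source by source.
        by_source = {r.source: r for r in concordance.rows}
        for source, info in truth.items():
            assert by_source[source].in_silico == info["model_growth"]

    def test_unmapped_sources_never_count_as_growth(self):
        model, _ = make_multisource_model(60, seed=1)
        plate, truth = make_phenotype_panel(model, PanelSpec(seed=1))
        concordance, solutions = screen_carbon_sources(
            model, plate, MediumSpec(free_exchange_ids=())
        )
        for row in concordance.rows:
            if truth[row.source]["exchange_id"] is None:
                assert not row.in_silico
                assert row.reason == "no_exchange"
                assert row.source not in solutions

    def test_agreement_invariant_under_row_permutation(self):
        model, _ = make_multisource_model(30, seed=3)
        spec = PanelSpec(n_sources=20, planted_counts=(8, 6, 3, 3), seed=3)
        plate, _ = make_phenotype_panel(model, spec)
        reversed_plate = PlateTable(list(reversed(plate.rows)))
        medium = MediumSpec(free_exchange_ids=())
        a, _ = screen_carbon_sources(model, plate, medium)
        b, _ = screen_carbon_sources(model, reversed_plate, medium)
        assert math.isclose(a.agreement_percent, b.agreement_percent)
        assert a.counts == b.counts

    def test_full_agreement_and_full_disagreement(self):
        model, _ = make_multisource_model(25, seed=4)
        medium = MediumSpec(free_exchange_ids=())
        perfect, _ = make_phenotype_panel(
            model, PanelSpec(n_sources=20, planted_counts=(10, 10, 0, 0), seed=4)
        )
        c, _ = screen_carbon_sources(model, perfect, medium)
        assert c.agreement_percent == 100.0
        wrong, _ = make_phenotype_panel(
            model, PanelSpec(n_sources=10, planted_counts=(0, 0, 5, 5), seed=4)
        )
        c, _ = screen_carbon_sources(model, wrong, medium)
        assert c.agreement_percent == 0.0

    def test_counts_always_sum_to_panel_size(self):
        model, _ = make_multisource_model(60, seed=1)
        plate, _ = make_phenotype_panel(model, PanelSpec(seed=1))
        concordance, _ = screen_carbon_sources(
            model, plate, MediumSpec(free_exchange_ids=())
        )
        assert sum(concordance.counts) == len(plate)

    def test_empty_plate_rejected(self):
        model, _ = make_multisource_model(3, seed=0)
        with pytest.raises(ValueError):
            screen_carbon_sources(model, PlateTable([]), MediumSpec(()))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 8),
        tn=st.integers(0, 8),
        fn=st.integers(0, 8),
        fp=st.integers(0, 8),
        seed=st.integers(0, 1000),
    )
    def test_planted_confusion_recovery_property(self, tp, tn, fn, fp, seed):
        """Any consistent planted confusion structure is recovered exactly."""
        n = tp + tn + fn + fp
        if n == 0:
            return
        model, _ = make_multisource_model(20, seed=seed)
        plate, _ = make_phenotype_panel(
            model,
            PanelSpec(n_sources=n, planted_counts=(tp, tn, fn, fp), seed=seed),
        )
        concordance, _ = screen_carbon_sources(
            model, plate, MediumSpec(free_exchange_ids=())
        )
        assert concordance.counts == (tp, tn, fn, fp)


def _solution(fluxes):
    return FluxSolution(status="optimal", objective_value=1.0, fluxes=fluxes)


class TestActivityClassification:
    def test_partition_and_boundary_conventions(self):
        n = 10
        rows = {
            "always": [1.0] * 10,
            "never": [0.0] * 10,
            # exactly 90% active: inactive fraction 10% → near-core
            "boundary_high": [1.0] * 9 + [0.0],
            # exactly 10% active → source-specific
            "boundary_low": [1.0] + [0.0] * 9,
            "middle": [1.0] * 5 + [0.0] * 5,
        }
        solutions = [
            _solution({r: vals[i] for r, vals in rows.items()}) for i in range(n)
        ]
        profile = classify_reaction_activity(solutions)
        assert profile.always_active == ["always"]
        assert profile.never_active == ["never"]
        assert set(profile.active_at_least_once) == {
            "boundary_high", "boundary_low", "middle",
        }
        assert profile.near_core == ["boundary_high"]
        assert profile.source_specific == ["boundary_low"]
        assert profile.type_associated == ["middle"]

    def test_partition_is_exhaustive_and_disjoint(self):
        from oleoflux.synthetic_data import make_activity_solutions

        solutions = make_activity_solutions(
            n_always=5, n_near_core=3, n_type_associated=4,
            n_source_specific=6, n_never=7, n_solutions=20, seed=9,
        )
        profile = classify_reaction_activity(solutions)
        n_total = len(profile.activity_fraction)
        assert (
            len(profile.always_active)
            + len(profile.active_at_least_once)
            + len(profile.never_active)
            == n_total == 25
        )
        aux = set(profile.active_at_least_once)
        assert (
            set(profile.near_core)
            | set(profile.type_associated)
            | set(profile.source_specific)
        ) == aux
        assert (
            len(profile.near_core)
            + len(profile.type_associated)
            + len(profile.source_specific)
            == len(aux)
        )

    def test_inconsistent_reaction_sets_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            classify_reaction_activity(
                [_solution({"a": 1.0}), _solution({"b": 1.0})]
            )

    def test_mean_active_reactions(self):
        s1 = _solution({"a": 1.0, "b": 1.0, "c": 1.0, "d": 0.0})
        s2 = _solution({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0, "e": 1.0})
        assert mean_active_reactions([s1, s2]) == 4.0
        assert mean_active_reactions([s1]) == 3.0

    def test_mean_active_matches_direct_recount_on_screen(self):
        model, _ = make_multisource_model(12, seed=5)
        plate, _ = make_phenotype_panel(
            model, PanelSpec(n_sources=10, planted_counts=(6, 2, 1, 1), seed=5)
        )
        _, solutions = screen_carbon_sources(
            model, plate, MediumSpec(free_exchange_ids=())
        )
        feasible = [s for s in solutions.values() if s.optimal]
        recount = [
            sum(1 for v in s.fluxes.values() if abs(v) > 1e-6) for s in feasible
        ]
        assert mean_active_reactions(feasible) == pytest.approx(
            sum(recount) / len(recount)
        )
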