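import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oleoflux.fseof_scan import (
    FseofScan,
    FseofRecord,
    aggregate_fseof,
    map_targets_to_genes,
    run_fseof,
)
from oleoflux.phenotype_screen import MediumSpec, configure_medium
from oleoflux.synthetic_data import (
    ToyCoreSpec,
    make_multisource_model,
    make_toy_core_model,
)


def _scan(model, record, **kwargs):
    return run_fseof(
        model, product_rxn=record.product_reaction, carbon_source="glc", **kwargs
    )


class TestRunFseof:
    def test_planted_slope_equals_coupling(self, product_model):
        model, record = product_model
        scan = _scan(model, record)
        slopes = {r.reaction_id: r.slope for r in scan.records}
        assert math.isclose(slopes["CARBOXYLASE"], record.planted_slope,
                            abs_tol=1e-6)

    def test_product_demand_slope_is_one(self, product_model):
        model, record = product_model
        scan = _scan(model, record)
        slopes = {r.reaction_id: r.slope for r in scan.records}
        assert math.isclose(slopes["DM_product_c"], 1.0, abs_tol=1e-6)

    def test_step_fluxes_match_independent_per_step_solves(self, product_model):
        """Step-by-step LP oracle: re-solve each enforcement level directly."""
        from oleoflux.fba_engine import solve_pfba

        model, record = product_model
        scan = _scan(model, record)
        planted = next(
            r for r in scan.records if r.reaction_id == "CARBOXYLASE"
        )
        for level, flux in planted.step_fluxes:
            stepped = model.copy()
            stepped.reaction(record.product_reaction).lower_bound = level
            oracle = solve_pfba(stepped)
            assert math.isclose(
                flux, abs(oracle.fluxes["CARBOXYLASE"]), abs_tol=1e-6
            )

    def test_inactive_reactions_excluded(self, product_model):
        model, record = product_model
        # ROUTE_1 (the poor-yield route) never carries parsimonious flux.
        scan = _scan(model, record)
        assert "ROUTE_1" not in scan.reported_reactions

    def test_biomass_trajectory_non_increasing(self, product_model):
        model, record = product_model
        scan = _scan(model, record)
        diffs = [
            b - a for a, b in zip(scan.biomass_trajectory,
                                  scan.biomass_trajectory[1:])
        ]
        assert all(d <= 1e-6 for d in diffs)

    def test_level_zero_reproduces_unconstrained_solution(self, product_model):
        from oleoflux.fba_engine import solve_pfba

        model, record = product_model
        scan = _scan(model, record)
        assert scan.enforced_levels[0] == pytest.approx(0.0, abs=1e-9)
        base = solve_pfba(model)
        assert scan.biomass_trajectory[0] == pytest.approx(
            base.objective_value, abs=1e-6
        )

    def test_unreachable_product_reports_reason(self):
        model, record = make_toy_core_model(
            ToyCoreSpec(include_product_branch=True)
        )
        model.reaction("PRODUCT_SYNTH").upper_bound = 0.0
        scan = _scan(model, record)
        assert scan.records == []
        assert "unreachable" in scan.reason

    def test_non_growing_medium_reports_reason(self, product_model):
        model, record = product_model
        model.reaction("EX_glc_e").lower_bound = 0.0
        scan = _scan(model, record)
        assert "does not grow" in scan.reason

    @pytest.mark.parametrize("coupling", [0.5, 1.0, 2.0, 5.0])
    def test_slope_recovery_across_couplings(self, coupling):
        model, record = make_toy_core_model(
            ToyCoreSpec(include_product_branch=True, coupling=coupling)
        )
        scan = _scan(model, record)
        slopes = {r.reaction_id: r.slope for r in scan.records}
        assert math.isclose(slopes["CARBOXYLASE"], coupling, abs_tol=1e-6)
        assert math.isclose(slopes["DM_product_c"], 1.0, abs_tol=1e-6)

    def test_endpoint_slope_agrees_on_linear_response(self, product_model):
        model, record = product_model
        regression = _scan(model, record)
        endpoint = _scan(model, record, slope_method="endpoint")
        s1 = {r.reaction_id: r.slope for r in regression.records}
        s2 = {r.reaction_id: r.slope for r in endpoint.records}
        for rxn in s1:
            assert math.isclose(s1[rxn], s2[rxn], abs_tol=1e-6)


def _mk_scan(source, slopes):
    records = [
        FseofRecord(source, rxn, slope, [], True)
        for rxn, slope in slopes.items()
    ]
    return FseofScan(source, records, [0, 1], [1, 0.5], 1.0)


class TestAggregation:
    def test_retention_filters(self):
        scans = [
            _mk_scan(f"s{i}", {"keep": 2.5, "low_slope": 1.5}) for i in range(6)
        ] + [_mk_scan(f"t{i}", {"few_sources": 10.0}) for i in range(4)]
        targets = aggregate_fseof(scans, min_sources=5, slope_threshold=2.0)
        assert targets.retained == ["keep"]
        assert targets.n_sources_reported("keep") == 6
        # Sub-threshold reports stay in the slope matrix for the heatmap.
        assert "low_slope" in targets.slopes
        assert "few_sources" in targets.slopes

    def test_slope_exactly_at_threshold_is_dropped(self):
        scans = [_mk_scan(f"s{i}", {"edge": 2.0}) for i in range(8)]
        assert aggregate_fseof(scans).retained == []

    def test_order_invariance_and_idempotence(self):
        scans = [
            _mk_scan(f"s{i}", {"a": 3.0, "b": 2.5 + 0.1 * i}) for i in range(7)
        ]
        forward = aggregate_fseof(scans)
        backward = aggregate_fseof(list(reversed(scans)))
        assert forward.retained == backward.retained
        assert forward.slopes == backward.slopes

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        min_sources=st.integers(1, 8),
        threshold=st.floats(0.5, 5.0),
        stricter_sources=st.integers(0, 3),
        stricter_slope=st.floats(0.0, 2.0),
    )
    def test_filter_monotonicity(
        self, min_sources, threshold, stricter_sources, stricter_slope
    ):
        """Raising either filter never grows the retained set."""
        scans = [
            _mk_scan(
                f"s{i}",
                {f"r{j}": 0.5 * i + 0.7 * j for j in range(5)},
            )
            for i in range(8)
        ]
        loose = set(aggregate_fseof(scans, min_sources, threshold).retained)
        strict = set(
            aggregate_fseof(
                scans,
                min_sources + stricter_sources,
                threshold + stricter_slope,
            ).retained
        )
        assert strict <= loose

    def test_multisource_planted_target_retained(self):
        model, _ = make_multisource_model(
            6, seed=7, include_product_branch=True, coupling=5.0
        )
        medium = MediumSpec(free_exchange_ids=())
        scans = []
        for i in range(1, 7):
            configured = configure_medium(
                model, medium.with_carbon(f"EX_src{i:03d}_e")
            )
            scan = run_fseof(
                configured, product_rxn="DM_product_c",
                carbon_source=f"src{i:03d}",
            )
            assert not scan.reason
            scans.append(scan)
        targets = aggregate_fseof(scans, min_sources=5, slope_threshold=2.0)
        assert targets.retained == ["CARBOXYLASE"]
        assert targets.n_sources_reported("CARBOXYLASE") == 6
        # PRODUCT_SYNTH has slope 1 in every medium: reported, not retained.
        assert "PRODUCT_SYNTH" in targets.slopes
        assert "PRODUCT_SYNTH" not in targets.retained


class TestGeneMapping:
    def test_gene_union(self, product_model):
        model, _ = product_model
        scans = [_mk_scan(f"s{i}", {"CARBOXYLASE": 3.0, "PRODUCT_SYNTH": 2.5})
                 for i in range(5)]
        targets = map_targets_to_genes(aggregate_fseof(scans), model)
        assert targets.gene_set == {"gACC1", "gACC2", "gFAS1"}
        assert targets.orphan_reactions == []

    def test_orphan_gpr_reaction_listed_separately(self, product_model):
        model, _ = product_model
        scans = [_mk_scan(f"s{i}", {"CARBOXYLASE": 3.0, "DM_product_c": 2.5})
                 for i in range(5)]
        targets = map_targets_to_genes(aggregate_fseof(scans), model)
        assert targets.orphan_reactions == ["DM_product_c"]
        assert targets.gene_set == {"gACC1", "gACC2"}

    def test_gene_count_matches_brute_force_union(self, product_model):
        model, _ = product_model
        from oleoflux.gem_core import gene_set

        scans = [
            _mk_scan(f"s{i}", {r.id: 3.0 for r in model.reactions})
            for i in range(5)
        ]
        targets = map_targets_to_genes(aggregate_fseof(scans), model)
        brute = set()
        for rxn_id in targets.retained:
            brute |= gene_set(model.reaction(rxn_id).gpr)
        assert targets.gene_set == brute
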