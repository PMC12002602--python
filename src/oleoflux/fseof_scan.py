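"""Flux Scanning based on Enforced Objective Flux (FSEOF).

FSEOF looks for amplification targets for a product of interest: the
product's flux is enforced in steps from its baseline up to a fraction of
its theoretical maximum while biomass remains the optimisation objective,
and reactions whose flux rises consistently with the enforced product flux
are candidate up-regulation targets.  A per-reaction *slope* (flux change
per unit enforced product flux) quantifies the co-upregulation; scanning is
repeated over many single-carbon-source media and targets reported in
enough independent scans with a large enough slope are retained and mapped
to genes through their GPR rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fba_engine import (
    ACTIVITY_EPSILON,
    GROWTH_THRESHOLD,
    solve_fba,
    solve_pfba,
)
from .gem_core import MetabolicModel, gene_set

__all__ = [
    "FseofRecord",
    "FseofScan",
    "FseofTargetSet",
    "run_fseof",
    "aggregate_fseof",
    "map_targets_to_genes",
]


@dataclass
class FseofRecord:
    """One reaction's response to enforced product flux on one carbon source."""

    carbon_source: str
    reaction_id: str
    slope: float
    step_fluxes: list[tuple[float, float]]
    monotone_increasing: bool


@dataclass
class FseofScan:
    """Full result of one per-carbon-source scan."""

    carbon_source: str
    records: list[FseofRecord]
    enforced_levels: list[float]
    biomass_trajectory: list[float]
    product_max: float
    sign_changing: list[str] = field(default_factory=list)
    reason: str = ""

    @property
    def reported_reactions(self) -> set[str]:
        return {r.reaction_id for r in self.records}


def _slope(levels: np.ndarray, fluxes: np.ndarray, method: str) -> float:
    if method == "endpoint":
        span = levels[-1] - levels[0]
        return float((fluxes[-1] - fluxes[0]) / span) if span > 0 else 0.0
    # Least-squares regression of |flux| on the enforced level; robust to
    # single-step degeneracy compared with the endpoint formula.
    if len(levels) < 2 or np.ptp(levels) == 0:
        return 0.0
    return float(np.polyfit(levels, fluxes, 1)[0])


#: Slopes below this magnitude are numerical noise on a constant flux
#: (solver feasibility tolerances leak into the per-step fluxes).
_SLOPE_TOL = 1e-6


def run_fseof(
    model: MetabolicModel,
    product_rxn: str,
    biomass_rxn: str | None = None,
    n_steps: int = 10,
    max_fraction: float = 0.9,
    carbon_source: str = "",
    slope_method: str = "regression",
    growth_threshold: float = GROWTH_THRESHOLD,
    activity_epsilon: float = ACTIVITY_EPSILON,
) -> FseofScan:
    """Scan reaction fluxes while stepping up the enforced product flux.

    The model must already be medium-configured and able to grow.  The
    enforced levels are ``n_steps`` evenly spaced values from the baseline
    product flux (at the unconstrained biomass optimum) up to
    ``max_fraction`` of the product's theoretical maximum; stopping short of
    the maximum avoids the typically infeasible extreme vertex.  At each
    level the product's lower bound is pinned, biomass is maximised, and
    the parsimonious flux distribution recorded.

    A reaction is reported when its |flux|-vs-level slope is positive and
    its |flux| is non-decreasing (within ``activity_epsilon``) across the
    levels; reactions whose flux changes sign across levels are excluded
    from the records and listed in ``sign_changing`` — "flux increases" is
    ill-defined across a direction reversal.
    """
    biomass_rxn = biomass_rxn or model.objective_reaction
    for rxn_id in (biomass_rxn, product_rxn):
        if not model.has_reaction(rxn_id):
            raise KeyError(f"reaction {rxn_id!r} not in model")
    if slope_method not in ("regression", "endpoint"):
        raise ValueError(f"unknown slope method {slope_method!r}")

    base = solve_pfba(model, biomass_rxn)
    if not base.optimal or base.objective_value <= growth_threshold:
        return FseofScan(
            carbon_source, [], [], [], 0.0, reason="model does not grow on this medium"
        )
    baseline_product = base.flux(product_rxn)

    vmax = solve_fba(model, product_rxn, sense="max")
    if not vmax.optimal or vmax.objective_value <= activity_epsilon:
        return FseofScan(
            carbon_source,
            [],
            [],
            [],
            vmax.objective_value if vmax.optimal else 0.0,
            reason="product unreachable on this medium",
        )
    product_max = vmax.objective_value

    levels = np.linspace(baseline_product, max_fraction * product_max, n_steps)
    kept_levels: list[float] = []
    biomass_traj: list[float] = []
    flux_rows: list[dict[str, float]] = []
    for level in levels:
        stepped = model.copy()
        prod = stepped.reaction(product_rxn)
        prod.lower_bound = float(level)
        if prod.upper_bound < level:
            prod.upper_bound = float(level)
        solution = solve_pfba(stepped, biomass_rxn)
        if not solution.optimal:
            warnings.warn(
                f"FSEOF step at enforced level {level:.6g} infeasible; dropped",
                stacklevel=2,
            )
            continue
        kept_levels.append(float(level))
        biomass_traj.append(solution.objective_value)
        flux_rows.append(solution.fluxes)

    if len(kept_levels) < 2:
        return FseofScan(
            carbon_source,
            [],
            kept_levels,
            biomass_traj,
            product_max,
            reason="fewer than two feasible enforcement steps",
        )

    # Biomass must trade off against the product: non-increasing objective.
    diffs = np.diff(biomass_traj)
    if np.any(diffs > 1e-6 * max(1.0, biomass_traj[0])):
        raise RuntimeError(
            "biomass objective increased along the enforcement grid; "
            "scan is inconsistent"
        )

    level_arr = np.array(kept_levels)
    records: list[FseofRecord] = []
    sign_changing: list[str] = []
    for rxn in model.reaction_ids:
        values = np.array([row[rxn] for row in flux_rows])
        has_pos = np.any(values > activity_epsilon)
        has_neg = np.any(values < -activity_epsilon)
        if has_pos and has_neg:
            sign_changing.append(rxn)
            continue
        magnitudes = np.abs(values)
        if np.all(magnitudes <= activity_epsilon):
            continue  # never active at any level
        slope = _slope(level_arr, magnitudes, slope_method)
        if abs(slope) <= _SLOPE_TOL:
            slope = 0.0
        monotone = bool(np.all(np.diff(magnitudes) >= -activity_epsilon))
        if slope > 0 and monotone:
            records.append(
                FseofRecord(
                    carbon_source=carbon_source,
                    reaction_id=rxn,
                    slope=slope,
                    step_fluxes=list(zip(kept_levels, magnitudes.tolist())),
                    monotone_increasing=monotone,
                )
            )
    return FseofScan(
        carbon_source,
        records,
        kept_levels,
        biomass_traj,
        product_max,
        sign_changing=sign_changing,
    )


@dataclass
class FseofTargetSet:
    """Reactions retained across carbon sources, with filter provenance."""

    slopes: dict[str, dict[str, float]]  # reaction -> source -> slope
    retained: list[str]
    min_sources: int
    slope_threshold: float
    genes_by_reaction: dict[str, set[str]] = field(default_factory=dict)
    orphan_reactions: list[str] = field(default_factory=list)

    @property
    def gene_set(self) -> set[str]:
        out: set[str] = set()
        for genes in self.genes_by_reaction.values():
            out |= genes
        return out

    def n_sources_reported(self, reaction_id: str) -> int:
        return sum(
            1
            for slope in self.slopes.get(reaction_id, {}).values()
            if slope > self.slope_threshold
        )

    def long_table(self) -> pd.DataFrame:
        """Heatmap-ready long format: reaction × carbon source → slope."""
        rows = [
            {"reaction": rxn, "carbon_source": src, "slope": slope}
            for rxn, by_source in sorted(self.slopes.items())
            for src, slope in sorted(by_source.items())
        ]
        return pd.DataFrame(rows, columns=["reaction", "carbon_source", "slope"])

    def target_table(self) -> pd.DataFrame:
        rows = []
        for rxn in sorted(self.retained):
            genes = sorted(self.genes_by_reaction.get(rxn, set()))
            slopes = self.slopes[rxn]
            rows.append(
                {
                    "reaction": rxn,
                    "n_sources": self.n_sources_reported(rxn),
                    "mean_slope": float(np.mean(list(slopes.values()))),
                    "max_slope": float(max(slopes.values())),
                    "genes": ";".join(genes),
                    "orphan_gpr": rxn in self.orphan_reactions,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "reaction",
                "n_sources",
                "mean_slope",
                "max_slope",
                "genes",
                "orphan_gpr",
            ],
        )


def aggregate_fseof(
    scans: list[FseofScan],
    min_sources: int = 5,
    slope_threshold: float = 2.0,
) -> FseofTargetSet:
    """Pool per-source scans and retain robust targets.

    A reaction is retained iff it is reported with slope above
    ``slope_threshold`` in at least ``min_sources`` independent
    carbon-source scans.  The full slope matrix (including sub-threshold
    reports) is kept for heatmap-style output; aggregation is idempotent
    and invariant to the order of the scans.
    """
    if not scans:
        raise ValueError("at least one scan is required")
    slopes: dict[str, dict[str, float]] = {}
    for scan in scans:
        for record in scan.records:
            slopes.setdefault(record.reaction_id, {})[
                scan.carbon_source
            ] = record.slope
    retained = sorted(
        rxn
        for rxn, by_source in slopes.items()
        if sum(1 for s in by_source.values() if s > slope_threshold)
        >= min_sources
    )
    return FseofTargetSet(
        slopes=slopes,
        retained=retained,
        min_sources=min_sources,
        slope_threshold=slope_threshold,
    )


def map_targets_to_genes(
    targets: FseofTargetSet, model: MetabolicModel
) -> FseofTargetSet:
    """Attach GPR-derived gene sets to the retained reactions.

    Reactions with an empty GPR are flagged as orphans (no gene annotation,
    e.g. manually added transport steps) and listed separately; they never
    contribute to the pooled gene set.
    """
    genes_by_reaction: dict[str, set[str]] = {}
    orphans: list[str] = []
    for rxn_id in targets.retained:
        genes = gene_set(model.reaction(rxn_id).gpr)
        genes_by_reaction[rxn_id] = genes
        if not genes:
            orphans.append(rxn_id)
    targets.genes_by_reaction = genes_by_reaction
    targets.orphan_reactions = orphans
    return targets
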