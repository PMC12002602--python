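"""Carbon-source utilisation screening and reaction-activity classification.

The screen mirrors a standard minimal-medium phenotype-array validation of a
genome-scale model: every plate compound is mapped to its exchange reaction,
the minimal medium is configured (a fixed list of freely exchanged
inorganic compounds plus one carbon source at a bounded uptake), growth is
predicted by parsimonious FBA, and the in-silico call is compared with the
majority call over plate replicates.  Compounds with no exchange reaction in
the model are structural no-growth predictions (missing transporter or
extracellular degradation), recorded with a machine-readable reason rather
than raised as errors.

Feasible per-source flux distributions are pooled into an activity profile:
reactions active in every solution (core), never active, or active at least
once but not always (the auxiliary set).  The auxiliary set is subdivided at
10%/90% activity thresholds into near-core, carbon-source-type-associated
and source-specific reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .fba_engine import (
    ACTIVITY_EPSILON,
    GROWTH_THRESHOLD,
    FluxSolution,
    growth_call,
    solve_fba,
    solve_pfba,
)
from .gem_core import DEFAULT_BOUND, MetabolicModel
from .model_io import PlateTable

__all__ = [
    "MediumSpec",
    "MediumError",
    "SourceResult",
    "ConcordanceResult",
    "ActivityProfile",
    "DEFAULT_FREE_EXCHANGES",
    "NO_EXCHANGE",
    "biolog_majority_call",
    "configure_medium",
    "screen_carbon_sources",
    "classify_reaction_activity",
    "mean_active_reactions",
    "default_source_to_exchange",
]

#: Minimal-medium compounds whose exchanges are left unconstrained:
#: phosphate, sulphite, sulphate, ammonium, plus CO2, O2, water and protons.
DEFAULT_FREE_EXCHANGES = (
    "EX_pi_e",
    "EX_so3_e",
    "EX_so4_e",
    "EX_nh4_e",
    "EX_co2_e",
    "EX_o2_e",
    "EX_h2o_e",
    "EX_h_e",
)

#: Reason code for plate compounds with no exchange reaction in the model.
NO_EXCHANGE = "no_exchange"


class MediumError(ValueError):
    """Medium references a reaction the model does not have."""


@dataclass
class MediumSpec:
    """Minimal-medium configuration for one growth simulation.

    ``free_exchange_ids`` are opened for both uptake and secretion; the
    carbon exchange is uptake-bounded at ``carbon_uptake_bound``
    (mmol·gDW⁻¹·h⁻¹); every other exchange is closed for uptake but left
    open for secretion.
    """

    free_exchange_ids: tuple[str, ...] = DEFAULT_FREE_EXCHANGES
    carbon_exchange_id: str | None = None
    carbon_uptake_bound: float = 10.0

    def with_carbon(self, exchange_id: str) -> "MediumSpec":
        if exchange_id in self.free_exchange_ids:
            raise MediumError(
                f"carbon source {exchange_id!r} is already a free exchange"
            )
        return MediumSpec(
            self.free_exchange_ids, exchange_id, self.carbon_uptake_bound
        )


def biolog_majority_call(
    replicate_calls: list[bool], min_positive: int = 2
) -> bool:
    """Majority rule over plate replicates (default: two of three)."""
    if not replicate_calls:
        raise ValueError("at least one replicate call is required")
    return sum(bool(c) for c in replicate_calls) >= min_positive


def configure_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a copy of the model with exchange bounds set to the medium.

    Raises :class:`MediumError` if any free id or the carbon id does not
    resolve to an exchange/demand reaction — for carbon sources this mirrors
    the missing-transporter diagnosis for plate compounds absent from the
    network.
    """
    configured = model.copy()
    exchange_ids = {r.id for r in configured.exchanges()}
    for rxn_id in medium.free_exchange_ids:
        if rxn_id not in exchange_ids:
            raise MediumError(f"free medium exchange {rxn_id!r} not in model")
    if medium.carbon_exchange_id is not None:
        if medium.carbon_exchange_id not in exchange_ids:
            raise MediumError(
                f"carbon source {medium.carbon_exchange_id!r} has no "
                "transporter/exchange reaction in the model"
            )
    free = set(medium.free_exchange_ids)
    for rxn in configured.reactions:
        if rxn.kind not in ("exchange", "demand"):
            continue
        if rxn.id in free:
            rxn.lower_bound = -DEFAULT_BOUND
        elif rxn.id == medium.carbon_exchange_id:
            rxn.lower_bound = -abs(medium.carbon_uptake_bound)
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)  # uptake closed
        rxn.upper_bound = max(rxn.upper_bound, 0.0)  # secretion stays open
    return configured


def default_source_to_exchange(source: str) -> str:
    """Default plate-compound → exchange-id mapping (``EX_<source>_e``)."""
    return f"EX_{source}_e"


@dataclass
class SourceResult:
    source: str
    substrate_class: str
    in_vitro: bool
    in_silico: bool
    reason: str = ""


@dataclass
class ConcordanceResult:
    """Per-source growth calls and the 2×2 confusion summary."""

    rows: list[SourceResult] = field(default_factory=list)

    @property
    def both_growth(self) -> int:
        return sum(1 for r in self.rows if r.in_vitro and r.in_silico)

    @property
    def both_no_growth(self) -> int:
        return sum(1 for r in self.rows if not r.in_vitro and not r.in_silico)

    @property
    def false_no_growth(self) -> int:
        """In vitro growth the model misses."""
        return sum(1 for r in self.rows if r.in_vitro and not r.in_silico)

    @property
    def false_growth(self) -> int:
        """In silico growth the plate contradicts."""
        return sum(1 for r in self.rows if not r.in_vitro and r.in_silico)

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (
            self.both_growth,
            self.both_no_growth,
            self.false_no_growth,
            self.false_growth,
        )

    @property
    def agreement_percent(self) -> float:
        if not self.rows:
            raise ValueError("concordance over an empty screen")
        return 100.0 * (self.both_growth + self.both_no_growth) / len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": r.source,
                    "class": r.substrate_class,
                    "in_vitro": r.in_vitro,
                    "in_silico": r.in_silico,
                    "reason": r.reason,
                }
                for r in self.rows
            ]
        )


def screen_carbon_sources(
    model: MetabolicModel,
    plate: PlateTable,
    medium_template: MediumSpec | None = None,
    growth_threshold: float = GROWTH_THRESHOLD,
    min_positive: int = 2,
    source_to_exchange=default_source_to_exchange,
    use_pfba: bool = True,
) -> tuple[ConcordanceResult, dict[str, FluxSolution]]:
    """Screen every plate compound as sole carbon source on minimal medium.

    Returns the concordance summary and the per-source flux solutions for
    sources that had an exchange reaction (feasible or not).  Sources
    without a mapped exchange are recorded as in-silico no-growth with the
    :data:`NO_EXCHANGE` reason and contribute no flux solution.
    """
    if len(plate) == 0:
        raise ValueError("empty plate")
    medium_template = medium_template or MediumSpec()
    exchange_ids = {r.id for r in model.exchanges()}

    rows: list[SourceResult] = []
    solutions: dict[str, FluxSolution] = {}
    for plate_row in plate.rows:
        in_vitro = biolog_majority_call(plate_row.replicate_calls, min_positive)
        exchange_id = source_to_exchange(plate_row.source)
        if exchange_id not in exchange_ids:
            rows.append(
                SourceResult(
                    plate_row.source,
                    plate_row.substrate_class,
                    in_vitro,
                    False,
                    reason=NO_EXCHANGE,
                )
            )
            continue
        medium = medium_template.with_carbon(exchange_id)
        configured = configure_medium(model, medium)
        solve = solve_pfba if use_pfba else solve_fba
        solution = solve(configured)
        solutions[plate_row.source] = solution
        grows = growth_call(solution, growth_threshold)
        rows.append(
            SourceResult(
                plate_row.source,
                plate_row.substrate_class,
                in_vitro,
                grows,
                reason="" if grows else "no_feasible_growth",
            )
        )
    return ConcordanceResult(rows), solutions


# ---------------------------------------------------------------------------
# Reaction-activity classification
# ---------------------------------------------------------------------------


@dataclass
class ActivityProfile:
    """Activity fractions across pooled solutions and their partition.

    ``always_active`` + ``active_at_least_once`` + ``never_active``
    partition the reaction set; the auxiliary subdivision (near-core /
    type-associated / source-specific) partitions ``active_at_least_once``.
    """

    activity_fraction: dict[str, float]
    n_solutions: int
    always_active: list[str]
    active_at_least_once: list[str]
    never_active: list[str]
    near_core: list[str]
    type_associated: list[str]
    source_specific: list[str]
    thresholds: tuple[float, float] = (0.10, 0.90)

    @property
    def auxiliary_shares(self) -> tuple[float, float, float]:
        """Percent of the auxiliary set in each subdivision."""
        n_aux = len(self.active_at_least_once)
        if n_aux == 0:
            return (0.0, 0.0, 0.0)
        return (
            100.0 * len(self.near_core) / n_aux,
            100.0 * len(self.type_associated) / n_aux,
            100.0 * len(self.source_specific) / n_aux,
        )

    def to_dataframe(self) -> pd.DataFrame:
        klass = {}
        for name, members in (
            ("always_active", self.always_active),
            ("near_core", self.near_core),
            ("type_associated", self.type_associated),
            ("source_specific", self.source_specific),
            ("never_active", self.never_active),
        ):
            for rxn in members:
                klass[rxn] = name
        return pd.DataFrame(
            {
                "reaction": list(self.activity_fraction),
                "activity_fraction": list(self.activity_fraction.values()),
                "class": [klass[r] for r in self.activity_fraction],
            }
        )


def classify_reaction_activity(
    solutions: list[FluxSolution],
    thresholds: tuple[float, float] = (0.10, 0.90),
    activity_epsilon: float = ACTIVITY_EPSILON,
) -> ActivityProfile:
    """Pool solutions and partition reactions by how often they carry flux.

    Activity fraction is the share of solutions with |flux| above
    ``activity_epsilon``.  Reactions active in every solution are core
    (``always_active``); never active reactions are ``never_active``; the
    rest are the auxiliary set, subdivided at the (low, high) thresholds:
    near-core reactions are inactive in at most ``1 − high`` of... precisely,
    near-core: inactive fraction ≤ (1 − high) equivalent to activity ≥ high;
    source-specific: activity ≤ low; remainder type-associated.  Both
    boundary comparisons are inclusive, near-core evaluated first, so the
    three classes always partition the auxiliary set.
    """
    if not solutions:
        raise ValueError("at least one solution is required")
    reaction_ids = list(solutions[0].fluxes)
    key = set(reaction_ids)
    for s in solutions[1:]:
        if set(s.fluxes) != key:
            raise ValueError("solutions cover inconsistent reaction sets")

    low, high = thresholds
    n = len(solutions)
    fraction: dict[str, float] = {}
    for rxn in reaction_ids:
        active = sum(1 for s in solutions if abs(s.fluxes[rxn]) > activity_epsilon)
        fraction[rxn] = active / n

    always = [r for r, f in fraction.items() if f == 1.0]
    never = [r for r, f in fraction.items() if f == 0.0]
    auxiliary = [r for r, f in fraction.items() if 0.0 < f < 1.0]

    near_core = [r for r in auxiliary if fraction[r] >= high]
    remaining = [r for r in auxiliary if r not in set(near_core)]
    source_specific = [r for r in remaining if fraction[r] <= low]
    type_associated = [r for r in remaining if r not in set(source_specific)]

    return ActivityProfile(
        activity_fraction=fraction,
        n_solutions=n,
        always_active=always,
        active_at_least_once=auxiliary,
        never_active=never,
        near_core=near_core,
        type_associated=type_associated,
        source_specific=source_specific,
        thresholds=thresholds,
    )


def mean_active_reactions(solutions: list[FluxSolution]) -> float:
    """Arithmetic mean of the active-set size across solutions."""
    if not solutions:
        raise ValueError("at least one solution is required")
    return sum(len(s.active_set) for s in solutions) / len(solutions)
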