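"""Assemble a biomass reaction from a macromolecular composition table.

A biomass reaction drains precursor metabolites in experimentally derived
proportions so that one flux unit builds exactly one gram of dry weight.
Given mass fractions f_macro (share of dry weight per macromolecule pool),
within-pool fractions f_comp and residue molecular weights MW (g·mol⁻¹),
the drain coefficient of each component is

    coefficient = 1000 · f_macro · f_comp / MW   [mmol·gDW⁻¹, consumed]

which makes Σ |coefficient| · MW = 1000 mg·gDW⁻¹ — the mass-balance
invariant checked by :meth:`BiomassReaction.mass_mg`.  Growth-associated
maintenance (GAM) adds ATP + H₂O → ADP + Pi + H⁺ at a configurable rate in
mmol ATP per gram of biomass formed; by default it lives inside the
biomass equation (a flag externalises it as a separate drain).

Residue weights are caller-supplied data; the package ships a reference
table (:mod:`oleoflux.composition_data`) but treats it as data, not truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .composition_data import (
    DEFAULT_GAM_ATP,
    REFERENCE_RESIDUE_WEIGHTS,
    UMBELOPSIS_COMPOSITION,
)
from .gem_core import Reaction

__all__ = [
    "BiomassComposition",
    "BiomassReaction",
    "CompositionReport",
    "validate_composition",
    "compose_biomass",
    "load_composition",
    "umbelopsis_composition",
]

#: Tolerance on fraction sums in strict validation.
SUM_TOLERANCE = 1e-9

GAM_STOICHIOMETRY = {
    "atp_c": -1.0,
    "h2o_c": -1.0,
    "adp_c": 1.0,
    "pi_c": 1.0,
    "h_c": 1.0,
}


@dataclass
class BiomassComposition:
    """Two-level mass-fraction table plus residue weights and GAM.

    ``macromolecules`` are fractions of dry weight (should sum to 1);
    ``components[macro]`` are within-pool fractions (each should sum
    to 1); ``molecular_weights`` are residue weights in g·mol⁻¹;
    ``gam_atp`` is in mmol ATP per gDW.
    """

    macromolecules: dict[str, float]
    components: dict[str, dict[str, float]]
    molecular_weights: dict[str, float]
    gam_atp: float = DEFAULT_GAM_ATP

    def __post_init__(self) -> None:
        if self.gam_atp < 0:
            raise ValueError("gam_atp must be non-negative")
        for comp, mw in self.molecular_weights.items():
            if mw <= 0:
                raise ValueError(f"molecular weight of {comp!r} must be positive")
        for macro in self.macromolecules:
            if macro not in self.components:
                raise ValueError(f"no component breakdown for {macro!r}")


@dataclass
class CompositionReport:
    """Fraction-sum violations; empty report = composition is exact."""

    findings: list[tuple[str, float]] = field(default_factory=list)

    def add(self, where: str, residual: float) -> None:
        self.findings.append((where, residual))

    def is_empty(self) -> bool:
        return not self.findings


def validate_composition(
    composition: BiomassComposition, tolerance: float = SUM_TOLERANCE
) -> CompositionReport:
    """List every fraction sum that misses 1 by more than ``tolerance``.

    Findings name the offending class and carry the signed residual
    (sum − 1); findings are data, not errors.
    """
    report = CompositionReport()
    macro_sum = sum(composition.macromolecules.values())
    if abs(macro_sum - 1.0) > tolerance:
        report.add("macromolecules", macro_sum - 1.0)
    for macro, breakdown in composition.components.items():
        class_sum = sum(breakdown.values())
        if abs(class_sum - 1.0) > tolerance:
            report.add(macro, class_sum - 1.0)
    return report


@dataclass
class BiomassReaction:
    """Drain coefficients (mmol·gDW⁻¹, negative = consumed) plus GAM."""

    coefficients: dict[str, float]
    gam_atp: float
    gam_metabolites: dict[str, float] = field(default_factory=dict)
    molecular_weights: dict[str, float] = field(default_factory=dict)

    def mass_mg(self) -> float:
        """Σ |coefficient|·MW over precursor components (target: 1000 mg)."""
        return sum(
            abs(coef) * self.molecular_weights[comp]
            for comp, coef in self.coefficients.items()
        )

    def to_reaction(
        self, reaction_id: str = "BIOMASS", component_to_metabolite=None
    ) -> Reaction:
        """Render as a model reaction, mapping components to metabolite ids.

        ``component_to_metabolite`` defaults to ``<component>_c``; lipid
        classes and other lumped pools should be mapped to representative
        species by the caller — the package does not invent acyl-chain
        distributions.
        """
        mapper = component_to_metabolite or (lambda comp: f"{comp}_c")
        stoich: dict[str, float] = {}
        for comp, coef in self.coefficients.items():
            met = mapper(comp)
            stoich[met] = stoich.get(met, 0.0) + coef
        for met, coef in self.gam_metabolites.items():
            stoich[met] = stoich.get(met, 0.0) + coef
        return Reaction(
            id=reaction_id, stoichiometry=stoich, lower_bound=0.0, kind="biomass"
        )


def compose_biomass(
    composition: BiomassComposition,
    renormalise: bool = True,
    gam_in_biomass: bool = True,
) -> BiomassReaction:
    """Turn a composition table into drain coefficients.

    With ``renormalise=True`` (default) each fraction family is rescaled to
    sum exactly to 1 first — the output then equals composing the
    exactly-normalised composition — and any residual above the strict
    tolerance is logged as a warning.  With ``renormalise=False`` a
    composition failing strict validation is rejected.

    ``gam_in_biomass=False`` leaves ``gam_metabolites`` empty so the
    maintenance drain can be externalised as its own pseudo-reaction.
    """
    report = validate_composition(composition)
    if not report.is_empty():
        if not renormalise:
            details = ", ".join(
                f"{where}: residual {residual:+.4g}"
                for where, residual in report.findings
            )
            raise ValueError(
                f"composition fails strict validation ({details}); "
                "pass renormalise=True to rescale"
            )
        warnings.warn(
            "composition fractions renormalised: "
            + ", ".join(
                f"{where} summed to {1 + residual:.6g}"
                for where, residual in report.findings
            ),
            stacklevel=2,
        )

    macro_sum = sum(composition.macromolecules.values())
    coefficients: dict[str, float] = {}
    for macro, f_macro in composition.macromolecules.items():
        breakdown = composition.components[macro]
        class_sum = sum(breakdown.values())
        for comp, f_comp in breakdown.items():
            if comp not in composition.molecular_weights:
                raise KeyError(
                    f"missing molecular weight for component {comp!r} "
                    f"(macromolecule {macro!r})"
                )
            f_m = f_macro / macro_sum if renormalise else f_macro
            f_c = f_comp / class_sum if renormalise else f_comp
            mw = composition.molecular_weights[comp]
            coefficients[comp] = (
                coefficients.get(comp, 0.0) - 1000.0 * f_m * f_c / mw
            )

    gam_mets = (
        {met: coef * composition.gam_atp for met, coef in GAM_STOICHIOMETRY.items()}
        if gam_in_biomass and composition.gam_atp > 0
        else {}
    )
    return BiomassReaction(
        coefficients=coefficients,
        gam_atp=composition.gam_atp,
        gam_metabolites=gam_mets,
        molecular_weights={
            c: composition.molecular_weights[c] for c in coefficients
        },
    )


def umbelopsis_composition(
    molecular_weights: dict[str, float] | None = None,
    gam_atp: float = DEFAULT_GAM_ATP,
) -> BiomassComposition:
    """The packaged oleaginous-fungus composition with reference weights."""
    weights = dict(REFERENCE_RESIDUE_WEIGHTS)
    if molecular_weights:
        weights.update(molecular_weights)
    macros = {
        k: v / 100.0
        for k, v in UMBELOPSIS_COMPOSITION["macromolecules_percent"].items()
    }
    components = {
        macro: {comp: v / 100.0 for comp, v in breakdown.items()}
        for macro, breakdown in UMBELOPSIS_COMPOSITION["components_percent"].items()
    }
    return BiomassComposition(macros, components, weights, gam_atp)


def load_composition(path: str | Path) -> BiomassComposition:
    """Load a composition from JSON mirroring the two-level table structure.

    Expected keys: ``macromolecules_percent``, ``components_percent``,
    optional ``molecular_weights`` (falls back to the reference table) and
    ``gam_atp``.
    """
    data = json.loads(Path(path).read_text())
    weights = dict(REFERENCE_RESIDUE_WEIGHTS)
    weights.update(data.get("molecular_weights", {}))
    macros = {k: v / 100.0 for k, v in data["macromolecules_percent"].items()}
    components = {
        macro: {comp: v / 100.0 for comp, v in breakdown.items()}
        for macro, breakdown in data["components_percent"].items()
    }
    return BiomassComposition(
        macros, components, weights, float(data.get("gam_atp", DEFAULT_GAM_ATP))
    )
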