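"""Reference biomass-composition data for an oleaginous Mucoromycota fungus.

``UMBELOPSIS_COMPOSITION`` is the experimentally derived macromolecular
breakdown of *Umbelopsis* dry biomass used throughout the package's worked
examples: five macromolecule pools (percent of dry weight) each split into
components (percent of the pool).  The printed component percentages do
not all sum to exactly 100 — protein sums to 100.09 %, lipids to 100.2 %
and RNA to 99.9 % — and are deliberately stored as printed;
:func:`oleoflux.biomass_builder.validate_composition` reports the residuals
and :func:`~oleoflux.biomass_builder.compose_biomass` renormalises them by
default.

``REFERENCE_RESIDUE_WEIGHTS`` maps components to polymer-residue molecular
weights (g·mol⁻¹): amino acids and nucleotides as their in-chain residues
(free weight minus water released on polymerisation), sugars as anhydro
residues, lipid classes as representative species dominated by C18
(oleate/linoleate) acyl chains.  These are reference data, not ground
truth — callers supplying their own measured weights override them.
"""

from __future__ import annotations

#: Growth-associated maintenance, mmol ATP hydrolysed per g dry weight.
DEFAULT_GAM_ATP = 153.0

#: Macromolecule pools (percent of dry weight) and their component
#: breakdowns (percent of the pool), stored exactly as printed.
UMBELOPSIS_COMPOSITION: dict[str, dict] = {
    "macromolecules_percent": {
        "DNA": 2.5,
        "RNA": 5.0,
        "protein": 35.0,
        "lipids": 40.0,
        "carbohydrates": 17.5,
    },
    "components_percent": {
        "DNA": {"dATP": 28.6, "dCTP": 22.4, "dGTP": 19.6, "dTTP": 29.4},
        "RNA": {"ATP": 26.4, "CTP": 25.2, "GTP": 20.1, "UTP": 28.2},
        "protein": {
            "alanine": 7.6,
            "arginine": 5.2,
            "asparagine": 4.7,
            "aspartate": 6.0,
            "cysteine": 1.2,
            "glutamate": 6.4,
            "glutamine": 4.6,
            "glycine": 5.7,
            "histidine": 2.4,
            "isoleucine": 5.7,
            "leucine": 8.8,
            "lysine": 5.89,
            "methionine": 2.4,
            "phenylalanine": 3.7,
            "proline": 5.1,
            "serine": 8.3,
            "threonine": 5.9,
            "tryptophan": 1.2,
            "tyrosine": 3.2,
            "valine": 6.1,
        },
        "lipids": {
            "triglycerides": 84.6,
            "diglycerides": 4.8,
            "free_fatty_acids": 4.8,
            "sterols": 1.0,
            "phosphatidylethanolamines": 0.7,
            "phosphatidylcholines": 2.8,
            "phosphatidylinositols": 0.7,
            "phosphatidylserines": 0.6,
            "phosphatidic_acid": 0.2,
        },
        "carbohydrates": {
            "fucose": 23.7,
            "glucosamine": 42.9,
            "galactose": 4.1,
            "glucose": 26.8,
            "mannose": 2.5,
        },
    },
}

#: Polymer-residue molecular weights, g·mol⁻¹ (reference data, overridable).
REFERENCE_RESIDUE_WEIGHTS: dict[str, float] = {
    # deoxynucleotide residues (dNMP in chain)
    "dATP": 313.21,
    "dCTP": 289.18,
    "dGTP": 329.21,
    "dTTP": 304.20,
    # ribonucleotide residues (NMP in chain)
    "ATP": 329.21,
    "CTP": 305.18,
    "GTP": 345.21,
    "UTP": 306.17,
    # amino-acid residues (free weight minus 18.02 for peptide-bond water)
    "alanine": 71.08,
    "arginine": 156.19,
    "asparagine": 114.10,
    "aspartate": 115.09,
    "cysteine": 103.14,
    "glutamate": 129.12,
    "glutamine": 128.13,
    "glycine": 57.05,
    "histidine": 137.14,
    "isoleucine": 113.16,
    "leucine": 113.16,
    "lysine": 128.17,
    "methionine": 131.19,
    "phenylalanine": 147.18,
    "proline": 97.12,
    "serine": 87.08,
    "threonine": 101.10,
    "tryptophan": 186.21,
    "tyrosine": 163.18,
    "valine": 99.13,
    # lipid classes, representative C18-dominated species
    "triglycerides": 879.38,  # trilinolein
    "diglycerides": 616.92,
    "free_fatty_acids": 280.45,  # linoleate
    "sterols": 396.65,  # ergosterol
    "phosphatidylethanolamines": 744.03,
    "phosphatidylcholines": 786.11,
    "phosphatidylinositols": 866.11,
    "phosphatidylserines": 787.03,
    "phosphatidic_acid": 700.97,
    # anhydro sugar residues
    "fucose": 146.14,
    "glucosamine": 161.16,
    "galactose": 162.14,
    "glucose": 162.14,
    "mannose": 162.14,
}
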