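#!/usr/bin/env python
"""Assemble the biomass equation from the packaged composition table.

Validates the printed fractions (reporting the residuals in the protein,
lipid and RNA breakdowns), composes the drain coefficients with
renormalisation, verifies the 1-gram mass balance, and writes the
coefficient table to results/biomass_equation.tsv.
"""

import warnings
from pathlib import Path

from oleoflux.biomass_builder import (
    compose_biomass,
    umbelopsis_composition,
    validate_composition,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    composition = umbelopsis_composition(gam_atp=153.0)
    report = validate_composition(composition)
    print("strict validation findings (class, residual of the fraction sum):")
    for where, residual in report.findings:
        print(f"  {where}: {residual:+.4%}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reaction = compose_biomass(composition, renormalise=True)
    print(f"{len(reaction.coefficients)} precursor components, "
          f"total drained mass {reaction.mass_mg():.6f} mg/gDW "
          "(target 1000)")
    print(f"GAM: {abs(reaction.gam_metabolites['atp_c']):g} mmol ATP + H2O "
          "-> ADP + Pi + H+ per gDW")

    lines = ["component\tcoefficient_mmol_per_gDW\tresidue_mw_g_per_mol"]
    for comp in sorted(reaction.coefficients):
        lines.append(f"{comp}\t{reaction.coefficients[comp]:.6f}"
                     f"\t{reaction.molecular_weights[comp]:g}")
    for met in sorted(reaction.gam_metabolites):
        lines.append(f"{met}\t{reaction.gam_metabolites[met]:.6f}\tGAM")
    (OUT / "biomass_equation.tsv").write_text("\n".join(lines) + "\n")
    print(f"wrote {OUT / 'biomass_equation.tsv'}")


if __name__ == "__main__":
    main()
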