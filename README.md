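# oleoflux

Constraint-based analysis toolkit for genome-scale metabolic models (GEMs)
of oleaginous fungi — organisms of biotechnological interest for
polyunsaturated fatty-acid (PUFA) production.  The package covers the
standard model-interrogation workflow end to end:

* **Biomass objective assembly** — turn a macromolecular composition table
  (mass fractions of DNA, RNA, protein, lipids, carbohydrates and their
  components) plus growth-associated maintenance (GAM) ATP into a
  stoichiometrically coherent biomass reaction that drains exactly one
  gram of precursors per flux unit.
* **Flux balance analysis** — FBA (max c·v s.t. S·v = 0, lb ≤ v ≤ ub,
  solved with HiGHS) and parsimonious FBA for deterministic flux supports.
* **Phenotype-array concordance screening** — simulate growth on every
  carbon source of a Biolog-style plate under a minimal medium, reduce
  plate replicates by majority call, and score the 2×2 agreement between
  in vitro and in silico growth; pool the solutions into a
  core / auxiliary / unused reaction-activity partition with 10 %/90 %
  subdivision of the auxiliary set.
* **FSEOF target scanning** — Flux Scanning based on Enforced Objective
  Flux: step the product flux from baseline toward its maximum while
  maximising biomass, report reactions whose flux rises with the product
  (slope = d|v|/d(enforced flux)), aggregate across carbon sources with
  robustness filters (≥ 5 media, slope > 2) and map retained reactions to
  genes through their GPR rules.
* **Synthetic ground truth** — generators for toy and random feasible
  networks, phenotype panels with planted confusion structure, and
  product-coupled networks with provable FSEOF slopes, so every stage is
  testable offline.

Models are read and written as SBML L3V1+FBC2, a JSON dialect mirroring
the in-memory types, or a flat TSV reaction table; plates as CSV.

## Worked example

```python
from oleoflux.synthetic_data import (
    PanelSpec, ToyCoreSpec, make_multisource_model,
    make_phenotype_panel, make_toy_core_model,
)
from oleoflux.phenotype_screen import MediumSpec, screen_carbon_sources
from oleoflux.fseof_scan import run_fseof

# Screen a 95-compound plate with a planted 41/36/8/10 confusion structure
model, _ = make_multisource_model(60, seed=0)
plate, _ = make_phenotype_panel(
    model, PanelSpec(n_sources=95, planted_counts=(41, 36, 8, 10), seed=0)
)
concordance, _ = screen_carbon_sources(
    model, plate, MediumSpec(free_exchange_ids=())
)
print(concordance.counts, round(concordance.agreement_percent, 2))
# (41, 36, 8, 10) 81.05

# Recover a planted amplification target
toy, record = make_toy_core_model(
    ToyCoreSpec(include_product_branch=True, coupling=2.0)
)
scan = run_fseof(toy, product_rxn=record.product_reaction)
print({r.reaction_id: round(r.slope, 6) for r in scan.records})
# {'CARBOXYLASE': 2.0, 'PRODUCT_SYNTH': 1.0, 'DM_product_c': 1.0}
```

The screen's four counts are (growth in both, no growth in both, in vitro
growth the model misses, spurious in silico growth); agreement is their
concordant share.  The FSEOF slopes say how strongly each reaction's flux
co-increases with enforced product flux: the planted carboxylation-like
step carries exactly `coupling` flux units per product unit, so its slope
is the coupling coefficient, and the product demand's own slope is 1 by
construction.

The numbered scripts under `analysis/` run the same stages as narrative
drivers (model construction and validation, biomass-equation assembly,
phenotype screen, FSEOF aggregation) and write their tables under
`results/`.

A `oleoflux` console command exposes the stages for shell use:
`oleoflux convert`, `oleoflux biomass`, `oleoflux fba`, `oleoflux screen`,
`oleoflux fseof`, `oleoflux synth`, `oleoflux run --config run.yaml`.

## Scope notes

Organism-specific genome-scale results (reaction/metabolite/gene counts of
a deposited reconstruction, activity partitions of real solutions,
predicted absolute growth rates) require that reconstruction and its
medium settings; `docs/methods.md` describes the conversion path for
externally obtained models and what the synthetic suites do and do not
certify.
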