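# Methods

`oleoflux` re-implements, as a tested library, the constraint-based
analysis workflow used to interrogate genome-scale metabolic models (GEMs)
of oleaginous fungi: assembling a biomass objective from a macromolecular
composition table, screening carbon-source utilisation against
phenotype-array data on a minimal medium, pooling flux solutions into a
reaction-activity partition, and scanning for product-amplification
targets with FSEOF.  Every stage runs on synthetic networks whose correct
answers are known in closed form, so the pipeline is verifiable without
downloading any deposited reconstruction.

## Model representation and structural operations

A model is metabolites (with compartments from an extensible registry,
default extracellular/cytosol/mitochondrion), reactions (signed
stoichiometry, bounds in mmol·gDW⁻¹·h⁻¹, optional boolean
gene–protein–reaction rule, a kind tag among internal / transport /
exchange / demand / biomass) and genes.  Exchanges are written in the
export direction, so uptake is negative flux and "unconstrained" means a
lower bound of −1000, the community default magnitude.  Duplicate ids are
hard errors at construction: silently shadowed reactions corrupt flux maps.

GPR rules use identifiers `[A-Za-z0-9_.-]+` with case-insensitive
`and`/`or` and parentheses; `and` binds tighter than `or` (the SBML-FBC
convention).  The parser produces an evaluable tree; the gene set of a
rule is invariant under boolean rewriting, which the tests exercise.

"Orphan" (dead-end) metabolites are defined as metabolites participating
in exactly one reaction.  `slim_model` removes each such metabolite with
its reaction and, by default, iterates to a fixed point, since removing a
reaction can strand further metabolites; a single-pass variant sits behind
`fixed_point=False` because either reading of a one-shot "strip the dead
ends" step is defensible.  The objective reaction is protected — stripping
it is refused with a diagnostic rather than silently returning a model
that cannot grow.

## Serialisation

SBML Level 3 Version 1 with FBC v2 is the primary interchange format
(bounds as shared parameters, the objective as an FBC flux objective, GPRs
as gene-product associations, reaction kinds as SBO terms).  Files without
FBC bounds fall back to (−1000, 1000) for reversible and (0, 1000) for
irreversible reactions.  A JSON dialect mirrors the domain-type fields
one-to-one; externally deposited GEMs in standard-GEM-style layouts can be
converted into it by mapping their metabolite/reaction/gene records onto
these fields — the converter documents the mapping rather than hard-coding
any particular repository's layout, and no network access is ever
attempted.  A flat TSV reaction table (id, equation, bounds, GPR, kind)
covers spreadsheet-style curation; it does not carry names, formulas or
annotations.  All writers sort ids, so identical inputs serialise to
identical bytes.

## Biomass equation

Given macromolecule mass fractions f_macro of dry weight, within-class
fractions f_comp and residue molecular weights MW (g·mol⁻¹), each
precursor is drained at

    1000 · f_macro · f_comp / MW   mmol·gDW⁻¹

so the reaction consumes exactly 1000 mg per gram of biomass formed;
`mass_mg()` re-derives Σ|coefficient|·MW as the invariant check
(tolerance 1e-6 mg).  Growth-associated maintenance enters as
ATP + H₂O → ADP + Pi + H⁺ at the configured rate, 153 mmol ATP·gDW⁻¹ by
default, inside the biomass equation; a flag externalises it for users who
prefer a separate maintenance pseudo-reaction, since both conventions are
common.

The packaged composition table for an oleaginous Mucoromycota fungus (DNA
2.5 %, RNA 5 %, protein 35 %, lipids 40 %, carbohydrates 17.5 % of dry
weight, with component breakdowns) stores the values as printed even where
a breakdown does not sum exactly to 100 % (protein 100.09 %, lipids
100.2 %, RNA 99.9 %).  Strict validation reports these residuals;
composition renormalises each family by default with a logged warning,
which is provably identical to composing the exactly normalised table.
Residue weights are data supplied by the caller; the shipped reference
table uses in-chain residue weights (monomer minus polymerisation water)
and representative C18-dominated species for the lumped lipid classes.
The package deliberately does not invent acyl-chain distributions — lipid
classes map to representative metabolites through a caller-supplied map.

## Flux balance analysis

FBA solves max c·v subject to S·v = 0, lb ≤ v ≤ ub with HiGHS
(`scipy.optimize.linprog`).  Infeasible and unbounded instances are
statuses on the returned solution, never exceptions.  Parsimonious FBA
re-solves with the objective pinned at its optimum (relative tolerance
1e-9) and total |v| minimised through the standard positive/negative flux
split.  All activity calls downstream use pFBA fluxes by default: plain LP
optima of metabolic networks are massively degenerate and their supports
solver-dependent, so pooling raw FBA active sets would not be
reproducible.  A reaction is "active" when |flux| exceeds 1e-6
mmol·gDW⁻¹·h⁻¹; growth is called when the objective exceeds 1e-6 h⁻¹.
These epsilons, and the default qualitative-screening uptake of
10 mmol·gDW⁻¹·h⁻¹, are package choices — only qualitative growth/no-growth
conclusions are drawn from them.

## Phenotype screening and activity pooling

The minimal medium leaves a fixed list of exchanges unconstrained
(defaults: phosphate, sulphite, sulphate, ammonium, CO₂, O₂, water,
protons), uptake-bounds exactly one carbon exchange, and closes every
other exchange for uptake while leaving secretion open.  Plate replicates
are reduced by a majority rule — positive when at least two of three
replicates grew.  Plate compounds with no exchange reaction in the model
are structural no-growth predictions carrying a `no_exchange` reason code
(the missing-transporter / extracellular-degradation situation) rather
than errors, so the screen's discrepancy taxonomy survives into the output
tables.

Feasible per-source solutions are pooled into activity fractions (share of
solutions with |flux| above the activity epsilon).  Reactions active in
every solution are core; never-active reactions are the unused set; the
auxiliary remainder ("active at least once") is subdivided at the 10 %/90 %
thresholds: near-core when inactive in at most 10 % of solutions,
source-specific when active in at most 10 %, type-associated otherwise.
Both boundary comparisons are inclusive and near-core is evaluated first,
so the three classes always partition the auxiliary set even at exactly
10 %/90 %; the thresholds are configurable.

## FSEOF

The scan computes the product's theoretical maximum, then enforces the
product flux as a lower bound at ten evenly spaced levels from the
baseline (the product flux at the unconstrained biomass optimum) up to
90 % of the maximum — stopping short of the typically infeasible extreme
vertex — while biomass remains the optimisation objective.  Per-step
fluxes come from pFBA.  The per-reaction slope is the least-squares
regression of |flux| on the enforced level; an endpoint-difference slope
is available behind a flag since both definitions circulate and they agree
exactly on linear responses.  A reaction is reported when its slope is
positive (above a 1e-6 noise floor — solver tolerances leak into per-step
fluxes of constant reactions) and its |flux| is non-decreasing across
levels; reactions reversing direction across levels are excluded from
targets and listed separately, because "flux increases" is ill-defined
across a sign change.  The biomass trajectory is asserted non-increasing
on every scan.  Aggregation across carbon-source media retains reactions
reported with slope above 2 in at least 5 media (both thresholds
configurable), and retained reactions are mapped to the union of their
GPR gene sets; reactions with no GPR are flagged as orphans and listed
separately.

## Synthetic data: what it emulates and what it does not

The generators are first-class, tested code and define the study
conditions:

* **Toy core** — one substrate exchange (uptake 10), parallel routes with
  yields 0.5 and 0.8 to a biomass precursor.  The FBA optimum is
  `uptake × best yield` by construction.  The optional product branch
  routes substrate through a committed carboxylation-like step into a
  demanded fatty-acid-like product at a chosen coupling c, so that step's
  FSEOF slope is exactly c and the product's own slope is exactly 1.
* **Multisource model** — the same core replicated over n carbon sources
  with per-source yields drawn from [0.3, 0.9].
* **Random feasible networks** — a guaranteed-growing catabolic chain plus
  random forward shortcuts and demands; rejection sampling of random
  stoichiometric matrices almost never yields a growing network, so
  feasibility is built in rather than sampled for.
* **Phenotype panels** — 95 compounds in the standard class mix
  (7 amines/amides, 13 amino acids, 15 carboxylic acids, 46 carbohydrates,
  5 polymers, 9 other) with a planted confusion structure, default
  41/36/8/10, realised so the screen recovers it exactly: false negatives
  are plate-positive compounds absent from the model, false positives
  model-feasible compounds with negative replicates.  Replicate noise only
  ever flips non-pivotal replicates, so majority calls are deterministic.
* **Planted activity matrices** — pooled solutions with chosen
  always/near-core/type-associated/source-specific/never counts (defaults
  212/41/188/221/1553 over 59 solutions, a 2215-reaction profile).

These networks reproduce the *arithmetic and algorithmic* behaviour of the
pipeline — confusion accounting, partition thresholds, slope recovery,
filter logic — under exactly known ground truth.  They do not reproduce
genome-scale topology: no cofactor coupling, no compartmentalised redox
balancing, no alternate-optima degeneracy at realistic scale, and activity
counts in the hundreds-of-reactions range arise only in the planted
matrices, not from the toy networks.  Passing tests therefore certify the
method implementation, not any organism-specific biology.

Whole-organism quantities — a reconstruction's 2215/2418/1627
reaction/metabolite/gene counts, an activity partition measured from real
solutions, a mean of ~336 active reactions per solution, a 297→23 FSEOF
reaction funnel over 33 genes, or a predicted μ = 0.117 h⁻¹ on glucose —
require the externally deposited model plus medium and uptake settings
that were never published.  The package substitutes the property-based
suites above and provides the conversion path (SBML reader, JSON mapping)
for users who fetch a deposited reconstruction themselves.

## Numerical choices

LP feasibility is checked at 1e-9 componentwise; pFBA pins the objective
at relative 1e-9; activity and growth epsilons are 1e-6; slope noise floor
1e-6; biomass mass balance asserted at 1e-6 mg.  Ties between equal-yield
routes are resolved by the parsimonious objective, not by solver order.
Degenerate inputs (empty models, closed media, unreachable products,
infeasible enforcement steps) return statuses or reasons rather than
raising, except where the input violates a structural invariant.

## Known limitations

* No flux variability analysis, knockout design (MOMA/ROOM/OptKnock),
  thermodynamic constraints, or mass/charge balancing of individual
  reactions.
* The TSV dialect is lossy (no names/annotations); SBML/JSON are the
  round-trip formats.
* The SBML reader targets FBC v2 core features; groups/layout packages are
  ignored.
* FSEOF retention uses strict inequalities ("slope greater than 2", "at
  least 5 media"); a slope of exactly 2 is dropped by design.
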