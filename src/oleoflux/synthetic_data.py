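"""Synthetic inputs with known ground truth for every pipeline stage.

Real genome-scale models are thousands of reactions with unpublished medium
details; everything here is built the other way around — small networks
whose optima, growth calls and scan slopes are known in closed form at
construction time — so each downstream stage can be tested against an
analytic record rather than against another solver run.

Generators
----------
* :func:`make_toy_core_model` — a substrate→precursor→biomass core with
  parallel routes of differing yield, optionally extended by a
  fatty-acid-like product branch whose committed (carboxylation-like) step
  is stoichiometrically coupled to the product at a chosen ratio, giving an
  exact planted FSEOF slope.
* :func:`make_multisource_model` — the same core replicated over many
  alternative carbon sources, for phenotype-panel screening.
* :func:`make_random_feasible_model` — random networks composed from
  guaranteed-feasible pathway motifs (rejection sampling of raw random
  stoichiometries almost never grows).
* :func:`make_phenotype_panel` — a Biolog-style plate with a planted
  confusion structure that the screen recovers exactly; false negatives are
  realised as plate-positive compounds with no exchange in the model
  (the missing-transporter situation), false positives as model-feasible
  compounds with plate-negative replicates.
* :func:`make_activity_solutions` — pooled flux solutions with planted
  always/auxiliary/never activity counts for the classifier.

All generators are deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fba_engine import FluxSolution, growth_call, solve_fba
from .gem_core import Gene, MetabolicModel, Metabolite, Reaction
from .model_io import SUBSTRATE_CLASSES, PlateRow, PlateTable
from .phenotype_screen import MediumSpec, configure_medium, default_source_to_exchange

__all__ = [
    "ToyCoreSpec",
    "ToyCoreRecord",
    "PanelSpec",
    "make_toy_core_model",
    "make_multisource_model",
    "make_random_feasible_model",
    "make_phenotype_panel",
    "make_activity_solutions",
]

#: Class mix of the default 95-compound plate
#: (amines/amides, amino acids, carboxylic acids, carbohydrates, polymers, other).
DEFAULT_CLASS_MIX = {
    "amine/amide": 7,
    "amino acid": 13,
    "carboxylic acid": 15,
    "carbohydrate": 46,
    "polymer": 5,
    "other": 9,
}


@dataclass
class ToyCoreSpec:
    """Parameters of the toy core network.

    ``yields`` are per-route biomass yields (gDW·mmol⁻¹); the FBA optimum
    is ``uptake_bound × max(yields)``.  With ``include_product_branch`` the
    product demand is fed through a committed step consuming ``coupling``
    substrate units per product unit, so that step's FSEOF slope is exactly
    ``coupling``.
    """

    uptake_bound: float = 10.0
    yields: tuple[float, ...] = (0.5, 0.8)
    include_product_branch: bool = False
    coupling: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.yields or any(y <= 0 for y in self.yields):
            raise ValueError("route yields must be positive")
        if self.coupling <= 0:
            raise ValueError("coupling coefficient must be positive")


@dataclass
class ToyCoreRecord:
    """Closed-form facts about a generated toy model."""

    optimum: float
    best_route: str
    biomass_reaction: str
    carbon_exchange: str
    product_reaction: str | None = None
    product_max: float | None = None
    planted_reaction: str | None = None
    planted_slope: float | None = None


def make_toy_core_model(
    spec: ToyCoreSpec | None = None,
) -> tuple[MetabolicModel, ToyCoreRecord]:
    """Build the toy core network together with its analytic record."""
    spec = spec or ToyCoreSpec()
    mets = [
        Metabolite("glc_e", name="substrate (extracellular)", compartment="e"),
        Metabolite("glc_c", name="substrate (cytosol)", compartment="c"),
        Metabolite("prec_c", name="biomass precursor", compartment="c"),
    ]
    rxns = [
        Reaction(
            "EX_glc_e",
            {"glc_e": -1.0},
            lower_bound=-spec.uptake_bound,
            upper_bound=1000.0,
            kind="exchange",
        ),
        Reaction(
            "T_glc",
            {"glc_e": -1.0, "glc_c": 1.0},
            lower_bound=0.0,
            kind="transport",
            gpr="gT1",
        ),
    ]
    genes = [Gene("gT1")]
    for i, y in enumerate(spec.yields, start=1):
        rxns.append(
            Reaction(
                f"ROUTE_{i}",
                {"glc_c": -1.0, "prec_c": float(y)},
                lower_bound=0.0,
                gpr=f"gR{i}",
            )
        )
        genes.append(Gene(f"gR{i}"))
    rxns.append(
        Reaction("BIOMASS", {"prec_c": -1.0}, lower_bound=0.0, kind="biomass")
    )

    best_idx = int(np.argmax(spec.yields))
    record = ToyCoreRecord(
        optimum=spec.uptake_bound * max(spec.yields),
        best_route=f"ROUTE_{best_idx + 1}",
        biomass_reaction="BIOMASS",
        carbon_exchange="EX_glc_e",
    )

    if spec.include_product_branch:
        mets += [
            Metabolite("mal_c", name="activated acyl precursor", compartment="c"),
            Metabolite("prod_c", name="fatty-acid-like product", compartment="c"),
        ]
        rxns += [
            # Committed carboxylation-like step: the planted FSEOF target.
            Reaction(
                "CARBOXYLASE",
                {"glc_c": -1.0, "mal_c": 1.0},
                lower_bound=0.0,
                gpr="gACC1 and gACC2",
            ),
            Reaction(
                "PRODUCT_SYNTH",
                {"mal_c": -spec.coupling, "prod_c": 1.0},
                lower_bound=0.0,
                gpr="gFAS1",
            ),
            Reaction(
                "DM_product_c",
                {"prod_c": -1.0},
                lower_bound=0.0,
                kind="demand",
            ),
        ]
        genes += [Gene("gACC1"), Gene("gACC2"), Gene("gFAS1")]
        record.product_reaction = "DM_product_c"
        record.product_max = spec.uptake_bound / spec.coupling
        record.planted_reaction = "CARBOXYLASE"
        record.planted_slope = spec.coupling

    model = MetabolicModel(
        id="toy_core",
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objective_reaction="BIOMASS",
    )
    return model, record


def make_multisource_model(
    n_sources: int = 60,
    seed: int = 0,
    include_product_branch: bool = False,
    coupling: float = 2.0,
) -> tuple[MetabolicModel, dict[str, float]]:
    """A core model growing on ``n_sources`` alternative carbon sources.

    Every source ``srcNNN`` enters through its own exchange, transporter
    and catabolic step with a per-source yield drawn from [0.3, 0.9];
    returns the model and the source → yield map (the closed-form growth
    rate on that source is ``10 × yield`` at the default screening uptake).
    Exchanges default to uptake-closed; :func:`~oleoflux.phenotype_screen.
    configure_medium` opens one at a time.
    """
    if n_sources < 1:
        raise ValueError("need at least one carbon source")
    rng = np.random.default_rng(seed)
    mets = [Metabolite("prec_c", name="biomass precursor", compartment="c")]
    rxns: list[Reaction] = []
    genes: list[Gene] = []
    yields: dict[str, float] = {}
    for i in range(1, n_sources + 1):
        src = f"src{i:03d}"
        y = float(rng.uniform(0.3, 0.9))
        yields[src] = y
        mets += [
            Metabolite(f"{src}_e", compartment="e"),
            Metabolite(f"{src}_c", compartment="c"),
        ]
        rxns += [
            Reaction(
                f"EX_{src}_e",
                {f"{src}_e": -1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
                kind="exchange",
            ),
            Reaction(
                f"T_{src}",
                {f"{src}_e": -1.0, f"{src}_c": 1.0},
                lower_bound=0.0,
                kind="transport",
                gpr=f"gT{i:03d}",
            ),
            Reaction(
                f"CATAB_{src}",
                {f"{src}_c": -1.0, "prec_c": y},
                lower_bound=0.0,
                gpr=f"gC{i:03d}",
            ),
        ]
        genes += [Gene(f"gT{i:03d}"), Gene(f"gC{i:03d}")]
    rxns.append(
        Reaction("BIOMASS", {"prec_c": -1.0}, lower_bound=0.0, kind="biomass")
    )
    if include_product_branch:
        mets += [
            Metabolite("mal_c", compartment="c"),
            Metabolite("prod_c", compartment="c"),
        ]
        rxns += [
            Reaction(
                "CARBOXYLASE",
                {"prec_c": -1.0, "mal_c": 1.0},
                lower_bound=0.0,
                gpr="gACC1 and gACC2",
            ),
            Reaction(
                "PRODUCT_SYNTH",
                {"mal_c": -coupling, "prod_c": 1.0},
                lower_bound=0.0,
                gpr="gFAS1",
            ),
            Reaction(
                "DM_product_c", {"prod_c": -1.0}, lower_bound=0.0, kind="demand"
            ),
        ]
        genes += [Gene("gACC1"), Gene("gACC2"), Gene("gFAS1")]
    model = MetabolicModel(
        id="multisource",
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objective_reaction="BIOMASS",
    )
    return model, yields


def make_random_feasible_model(
    n_mets: int, n_rxns: int, seed: int = 0, uptake_bound: float = 10.0
) -> MetabolicModel:
    """Random network with guaranteed growth, exact dimensions per seed.

    A substrate exchange feeds a linear catabolic chain ending in the
    biomass reaction; leftover reaction budget is spent on random forward
    shortcut conversions (yield ≤ 1, so the optimum stays bounded) and
    demand reactions.  Any metabolite budget the chain cannot absorb
    becomes inert storage species.
    """
    if n_mets < 2:
        raise ValueError("need at least two metabolites")
    if n_rxns < n_mets:
        raise ValueError("need at least as many reactions as metabolites")
    rng = np.random.default_rng(seed)

    chain_len = min(n_mets - 1, n_rxns - 2)
    mets = [Metabolite("sub_e", compartment="e")]
    chain_ids = ["sub_e"]
    for i in range(1, chain_len + 1):
        met_id = f"int{i:03d}_c"
        mets.append(Metabolite(met_id, compartment="c"))
        chain_ids.append(met_id)
    for i in range(n_mets - 1 - chain_len):
        mets.append(Metabolite(f"store{i + 1:03d}_c", compartment="c"))

    rxns = [
        Reaction(
            "EX_sub_e",
            {"sub_e": -1.0},
            lower_bound=-uptake_bound,
            upper_bound=1000.0,
            kind="exchange",
        )
    ]
    genes: list[Gene] = []
    for i in range(chain_len):
        kind = "transport" if i == 0 else "internal"
        rxns.append(
            Reaction(
                f"STEP_{i + 1:03d}",
                {chain_ids[i]: -1.0, chain_ids[i + 1]: 1.0},
                lower_bound=0.0,
                kind=kind,
                gpr=f"g{i + 1:03d}",
            )
        )
        genes.append(Gene(f"g{i + 1:03d}"))
    rxns.append(
        Reaction(
            "BIOMASS", {chain_ids[-1]: -1.0}, lower_bound=0.0, kind="biomass"
        )
    )

    extra = n_rxns - len(rxns)
    for k in range(extra):
        if len(chain_ids) >= 2 and rng.random() < 0.7:
            i, j = sorted(rng.choice(len(chain_ids), size=2, replace=False))
            y = float(rng.uniform(0.3, 1.0))
            rxns.append(
                Reaction(
                    f"ALT_{k + 1:03d}",
                    {chain_ids[i]: -1.0, chain_ids[j]: y},
                    lower_bound=0.0,
                )
            )
        else:
            target = chain_ids[int(rng.integers(0, len(chain_ids)))]
            rxns.append(
                Reaction(
                    f"DM_{k + 1:03d}",
                    {target: -1.0},
                    lower_bound=0.0,
                    kind="demand",
                )
            )
    model = MetabolicModel(
        id=f"random_{seed}",
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objective_reaction="BIOMASS",
    )
    return model


# ---------------------------------------------------------------------------
# Phenotype panels with planted confusion structure
# ---------------------------------------------------------------------------


@dataclass
class PanelSpec:
    """Plate layout and planted confusion counts.

    ``planted_counts`` order: (both_growth, both_no_growth,
    false_no_growth, false_growth); they must sum to ``n_sources``.
    Replicate noise flips only non-pivotal replicates so the majority call
    (and therefore the planted confusion structure) is never perturbed.
    """

    n_sources: int = 95
    class_mix: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    planted_counts: tuple[int, int, int, int] = (41, 36, 8, 10)
    replicates: int = 3
    noise_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.planted_counts) != self.n_sources:
            raise ValueError(
                f"planted counts {self.planted_counts} must sum to "
                f"n_sources={self.n_sources}"
            )
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise rate must lie in [0, 1)")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if any(c not in SUBSTRATE_CLASSES for c in self.class_mix):
            raise ValueError("unknown substrate class in class mix")


def _class_assignment(spec: PanelSpec, rng: np.random.Generator) -> list[str]:
    """Scale the class mix to n_sources by largest remainder, then shuffle."""
    total_mix = sum(spec.class_mix.values())
    raw = {
        c: spec.n_sources * n / total_mix for c, n in spec.class_mix.items()
    }
    counts = {c: math.floor(v) for c, v in raw.items()}
    shortfall = spec.n_sources - sum(counts.values())
    by_remainder = sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in by_remainder[:shortfall]:
        counts[c] += 1
    classes = [c for c, n in counts.items() for _ in range(n)]
    rng.shuffle(classes)
    return classes


def _replicates(
    positive: bool, spec: PanelSpec, rng: np.random.Generator, min_positive: int = 2
) -> list[bool]:
    calls = [positive] * spec.replicates
    n_true = spec.replicates if positive else 0
    # Flip one replicate only when the majority call provably survives it.
    can_flip = (
        (positive and n_true - 1 >= min_positive)
        or (not positive and n_true + 1 < min_positive)
    )
    if can_flip and rng.random() < spec.noise_rate:
        calls[int(rng.integers(0, spec.replicates))] = not positive
    return calls


def make_phenotype_panel(
    model: MetabolicModel,
    spec: PanelSpec | None = None,
    medium_template: MediumSpec | None = None,
    growth_threshold: float = 1e-6,
) -> tuple[PlateTable, dict[str, dict]]:
    """Plate whose screen against ``model`` reproduces the planted counts.

    Concordant-growth and false-growth compounds are drawn from carbon
    sources the model actually grows on (determined here by FBA on the
    configured medium); concordant-no-growth and false-no-growth compounds
    are invented plate compounds with no exchange reaction in the model.
    Returns the plate and a ground-truth map
    ``source → {category, exchange_id, model_growth}``.
    """
    spec = spec or PanelSpec()
    medium_template = medium_template or MediumSpec(free_exchange_ids=())
    rng = np.random.default_rng(spec.seed)
    n_tp, n_tn, n_fn, n_fp = spec.planted_counts

    free = set(medium_template.free_exchange_ids)
    feasible_sources: list[str] = []
    for rxn in model.exchanges():
        if rxn.kind != "exchange" or rxn.id in free:
            continue
        if not (rxn.id.startswith("EX_") and rxn.id.endswith("_e")):
            continue
        source = rxn.id[len("EX_"):-len("_e")]
        configured = configure_medium(model, medium_template.with_carbon(rxn.id))
        if growth_call(solve_fba(configured), growth_threshold):
            feasible_sources.append(source)
    if not feasible_sources:
        raise ValueError("model grows on none of its carbon exchanges")
    if n_tp + n_fp > len(feasible_sources):
        raise ValueError(
            f"planted growth-capable counts ({n_tp}+{n_fp}) exceed the "
            f"{len(feasible_sources)} model-feasible carbon sources"
        )
    rng.shuffle(feasible_sources)
    tp_sources = feasible_sources[:n_tp]
    fp_sources = feasible_sources[n_tp : n_tp + n_fp]
    tn_sources = [f"cpd_absent{i + 1:03d}" for i in range(n_tn)]
    fn_sources = [f"cpd_missingT{i + 1:03d}" for i in range(n_fn)]

    entries: list[tuple[str, str, bool, bool]] = []  # source, cat, vitro, silico
    entries += [(s, "both_growth", True, True) for s in tp_sources]
    entries += [(s, "both_no_growth", False, False) for s in tn_sources]
    entries += [(s, "false_no_growth", True, False) for s in fn_sources]
    entries += [(s, "false_growth", False, True) for s in fp_sources]
    rng.shuffle(entries)

    classes = _class_assignment(spec, rng)
    rows: list[PlateRow] = []
    truth: dict[str, dict] = {}
    for (source, category, in_vitro, model_growth), substrate_class in zip(
        entries, classes
    ):
        rows.append(
            PlateRow(source, substrate_class, _replicates(in_vitro, spec, rng))
        )
        exchange_id = default_source_to_exchange(source)
        truth[source] = {
            "category": category,
            "exchange_id": exchange_id
            if model.has_reaction(exchange_id)
            else None,
            "model_growth": model_growth,
        }
    return PlateTable(rows), truth


# ---------------------------------------------------------------------------
# Planted activity matrices
# ---------------------------------------------------------------------------


def make_activity_solutions(
    n_always: int = 212,
    n_near_core: int = 41,
    n_type_associated: int = 188,
    n_source_specific: int = 221,
    n_never: int = 1553,
    n_solutions: int = 59,
    seed: int = 0,
) -> list[FluxSolution]:
    """Pooled flux solutions with a planted activity partition.

    Auxiliary reactions are active in ``ceil(0.9·n)`` solutions
    (near-core), ``round(n/2)`` (type-associated) or ``max(1, floor(0.1·n))``
    (source-specific); which particular solutions carry the flux is drawn
    per reaction.  Defaults mirror a 2215-reaction model pooled over 59
    carbon sources.
    """
    rng = np.random.default_rng(seed)
    active_counts: dict[str, int] = {}

    def add(prefix: str, count: int, active_in: int) -> None:
        for i in range(count):
            active_counts[f"{prefix}{i + 1:04d}"] = active_in

    near = min(n_solutions - 1, math.ceil(0.9 * n_solutions))
    rare = max(1, math.floor(0.1 * n_solutions))
    add("core", n_always, n_solutions)
    add("nearcore", n_near_core, near)
    add("typeassoc", n_type_associated, round(n_solutions / 2))
    add("specific", n_source_specific, rare)
    add("never", n_never, 0)

    membership = {
        rxn: set(rng.choice(n_solutions, size=k, replace=False).tolist())
        for rxn, k in active_counts.items()
    }
    solutions = []
    for s in range(n_solutions):
        fluxes = {
            rxn: (1.0 if s in membership[rxn] else 0.0) for rxn in active_counts
        }
        solutions.append(
            FluxSolution(status="optimal", objective_value=1.0, fluxes=fluxes)
        )
    return solutions
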