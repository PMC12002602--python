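"""Readers and writers for models and phenotype plates.

Three model serialisations are supported:

* **sbml** — SBML Level 3 Version 1 with the FBC v2 package (bounds,
  objective, gene products).  Files without FBC bounds fall back to the
  community defaults: reversible reactions get (−1000, 1000), irreversible
  (0, 1000).
* **json** — a package-defined dialect that mirrors the domain-type fields
  one-to-one, so externally hosted models in similar layouts can be
  converted with a documented mapping.
* **tsv** — a flat reaction table (columns: id, equation, lb, ub, gpr,
  subsystem) with the objective carried in a ``#! objective=`` header line.
  Metabolite compartments are recovered from the ``_e``/``_c``/``_m`` id
  suffix.  Names, formulas and annotations are not representable in this
  dialect and are dropped on write.

Phenotype-array plates are CSV files with header ``source,class,rep1..repN``
and boolean cells drawn from {0, 1, TRUE, FALSE, +, −}.

All writers sort ids so output is byte-stable for identical inputs; readers
never mutate their input files.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import libsbml

from .gem_core import (
    DEFAULT_BOUND,
    DEFAULT_COMPARTMENTS,
    Gene,
    GprAnd,
    GprEmpty,
    GprGene,
    GprNode,
    GprOr,
    MetabolicModel,
    Metabolite,
    ModelStructureError,
    Reaction,
    gene_set,
    parse_gpr,
)

__all__ = [
    "PlateTable",
    "PlateRow",
    "ModelReadError",
    "PlateReadError",
    "read_model",
    "write_model",
    "read_plate",
    "write_plate",
    "parse_equation",
    "SUBSTRATE_CLASSES",
]

MODEL_FORMATS = ("sbml", "json", "tsv")

#: Biolog substrate classes used for plate rows.
SUBSTRATE_CLASSES = (
    "amine/amide",
    "amino acid",
    "carboxylic acid",
    "carbohydrate",
    "polymer",
    "other",
)

_SBO_BY_KIND = {
    "internal": "SBO:0000375",
    "transport": "SBO:0000655",
    "exchange": "SBO:0000627",
    "demand": "SBO:0000628",
    "biomass": "SBO:0000629",
}
_KIND_BY_SBO = {v: k for k, v in _SBO_BY_KIND.items()}


class ModelReadError(ValueError):
    """Malformed model file (carries file/element context in the message)."""


class PlateReadError(ValueError):
    """Malformed phenotype plate CSV."""


# ---------------------------------------------------------------------------
# Phenotype plates
# ---------------------------------------------------------------------------


@dataclass
class PlateRow:
    source: str
    substrate_class: str
    replicate_calls: list[bool]


@dataclass
class PlateTable:
    rows: list[PlateRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for row in self.rows:
            if row.source in seen:
                raise PlateReadError(f"duplicate source id {row.source!r}")
            seen.add(row.source)
            if not row.replicate_calls:
                raise PlateReadError(
                    f"source {row.source!r} has no replicate calls"
                )

    @property
    def sources(self) -> list[str]:
        return [r.source for r in self.rows]

    def __len__(self) -> int:
        return len(self.rows)


_TRUTHY = {"1", "true", "+", "t"}
_FALSY = {"0", "false", "-", "−", "f"}


def _parse_call(cell: str, source: str, column: str) -> bool:
    text = cell.strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise PlateReadError(
        f"non-boolean cell {cell!r} at source {source!r}, column {column!r}"
    )


def read_plate(path: str | Path) -> PlateTable:
    """Read a Biolog-style plate CSV (``source,class,rep1..repN``)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise PlateReadError(f"{path}: empty plate file")
    header = [h.strip() for h in lines[0].split(",")]
    if len(header) < 3 or header[0] != "source" or header[1] != "class":
        raise PlateReadError(
            f"{path}: expected header 'source,class,rep1..repN', got {lines[0]!r}"
        )
    rep_columns = header[2:]
    rows: list[PlateRow] = []
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split(",")]
        if len(cells) != len(header):
            raise PlateReadError(
                f"{path}: row {cells[0]!r} has {len(cells)} cells, expected {len(header)}"
            )
        source, substrate_class = cells[0], cells[1]
        calls = [
            _parse_call(cell, source, col)
            for cell, col in zip(cells[2:], rep_columns)
        ]
        rows.append(PlateRow(source, substrate_class, calls))
    return PlateTable(rows)


def write_plate(plate: PlateTable, path: str | Path) -> None:
    path = Path(path)
    n_reps = max(len(r.replicate_calls) for r in plate.rows)
    header = "source,class," + ",".join(f"rep{i + 1}" for i in range(n_reps))
    lines = [header]
    for row in plate.rows:
        calls = ",".join("1" if c else "0" for c in row.replicate_calls)
        lines.append(f"{row.source},{row.substrate_class},{calls}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Reaction equation strings (TSV dialect)
# ---------------------------------------------------------------------------

_ARROWS = ("<->", "<=>", "->", "=>")


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse ``2 A_c + B_c -> C_c`` into a stoichiometry map.

    Returns (stoichiometry, reversible).  Either side may be empty
    (exchange/demand notation, e.g. ``glc_e ->``).
    """
    arrow = next((a for a in _ARROWS if a in equation), None)
    if arrow is None:
        raise ModelReadError(f"equation {equation!r} has no reaction arrow")
    reversible = arrow in ("<->", "<=>")
    lhs_text, rhs_text = equation.split(arrow, 1)
    stoich: dict[str, float] = {}

    def add_side(text: str, sign: float) -> None:
        text = text.strip()
        if not text:
            return
        for term in text.split("+"):
            term = term.strip()
            if not term:
                raise ModelReadError(f"empty term in equation {equation!r}")
            parts = term.split()
            if len(parts) == 1:
                coef, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError as exc:
                    raise ModelReadError(
                        f"bad coefficient {parts[0]!r} in equation {equation!r}"
                    ) from exc
                met = parts[1]
            else:
                raise ModelReadError(f"bad term {term!r} in equation {equation!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(lhs_text, -1.0)
    add_side(rhs_text, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise ModelReadError(f"equation {equation!r} has empty stoichiometry")
    return stoich, reversible


def _compartment_from_id(met_id: str) -> str:
    for suffix in DEFAULT_COMPARTMENTS:
        if met_id.endswith(f"_{suffix}"):
            return suffix
    return "c"


def _infer_kind(rxn_id: str, stoich: dict[str, float], objective: str) -> str:
    if rxn_id == objective:
        return "biomass"
    if len(stoich) == 1:
        return "demand" if rxn_id.startswith("DM_") else "exchange"
    compartments = {_compartment_from_id(m) for m in stoich}
    return "transport" if len(compartments) > 1 else "internal"


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------


def _model_to_json_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "compartments": dict(sorted(model.compartments.items())),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "annotations": dict(sorted(m.annotations.items())),
            }
            for m in sorted(model.metabolites, key=lambda m: m.id)
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr,
                "kind": r.kind,
                "annotations": dict(sorted(r.annotations.items())),
            }
            for r in sorted(model.reactions, key=lambda r: r.id)
        ],
        "genes": [
            {"id": g.id, "name": g.name}
            for g in sorted(model.genes, key=lambda g: g.id)
        ],
        "objective_reaction": model.objective_reaction,
    }


def _model_from_json_dict(data: dict, context: str) -> MetabolicModel:
    try:
        metabolites = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula"),
                annotations=dict(m.get("annotations", {})),
            )
            for m in data["metabolites"]
        ]
        reactions = [
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                gpr=r.get("gpr", ""),
                kind=r.get("kind", "internal"),
                annotations=dict(r.get("annotations", {})),
            )
            for r in data["reactions"]
        ]
        genes = [Gene(id=g["id"], name=g.get("name", "")) for g in data.get("genes", [])]
        objective = data.get("objective_reaction", "")
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelReadError(f"{context}: malformed model JSON ({exc})") from exc
    if not objective:
        raise ModelReadError(f"{context}: missing objective_reaction")
    model = MetabolicModel(
        id=data.get("id", "model"),
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        compartments=dict(data.get("compartments", DEFAULT_COMPARTMENTS)),
        objective_reaction=objective,
    )
    if not model.has_reaction(objective):
        raise ModelReadError(
            f"{context}: objective reaction {objective!r} not in model"
        )
    return model


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_TSV_HEADER = "id\tequation\tlb\tub\tgpr\tsubsystem"


def _model_to_tsv(model: MetabolicModel) -> str:
    lines = [
        f"#! model={model.id}",
        f"#! objective={model.objective_reaction}",
        _TSV_HEADER,
    ]
    for rxn in sorted(model.reactions, key=lambda r: r.id):
        lines.append(
            "\t".join(
                [
                    rxn.id,
                    rxn.equation(),
                    f"{rxn.lower_bound:g}",
                    f"{rxn.upper_bound:g}",
                    rxn.gpr,
                    rxn.kind,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def _model_from_tsv(text: str, context: str) -> MetabolicModel:
    model_id, objective = "model", ""
    reactions: list[Reaction] = []
    header_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#!"):
            key, _, value = line[2:].strip().partition("=")
            if key == "model":
                model_id = value
            elif key == "objective":
                objective = value
            continue
        if line.startswith("#"):
            continue
        if not header_seen:
            if line.strip() != _TSV_HEADER.replace("\t", "\t").strip():
                # tolerate arbitrary whitespace in the header
                if [c.strip() for c in line.split("\t")] != _TSV_HEADER.split("\t"):
                    raise ModelReadError(
                        f"{context}:{lineno}: unexpected TSV header {line!r}"
                    )
            header_seen = True
            continue
        cells = line.split("\t")
        if len(cells) != 6:
            raise ModelReadError(
                f"{context}:{lineno}: expected 6 tab-separated columns, got {len(cells)}"
            )
        rxn_id, equation, lb, ub, gpr, subsystem = (c.strip() for c in cells)
        try:
            stoich, reversible = parse_equation(equation)
            lower, upper = float(lb), float(ub)
        except (ModelReadError, ValueError) as exc:
            raise ModelReadError(f"{context}:{lineno}: {exc}") from exc
        kind = (
            subsystem
            if subsystem in _SBO_BY_KIND
            else _infer_kind(rxn_id, stoich, objective)
        )
        reactions.append(
            Reaction(
                id=rxn_id,
                stoichiometry=stoich,
                lower_bound=lower,
                upper_bound=upper,
                gpr=gpr,
                kind=kind,
            )
        )
    if not objective:
        raise ModelReadError(f"{context}: missing '#! objective=' header line")
    if any(r.id == objective for r in reactions) is False:
        raise ModelReadError(f"{context}: objective {objective!r} not in table")
    met_ids = sorted({m for r in reactions for m in r.stoichiometry})
    metabolites = [
        Metabolite(id=m, compartment=_compartment_from_id(m)) for m in met_ids
    ]
    genes = sorted({g for r in reactions for g in gene_set(r.gpr)})
    seen_rxn: set[str] = set()
    for r in reactions:
        if r.id in seen_rxn:
            raise ModelReadError(f"{context}: duplicate reaction id {r.id!r}")
        seen_rxn.add(r.id)
    return MetabolicModel(
        id=model_id,
        metabolites=metabolites,
        reactions=reactions,
        genes=[Gene(id=g) for g in genes],
        objective_reaction=objective,
    )


# ---------------------------------------------------------------------------
# SBML L3V1 + FBC v2
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _formula_to_string(formula: dict[str, int]) -> str:
    # Hill order: C, H, then alphabetical.
    keys = sorted(formula, key=lambda e: (e != "C", e != "H", e))
    return "".join(
        f"{el}{formula[el] if formula[el] != 1 else ''}" for el in keys
    )


def _formula_from_string(text: str) -> dict[str, int] | None:
    if not text:
        return None
    out: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos:
            return None  # unparseable formula: drop rather than fail the load
        out[m.group(1)] = int(m.group(2) or 1)
        pos = m.end()
    return out


def _gpr_to_fbc(node: GprNode, parent) -> None:
    if isinstance(node, GprGene):
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(_sbml_gene_id(node.gene_id))
    elif isinstance(node, GprAnd):
        assoc = parent.createAnd()
        for child in node.children:
            _gpr_to_fbc(child, assoc)
    elif isinstance(node, GprOr):
        assoc = parent.createOr()
        for child in node.children:
            _gpr_to_fbc(child, assoc)


def _fbc_to_gpr_string(assoc, label_by_id: dict[str, str]) -> str:
    if assoc is None:
        return ""
    if assoc.isGeneProductRef():
        gid = assoc.getGeneProduct()
        return label_by_id.get(gid, gid)
    children = [
        _fbc_to_gpr_string(assoc.getAssociation(i), label_by_id)
        for i in range(assoc.getNumAssociations())
    ]
    joiner = " and " if assoc.isFbcAnd() else " or "
    return "(" + joiner.join(children) + ")"


def _sbml_safe(identifier: str) -> str:
    safe = re.sub(r"[^A-Za-z0-9_]", "_", identifier)
    if not safe or not (safe[0].isalpha() or safe[0] == "_"):
        safe = "x_" + safe
    return safe


def _sbml_gene_id(gene_id: str) -> str:
    return "G_" + _sbml_safe(gene_id)


def _check(status, what: str) -> None:
    if status is None or (isinstance(status, int) and status < 0):
        raise ModelReadError(f"libsbml failure while {what}")


def _model_to_sbml(model: MetabolicModel) -> str:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sbml_safe(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for cid, cname in sorted(model.compartments.items()):
        comp = sbml_model.createCompartment()
        comp.setId(cid)
        comp.setName(cname)
        comp.setConstant(True)

    for met in sorted(model.metabolites, key=lambda m: m.id):
        sp = sbml_model.createSpecies()
        sp.setId("M_" + _sbml_safe(met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setInitialConcentration(0.0)
        if met.formula:
            sp.getPlugin("fbc").setChemicalFormula(
                _formula_to_string(met.formula)
            )
        if met.annotations:
            sp.appendNotes(_annotations_to_notes(met.annotations))

    genes_needed = sorted(
        {g for r in model.reactions for g in gene_set(r.gpr)}
        | {g.id for g in model.genes}
    )
    names = {g.id: g.name for g in model.genes}
    for gid in genes_needed:
        gp = mplug.createGeneProduct()
        gp.setId(_sbml_gene_id(gid))
        gp.setLabel(gid)
        if names.get(gid):
            gp.setName(names[gid])

    # Shared bound parameters, one per distinct value.
    bound_param: dict[float, str] = {}

    def bound_id(value: float) -> str:
        if value not in bound_param:
            pid = f"fb_{len(bound_param)}"
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_param[value] = pid
        return bound_param[value]

    for rxn in sorted(model.reactions, key=lambda r: r.id):
        sr = sbml_model.createReaction()
        sr.setId("R_" + _sbml_safe(rxn.id))
        sr.setName(rxn.name or rxn.id)
        sr.setFast(False)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setSBOTerm(_SBO_BY_KIND[rxn.kind])
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_id(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_id(rxn.upper_bound))
        for met_id, coef in sorted(rxn.stoichiometry.items()):
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies("M_" + _sbml_safe(met_id))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        tree = parse_gpr(rxn.gpr)
        if not isinstance(tree, GprEmpty):
            gpa = rplug.createGeneProductAssociation()
            _gpr_to_fbc(tree, gpa)
        if rxn.annotations:
            sr.appendNotes(_annotations_to_notes(rxn.annotations))

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    flux_obj = objective.createFluxObjective()
    flux_obj.setReaction("R_" + _sbml_safe(model.objective_reaction))
    flux_obj.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    return libsbml.writeSBMLToString(doc)


def _annotations_to_notes(annotations: dict[str, str]) -> str:
    items = "".join(
        f"<p>{k}: {v}</p>" for k, v in sorted(annotations.items())
    )
    return (
        '<body xmlns="http://www.w3.org/1999/xhtml">' + items + "</body>"
    )


_NOTE_LINE = re.compile(r"<p>\s*([^:<]+):\s*([^<]*)</p>")


def _annotations_from_notes(notes: str) -> dict[str, str]:
    if not notes:
        return {}
    return {
        k.strip(): v.strip() for k, v in _NOTE_LINE.findall(notes)
    }


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _model_from_sbml(text: str, context: str) -> MetabolicModel:
    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelReadError(
            f"{context}: SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelReadError(f"{context}: no model element in SBML document")
    mplug = sbml_model.getPlugin("fbc")

    compartments = dict(DEFAULT_COMPARTMENTS)
    for i in range(sbml_model.getNumCompartments()):
        comp = sbml_model.getCompartment(i)
        compartments[comp.getId()] = comp.getName() or comp.getId()

    metabolites: list[Metabolite] = []
    species_to_id: dict[str, str] = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        met_id = _strip_prefix(sp.getId(), "M_")
        species_to_id[sp.getId()] = met_id
        formula = None
        splug = sp.getPlugin("fbc")
        if splug is not None and splug.isSetChemicalFormula():
            formula = _formula_from_string(splug.getChemicalFormula())
        metabolites.append(
            Metabolite(
                id=met_id,
                name="" if sp.getName() == met_id else sp.getName(),
                compartment=sp.getCompartment() or "c",
                formula=formula,
                annotations=_annotations_from_notes(sp.getNotesString()),
            )
        )

    label_by_gene: dict[str, str] = {}
    genes: list[Gene] = []
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            label = gp.getLabel() or gp.getId()
            label_by_gene[gp.getId()] = label
            genes.append(Gene(id=label, name=gp.getName() or ""))

    parameters = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    objective_reaction = ""
    if mplug is not None and mplug.getNumObjectives() > 0:
        active = mplug.getActiveObjective() or mplug.getObjective(0)
        if active is not None and active.getNumFluxObjectives() > 0:
            objective_reaction = _strip_prefix(
                active.getFluxObjective(0).getReaction(), "R_"
            )

    reactions: list[Reaction] = []
    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        rxn_id = _strip_prefix(sr.getId(), "R_")
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            met = species_to_id.get(ref.getSpecies(), ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            met = species_to_id.get(ref.getSpecies(), ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        if (
            rplug is not None
            and rplug.isSetLowerFluxBound()
            and rplug.getLowerFluxBound() in parameters
        ):
            lower = parameters[rplug.getLowerFluxBound()]
            upper = parameters.get(rplug.getUpperFluxBound(), DEFAULT_BOUND)
        else:
            # No FBC bounds: documented defaults from reversibility.
            lower = -DEFAULT_BOUND if sr.getReversible() else 0.0
            upper = DEFAULT_BOUND
        gpr = ""
        if rplug is not None and rplug.isSetGeneProductAssociation():
            gpr = _fbc_to_gpr_string(
                rplug.getGeneProductAssociation().getAssociation(), label_by_gene
            )
            if gpr.startswith("(") and gpr.endswith(")"):
                gpr = gpr[1:-1]
        sbo = sr.getSBOTermID() if sr.isSetSBOTerm() else ""
        kind = _KIND_BY_SBO.get(sbo) or _infer_kind(
            rxn_id, stoich, objective_reaction
        )
        name = sr.getName()
        reactions.append(
            Reaction(
                id=rxn_id,
                name="" if name == rxn_id else name,
                stoichiometry=stoich,
                lower_bound=float(lower),
                upper_bound=float(upper),
                gpr=gpr,
                kind=kind,
                annotations=_annotations_from_notes(sr.getNotesString()),
            )
        )

    if not objective_reaction:
        raise ModelReadError(f"{context}: SBML file declares no flux objective")
    if not genes:
        gene_ids = sorted({g for r in reactions for g in gene_set(r.gpr)})
        genes = [Gene(id=g) for g in gene_ids]
    return MetabolicModel(
        id=sbml_model.getId() or "model",
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        compartments=compartments,
        objective_reaction=objective_reaction,
    )


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------


def _detect_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in MODEL_FORMATS:
            raise ValueError(f"unknown model format {format!r}")
        return format
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise ValueError(f"cannot infer model format from path {path}")


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a model from SBML, JSON or TSV (format inferred from suffix)."""
    path = Path(path)
    fmt = _detect_format(path, format)
    text = path.read_text()
    if fmt == "sbml":
        return _model_from_sbml(text, str(path))
    if fmt == "json":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ModelReadError(f"{path}: invalid JSON ({exc})") from exc
        return _model_from_json_dict(data, str(path))
    return _model_from_tsv(text, str(path))


def write_model(
    model: MetabolicModel, path: str | Path, format: str | None = None
) -> None:
    """Serialise a model; output is byte-stable for identical inputs."""
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "sbml":
        path.write_text(_model_to_sbml(model))
    elif fmt == "json":
        path.write_text(
            json.dumps(_model_to_json_dict(model), indent=1, sort_keys=False)
            + "\n"
        )
    else:
        path.write_text(_model_to_tsv(model))
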