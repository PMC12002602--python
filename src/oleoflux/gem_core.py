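"""Core domain types for genome-scale metabolic models.

A :class:`MetabolicModel` is a plain in-memory network: metabolites assigned
to compartments, reactions with signed stoichiometry, flux bounds and
optional gene-protein-reaction (GPR) rules, and a declared objective
reaction.  Structural operations — stoichiometric matrix assembly, model
validation, GPR parsing and dead-end ("orphan") stripping — live here;
anything that needs a linear-programming solve lives in
:mod:`oleoflux.fba_engine`.

Conventions
-----------
* Flux units are mmol·gDW⁻¹·h⁻¹ throughout; biomass objectives are h⁻¹.
* Stoichiometric coefficients are negative for consumed metabolites.
* Exchange and demand reactions touch exactly one metabolite; exchanges are
  written in the export direction ("met_e →"), so uptake is negative flux.
* Compartment ids follow the suffix convention ``_e`` (extracellular),
  ``_c`` (cytosol), ``_m`` (mitochondrion) when models are serialised to
  flat formats.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Metabolite",
    "Reaction",
    "Gene",
    "MetabolicModel",
    "ValidationReport",
    "StoichiometricMatrix",
    "GprNode",
    "GprGene",
    "GprAnd",
    "GprOr",
    "GprEmpty",
    "GprParseError",
    "ModelStructureError",
    "DEFAULT_COMPARTMENTS",
    "DEFAULT_BOUND",
    "parse_gpr",
    "gene_set",
    "build_stoichiometric_matrix",
    "validate_model",
    "slim_model",
]

#: Default flux-bound magnitude (community convention).
DEFAULT_BOUND = 1000.0

#: Built-in compartment registry; models may extend it.
DEFAULT_COMPARTMENTS = {
    "e": "extracellular",
    "c": "cytosol",
    "m": "mitochondrion",
}

REACTION_KINDS = ("internal", "transport", "exchange", "demand", "biomass")


class ModelStructureError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: dict[str, int] | None = None
    annotations: dict[str, str] = field(default_factory=dict)


@dataclass
class Reaction:
    """A reaction with signed stoichiometry and flux bounds.

    ``stoichiometry`` maps metabolite id to a signed real coefficient
    (negative = consumed).  ``gpr`` is the raw boolean rule string
    ("g1 and (g2 or g3)"); parse it with :func:`parse_gpr`.
    """

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    kind: str = "internal"
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ModelStructureError(
                f"reaction {self.id!r}: unknown kind {self.kind!r}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def equation(self) -> str:
        """Human-readable equation string, e.g. ``A_c + 2 B_c -> C_c``."""
        lhs, rhs = [], []
        for met, coef in sorted(self.stoichiometry.items()):
            mag = abs(coef)
            term = met if mag == 1 else f"{mag:g} {met}"
            (lhs if coef < 0 else rhs).append(term)
        arrow = "<->" if self.reversible else "->"
        return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


@dataclass
class Gene:
    id: str
    name: str = ""


@dataclass
class ValidationReport:
    """Findings from :func:`validate_model`; findings are data, not errors."""

    dangling_metabolite_ids: list[str] = field(default_factory=list)
    orphan_metabolite_ids: list[str] = field(default_factory=list)
    duplicate_ids: list[str] = field(default_factory=list)
    unbounded_exchange_ids: list[str] = field(default_factory=list)
    invalid_bound_ids: list[str] = field(default_factory=list)
    unresolved_metabolite_refs: list[str] = field(default_factory=list)
    gpr_parse_errors: dict[str, str] = field(default_factory=dict)

    def is_empty(self) -> bool:
        return not any(
            (
                self.dangling_metabolite_ids,
                self.orphan_metabolite_ids,
                self.duplicate_ids,
                self.unbounded_exchange_ids,
                self.invalid_bound_ids,
                self.unresolved_metabolite_refs,
                self.gpr_parse_errors,
            )
        )


@dataclass
class MetabolicModel:
    id: str = "model"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[Gene] = field(default_factory=list)
    compartments: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENTS)
    )
    objective_reaction: str = ""

    def __post_init__(self) -> None:
        self._check_unique("metabolite", [m.id for m in self.metabolites])
        self._check_unique("reaction", [r.id for r in self.reactions])
        self._check_unique("gene", [g.id for g in self.genes])

    @staticmethod
    def _check_unique(what: str, ids: Sequence[str]) -> None:
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise ModelStructureError(f"duplicate {what} id {i!r}")
            seen.add(i)

    # -- lookups -----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def gene_ids(self) -> list[str]:
        return [g.id for g in self.genes]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind in ("exchange", "demand")]

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# GPR parsing
# ---------------------------------------------------------------------------


class GprParseError(ValueError):
    """Malformed GPR expression; carries the character position."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


class GprNode:
    """Base class of the boolean expression tree over gene ids."""

    def evaluate(self, present: set[str]) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError

    def genes(self) -> set[str]:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class GprEmpty(GprNode):
    """Absent rule: no gene requirement (evaluates true, empty gene set)."""

    def evaluate(self, present: set[str]) -> bool:
        return True

    def genes(self) -> set[str]:
        return set()


@dataclass(frozen=True)
class GprGene(GprNode):
    gene_id: str

    def evaluate(self, present: set[str]) -> bool:
        return self.gene_id in present

    def genes(self) -> set[str]:
        return {self.gene_id}


@dataclass(frozen=True)
class GprAnd(GprNode):
    children: tuple[GprNode, ...]

    def evaluate(self, present: set[str]) -> bool:
        return all(c.evaluate(present) for c in self.children)

    def genes(self) -> set[str]:
        return set().union(*(c.genes() for c in self.children))


@dataclass(frozen=True)
class GprOr(GprNode):
    children: tuple[GprNode, ...]

    def evaluate(self, present: set[str]) -> bool:
        return any(c.evaluate(present) for c in self.children)

    def genes(self) -> set[str]:
        return set().union(*(c.genes() for c in self.children))


_GPR_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.\-]+)")


def _tokenise_gpr(expression: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(expression):
        m = _GPR_TOKEN.match(expression, pos)
        if m is None:
            stripped = expression[pos:].lstrip()
            if not stripped:
                break
            raise GprParseError(
                f"unexpected character {stripped[0]!r}", pos
            )
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(expression: str | None) -> GprNode:
    """Parse a GPR rule into a boolean expression tree.

    Grammar: identifiers ``[A-Za-z0-9_.-]+``, ``and``/``or``
    (case-insensitive), parentheses; ``and`` binds tighter than ``or``
    (SBML-FBC convention).  An empty or ``None`` expression yields
    :class:`GprEmpty`.
    """
    if expression is None or not expression.strip():
        return GprEmpty()
    tokens = _tokenise_gpr(expression)
    idx = 0

    def peek() -> tuple[str, int] | None:
        return tokens[idx] if idx < len(tokens) else None

    def parse_or() -> GprNode:
        nonlocal idx
        children = [parse_and()]
        while (tok := peek()) is not None and tok[0].lower() == "or":
            idx += 1
            children.append(parse_and())
        return children[0] if len(children) == 1 else GprOr(tuple(children))

    def parse_and() -> GprNode:
        nonlocal idx
        children = [parse_atom()]
        while (tok := peek()) is not None and tok[0].lower() == "and":
            idx += 1
            children.append(parse_atom())
        return children[0] if len(children) == 1 else GprAnd(tuple(children))

    def parse_atom() -> GprNode:
        nonlocal idx
        tok = peek()
        if tok is None:
            raise GprParseError("unexpected end of expression", len(expression))
        text, pos = tok
        if text == "(":
            idx += 1
            node = parse_or()
            closing = peek()
            if closing is None or closing[0] != ")":
                raise GprParseError("unbalanced parenthesis", pos)
            idx += 1
            return node
        if text == ")" or text.lower() in ("and", "or"):
            raise GprParseError(f"unexpected token {text!r}", pos)
        idx += 1
        return GprGene(text)

    tree = parse_or()
    if idx != len(tokens):
        raise GprParseError(f"trailing token {tokens[idx][0]!r}", tokens[idx][1])
    return tree


def gene_set(node_or_expression: GprNode | str | None) -> set[str]:
    """All gene ids referenced by a GPR rule (tree or raw string)."""
    if isinstance(node_or_expression, GprNode):
        return node_or_expression.genes()
    return parse_gpr(node_or_expression).genes()


# ---------------------------------------------------------------------------
# Stoichiometric matrix
# ---------------------------------------------------------------------------


@dataclass
class StoichiometricMatrix:
    """Sparse S matrix (metabolites × reactions) with id indexes."""

    matrix: sp.csr_matrix
    metabolite_ids: list[str]
    reaction_ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def to_dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def coefficient(self, met_id: str, rxn_id: str) -> float:
        i = self.metabolite_ids.index(met_id)
        j = self.reaction_ids.index(rxn_id)
        return float(self.matrix[i, j])

    def reconstruct_stoichiometries(self) -> dict[str, dict[str, float]]:
        """Invert the matrix build: reaction id → stoichiometry map."""
        csc = self.matrix.tocsc()
        out: dict[str, dict[str, float]] = {}
        for j, rxn in enumerate(self.reaction_ids):
            col = csc.getcol(j).tocoo()
            out[rxn] = {
                self.metabolite_ids[i]: float(v) for i, v in zip(col.row, col.data)
            }
        return out


def build_stoichiometric_matrix(model: MetabolicModel) -> StoichiometricMatrix:
    """Assemble S with entry (i, j) = coefficient of metabolite i in reaction j.

    Raises :class:`ModelStructureError` naming the reaction if any
    stoichiometry key does not resolve to a model metabolite.
    """
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            if met_id not in met_index:
                raise ModelStructureError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
            rows.append(met_index[met_id])
            cols.append(j)
            data.append(float(coef))
    matrix = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )
    return StoichiometricMatrix(matrix, model.metabolite_ids, model.reaction_ids)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _participation_counts(model: MetabolicModel) -> dict[str, int]:
    counts = {m.id: 0 for m in model.metabolites}
    for rxn in model.reactions:
        for met_id in rxn.stoichiometry:
            if met_id in counts:
                counts[met_id] += 1
    return counts


def validate_model(model: MetabolicModel) -> ValidationReport:
    """Structural audit: dead ends, dangling metabolites, bad bounds, GPR errors.

    Orphan metabolites participate in exactly one reaction (classic dead
    ends); dangling metabolites participate in none.  The two categories are
    disjoint by construction.
    """
    report = ValidationReport()
    counts = _participation_counts(model)
    for met_id, n in counts.items():
        if n == 0:
            report.dangling_metabolite_ids.append(met_id)
        elif n == 1:
            report.orphan_metabolite_ids.append(met_id)

    met_ids = set(counts)
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            report.invalid_bound_ids.append(rxn.id)
        for met_id in rxn.stoichiometry:
            if met_id not in met_ids:
                report.unresolved_metabolite_refs.append(f"{rxn.id}:{met_id}")
        if rxn.kind in ("exchange", "demand") and len(rxn.stoichiometry) != 1:
            report.unbounded_exchange_ids.append(rxn.id)
        if rxn.gpr:
            try:
                parse_gpr(rxn.gpr)
            except GprParseError as exc:
                report.gpr_parse_errors[rxn.id] = str(exc)
    return report


# ---------------------------------------------------------------------------
# Orphan stripping ("slim" models)
# ---------------------------------------------------------------------------


def slim_model(
    model: MetabolicModel, *, fixed_point: bool = True
) -> MetabolicModel:
    """Strip dead-end metabolites and their reactions.

    A metabolite participating in exactly one reaction is removed together
    with that reaction.  With ``fixed_point=True`` (default) removal is
    iterated until no dead end remains, since stripping one reaction can
    strand further metabolites; ``fixed_point=False`` applies a single pass.
    The objective reaction is protected: if stripping would remove it, the
    operation refuses with a diagnostic.  The input model is untouched.
    """
    slim = model.copy()
    initially_dangling = {
        m for m, n in _participation_counts(slim).items() if n == 0
    }
    removed_any = False
    while True:
        counts = _participation_counts(slim)
        orphans = {m for m, n in counts.items() if n == 1}
        if not orphans:
            break
        doomed_rxns = {
            r.id
            for r in slim.reactions
            if any(m in orphans for m in r.stoichiometry)
        }
        if slim.objective_reaction in doomed_rxns:
            raise ModelStructureError(
                "slim_model would remove the objective reaction "
                f"{slim.objective_reaction!r}; refusing"
            )
        slim.reactions = [r for r in slim.reactions if r.id not in doomed_rxns]
        slim.metabolites = [m for m in slim.metabolites if m.id not in orphans]
        removed_any = True
        if not fixed_point:
            break
    # Drop metabolites stranded by the stripping itself (now in zero
    # reactions); metabolites that were already dangling on entry are kept so
    # an orphan-free model round-trips unchanged.
    counts = _participation_counts(slim)
    slim.metabolites = [
        m
        for m in slim.metabolites
        if counts[m.id] > 0 or m.id in initially_dangling
    ]
    if removed_any:
        referenced_genes: set[str] = set()
        for rxn in slim.reactions:
            referenced_genes |= gene_set(rxn.gpr)
        slim.genes = [g for g in slim.genes if g.id in referenced_genes]
    return slim
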