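"""Linear-programming core: FBA, parsimonious FBA and growth-rate prediction.

Flux balance analysis solves

    max  c·v   subject to   S·v = 0,   lb ≤ v ≤ ub

with HiGHS (``scipy.optimize.linprog``).  Parsimonious FBA (pFBA) re-solves
with the objective pinned at its optimum and total absolute flux minimised
via the standard positive/negative flux split; it yields a deterministic
flux support, which matters because plain LP optima of genome-scale models
are heavily degenerate and their active sets are solver-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .gem_core import MetabolicModel, build_stoichiometric_matrix

__all__ = [
    "FluxSolution",
    "ACTIVITY_EPSILON",
    "GROWTH_THRESHOLD",
    "FEASIBILITY_TOL",
    "solve_fba",
    "solve_pfba",
    "predict_growth_rate",
    "growth_call",
]

#: |flux| above which a reaction counts as active (mmol·gDW⁻¹·h⁻¹).
ACTIVITY_EPSILON = 1e-6
#: Objective value above which a solution counts as growth (h⁻¹).
GROWTH_THRESHOLD = 1e-6
#: Componentwise steady-state tolerance on S·v.
FEASIBILITY_TOL = 1e-9
#: Tolerance when pinning the primary objective during pFBA.
_FIX_TOL = 1e-9


@dataclass
class FluxSolution:
    """Outcome of one LP solve.

    ``status`` is one of ``optimal``, ``infeasible`` or ``unbounded``;
    solver failures are reported through ``status``/``message``, never as
    exceptions.
    """

    status: str
    objective_value: float = 0.0
    fluxes: dict[str, float] = field(default_factory=dict)
    message: str = ""
    activity_epsilon: float = ACTIVITY_EPSILON

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    @property
    def active_set(self) -> set[str]:
        return {
            r for r, v in self.fluxes.items() if abs(v) > self.activity_epsilon
        }

    def flux(self, rxn_id: str) -> float:
        return self.fluxes.get(rxn_id, 0.0)


_STATUS_BY_CODE = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded"}


def _lp_status(result) -> str:
    return _STATUS_BY_CODE.get(result.status, "failed")


def _bounds(model: MetabolicModel) -> list[tuple[float, float]]:
    return [(r.lower_bound, r.upper_bound) for r in model.reactions]


def solve_fba(
    model: MetabolicModel,
    objective: str | None = None,
    sense: str = "max",
) -> FluxSolution:
    """Maximise (or minimise) one reaction's flux at steady state.

    ``objective`` defaults to the model's declared objective reaction.
    Infeasible and unbounded instances come back as a status, not an
    exception.
    """
    objective = objective or model.objective_reaction
    if not model.has_reaction(objective):
        raise KeyError(f"objective reaction {objective!r} not in model")
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")

    smat = build_stoichiometric_matrix(model)
    n = len(model.reactions)
    c = np.zeros(n)
    j = model.reaction_ids.index(objective)
    c[j] = -1.0 if sense == "max" else 1.0

    result = linprog(
        c,
        A_eq=smat.matrix,
        b_eq=np.zeros(smat.shape[0]),
        bounds=_bounds(model),
        method="highs",
    )
    status = _lp_status(result)
    if status != "optimal":
        return FluxSolution(status=status, message=result.message)
    fluxes = dict(zip(model.reaction_ids, (float(v) for v in result.x)))
    return FluxSolution(
        status="optimal",
        objective_value=float(fluxes[objective]),
        fluxes=fluxes,
        message=result.message,
    )


def solve_pfba(
    model: MetabolicModel,
    objective: str | None = None,
    fix_tol: float = _FIX_TOL,
) -> FluxSolution:
    """FBA followed by total-flux minimisation at the fixed optimum.

    Splits each flux v = p − q with p, q ≥ 0 and minimises Σ(p + q) subject
    to S·(p − q) = 0, the original bounds, and the primary objective pinned
    to its FBA optimum (± ``fix_tol``).  The reported objective value is the
    pinned optimum; fluxes are the parsimonious distribution.
    """
    objective = objective or model.objective_reaction
    primary = solve_fba(model, objective)
    if not primary.optimal:
        return primary

    smat = build_stoichiometric_matrix(model)
    n = len(model.reactions)
    j = model.reaction_ids.index(objective)
    opt = primary.objective_value

    # Variables x = [p; q], v = p - q.
    A_eq = sp.hstack([smat.matrix, -smat.matrix]).tocsr()
    b_eq = np.zeros(smat.shape[0])
    bounds: list[tuple[float, float]] = []
    for rxn in model.reactions:
        lb, ub = rxn.lower_bound, rxn.upper_bound
        bounds.append((max(lb, 0.0), max(ub, 0.0)))  # p
    for rxn in model.reactions:
        lb, ub = rxn.lower_bound, rxn.upper_bound
        bounds.append((max(-ub, 0.0), max(-lb, 0.0)))  # q

    # Pin the primary objective: opt - tol <= v_j <= opt + tol.
    pin = sp.lil_matrix((1, 2 * n))
    pin[0, j] = 1.0
    pin[0, n + j] = -1.0
    A_ub = sp.vstack([pin, -pin]).tocsr()
    slack = fix_tol * max(1.0, abs(opt))
    b_ub = np.array([opt + slack, -(opt - slack)])

    c = np.ones(2 * n)
    result = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    status = _lp_status(result)
    if status != "optimal":
        return FluxSolution(status=status, message=result.message)
    p = result.x[:n]
    q = result.x[n:]
    v = p - q
    fluxes = dict(zip(model.reaction_ids, (float(x) for x in v)))
    return FluxSolution(
        status="optimal",
        objective_value=float(opt),
        fluxes=fluxes,
        message=result.message,
    )


def predict_growth_rate(
    model: MetabolicModel,
    carbon_exchange: str,
    uptake_rate: float,
    objective: str | None = None,
) -> tuple[float, FluxSolution]:
    """Predicted growth rate μ (h⁻¹) at a given carbon uptake rate.

    Sets the carbon exchange's lower bound to −uptake_rate (uptake-negative
    convention) and maximises biomass.  An infeasible medium yields μ = 0
    with the status carried on the returned solution.
    """
    if uptake_rate < 0:
        raise ValueError("uptake_rate must be non-negative")
    if not model.has_reaction(carbon_exchange):
        raise KeyError(f"carbon exchange {carbon_exchange!r} not in model")
    constrained = model.copy()
    constrained.reaction(carbon_exchange).lower_bound = -uptake_rate
    solution = solve_fba(constrained, objective)
    mu = solution.objective_value if solution.optimal else 0.0
    return mu, solution


def growth_call(
    solution: FluxSolution, growth_threshold: float = GROWTH_THRESHOLD
) -> bool:
    """True iff the solution is optimal with objective above the threshold."""
    return solution.optimal and solution.objective_value > growth_threshold
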