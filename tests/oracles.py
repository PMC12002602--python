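"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the vertex enumerator
solves the flux LP by brute force over candidate basic solutions instead of
calling an LP solver.
"""

from __future__ import annotations

import itertools

import numpy as np

from oleoflux.gem_core import MetabolicModel, build_stoichiometric_matrix


def brute_force_fba_optimum(
    model: MetabolicModel, objective: str, tol: float = 1e-9
) -> float:
    """Maximum of the objective flux over {S·v = 0, lb ≤ v ≤ ub}.

    Enumerates candidate vertices: every choice of n − rank(S) variables
    fixed at one of their bounds, with the remaining (basic) variables
    solved from the steady-state system.  The optimum of a bounded feasible
    LP is attained at such a point.  Exponential — only for tiny models.
    """
    S = build_stoichiometric_matrix(model).to_dense()
    n = S.shape[1]
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    j_obj = model.reaction_ids.index(objective)
    rank = np.linalg.matrix_rank(S)
    n_fixed = n - rank

    best = None
    for fixed in itertools.combinations(range(n), n_fixed):
        basic = [j for j in range(n) if j not in fixed]
        S_b = S[:, basic]
        if np.linalg.matrix_rank(S_b) < rank:
            continue
        for pattern in itertools.product((0, 1), repeat=n_fixed):
            v = np.empty(n)
            for j, side in zip(fixed, pattern):
                v[j] = lb[j] if side == 0 else ub[j]
            rhs = -S[:, fixed] @ v[list(fixed)] if n_fixed else np.zeros(S.shape[0])
            sol, *_ = np.linalg.lstsq(S_b, rhs, rcond=None)
            v[basic] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            if best is None or v[j_obj] > best:
                best = v[j_obj]
    if best is None:
        raise ValueError("LP infeasible under brute-force enumeration")
    return float(best)


def cobra_fba_optimum(model: MetabolicModel, tmp_path) -> float:
    """Reference FBA optimum from an independent implementation (cobrapy)."""
    import cobra
    from oleoflux.model_io import write_model

    path = tmp_path / f"{model.id}_oracle.xml"
    write_model(model, path)
    cobra_model = cobra.io.read_sbml_model(str(path))
    value = cobra_model.slim_optimize()
    return float(value)
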