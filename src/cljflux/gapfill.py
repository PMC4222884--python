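"""Minimal-reaction gap-filling.

Given a model whose objective is infeasible (or below a producibility
threshold) and a universal reaction pool, find the smallest sets of pool
reactions whose addition restores the objective.  The search is a mixed-
integer LP: binary indicators gate the bounds of candidate reactions and
the indicator sum is minimized; alternate minimal sets are enumerated
with integer cuts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import LinearConstraint, milp
from scipy.optimize import Bounds as OptBounds

from .errors import NoFillExistsError, SolverError
from .fba import fba
from .model import MetabolicModel, Reaction, build_model, stoichiometric_matrix

__all__ = ["GapfillResult", "gapfill"]

#: default producibility threshold (objective units)
DEFAULT_MIN_OBJECTIVE = 1e-3


@dataclass(frozen=True)
class GapfillResult:
    """One minimal reaction set restoring the objective.

    Removing any single member drops the objective below the threshold
    again (minimality witness, verified before the result is returned).
    """

    added_reaction_ids: tuple[str, ...]
    restored_objective_value: float
    alternates: tuple[tuple[str, ...], ...] = field(default_factory=tuple)


def _extended_model(
    model: MetabolicModel, pool: Sequence[Reaction]
) -> tuple[MetabolicModel, list[str]]:
    existing = {r.id for r in model.reactions}
    added = [r for r in pool if r.id not in existing]
    met_ids = {m.id for m in model.metabolites}
    for r in added:
        for met_id in r.stoichiometry:
            if met_id not in met_ids:
                raise KeyError(
                    f"pool reaction {r.id!r} references metabolite {met_id!r} "
                    "absent from the model"
                )
    ext = build_model(
        model.metabolites,
        [r.copy() for r in model.reactions] + [r.copy() for r in added],
        genes=model.genes,
        objective_id=model.objective_id,
    )
    return ext, [r.id for r in added]


def gapfill(
    model: MetabolicModel,
    universal_reactions: Sequence[Reaction],
    objective_id: str | None = None,
    min_objective: float = DEFAULT_MIN_OBJECTIVE,
    max_solutions: int = 1,
) -> list[GapfillResult]:
    """Enumerate minimal universal-reaction sets restoring the objective.

    Returns up to ``max_solutions`` solutions of the first (smallest)
    cardinality found, each verified for the minimality witness.  If the
    input model already reaches ``min_objective`` a single empty result
    is returned.  Raises :class:`NoFillExistsError` when even the full
    pool cannot reach the threshold.
    """
    objective_id = objective_id or model.objective_id
    if not universal_reactions:
        raise ValueError("universal pool is empty")
    base = fba(model, objective_id)
    if base.ok and base.objective_value >= min_objective:
        return [GapfillResult((), base.objective_value)]

    ext, pool_ids = _extended_model(model, universal_reactions)
    if not pool_ids:
        raise NoFillExistsError("pool contains no reactions new to the model")
    full = fba(ext, objective_id)
    if not full.ok or full.objective_value < min_objective:
        raise NoFillExistsError(
            f"objective cannot reach {min_objective} even with the full pool"
        )

    S = stoichiometric_matrix(ext)
    m, n = S.shape
    k = len(pool_ids)
    pool_idx = [ext.reaction_index(rid) for rid in pool_ids]

    # variables: v (n continuous), y (k binary)
    nv = n + k
    integrality = np.concatenate([np.zeros(n), np.ones(k)])
    lb = np.array([r.lower_bound for r in ext.reactions] + [0.0] * k)
    ub = np.array([r.upper_bound for r in ext.reactions] + [1.0] * k)

    constraints = [LinearConstraint(_hstack_eq(S, n, k), np.zeros(m), np.zeros(m))]

    # indicator gating: lb_j * y_j <= v_j <= ub_j * y_j
    gate_rows, gate_lo, gate_hi = [], [], []
    for jj, j in enumerate(pool_idx):
        r = ext.reactions[j]
        row = np.zeros(nv)
        row[j] = 1.0
        row[n + jj] = -r.upper_bound
        gate_rows.append(row)
        gate_lo.append(-np.inf)
        gate_hi.append(0.0)
        row = np.zeros(nv)
        row[j] = 1.0
        row[n + jj] = -r.lower_bound
        gate_rows.append(row)
        gate_lo.append(0.0)
        gate_hi.append(np.inf)
    constraints.append(LinearConstraint(np.array(gate_rows), gate_lo, gate_hi))

    obj_row = np.zeros(nv)
    obj_row[ext.reaction_index(objective_id)] = 1.0
    constraints.append(LinearConstraint(obj_row, min_objective, np.inf))

    c = np.concatenate([np.zeros(n), np.ones(k)])
    cuts: list[LinearConstraint] = []
    solutions: list[tuple[str, ...]] = []
    best_card: int | None = None

    while len(solutions) < max_solutions:
        res = milp(
            c,
            constraints=constraints + cuts,
            integrality=integrality,
            bounds=OptBounds(lb, ub),
        )
        if res.status == 2:  # infeasible: enumeration exhausted
            break
        if not res.success:
            raise SolverError(f"MILP failed: {res.message}", status=res.status)
        y = res.x[n:]
        chosen = tuple(sorted(pool_ids[j] for j in range(k) if y[j] > 0.5))
        card = len(chosen)
        if best_card is None:
            best_card = card
        elif card > best_card:
            break  # only enumerate sets of minimal cardinality
        solutions.append(chosen)
        cut = np.zeros(nv)
        for j in range(k):
            if y[j] > 0.5:
                cut[n + j] = 1.0
        cuts.append(LinearConstraint(cut, -np.inf, card - 1))

    if not solutions:
        raise NoFillExistsError("MILP found no admissible reaction set")

    results = []
    pool_by_id = {r.id: r for r in universal_reactions}
    others = tuple(s for s in solutions[1:])
    for chosen in solutions:
        value = _restored_value(model, pool_by_id, chosen, objective_id)
        if value < min_objective:
            raise SolverError(
                f"gap-fill verification failed for {chosen}: objective {value}"
            )
        for dropped in chosen:
            sub = tuple(r for r in chosen if r != dropped)
            if _restored_value(model, pool_by_id, sub, objective_id) >= min_objective:
                raise SolverError(
                    f"gap-fill set {chosen} not minimal: {dropped} removable"
                )
        results.append(
            GapfillResult(chosen, value, alternates=others if chosen == solutions[0] else ())
        )
    return results


def _restored_value(model, pool_by_id, chosen, objective_id) -> float:
    trial, _ = _extended_model(model, [pool_by_id[rid] for rid in chosen])
    sol = fba(trial, objective_id)
    return sol.objective_value if sol.ok else -np.inf


def _hstack_eq(S: np.ndarray, n: int, k: int) -> np.ndarray:
    m = S.shape[0]
    return np.hstack([S, np.zeros((m, k))])
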