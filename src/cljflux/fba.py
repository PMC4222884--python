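"""Linear-programming engine: FBA, FVA, parsimonious FBA, deletions.

All solves go through scipy's HiGHS backend.  The flux polytope is
{v : S v = 0, lb <= v <= ub}; flux balance analysis maximizes (or
minimizes) one reaction's flux over it.  With the biomass drain as the
objective the optimal value is the specific growth rate in 1/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .errors import InfeasibleScenario, SolverError
from .model import MetabolicModel, stoichiometric_matrix

__all__ = [
    "Medium",
    "FluxSolution",
    "DeletionResult",
    "apply_medium",
    "fba",
    "fva",
    "parsimonious_solution",
    "single_gene_deletion",
    "knockout_genes",
    "carbon_exchange_balance",
]

#: A growth condition: exchange-reaction id -> (lower, upper) in mmol/gDW/h.
Medium = dict[str, tuple[float, float]]

#: Feasibility/optimality tolerance; growth below GROWTH_EPS is "no growth".
LP_TOL = 1e-9
GROWTH_EPS = 1e-9

_HIGHS_OPTS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-10,
}


@dataclass
class FluxSolution:
    """Result of one LP solve.

    ``status`` is ``"optimal"``, ``"infeasible"`` or ``"unbounded"``;
    fluxes are keyed by reaction id and only populated when optimal.
    """

    status: str
    objective_value: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass(frozen=True)
class DeletionResult:
    """Single-gene knockout outcome; growth_ratio = KO growth / WT growth."""

    gene: str
    status: str
    growth: float
    growth_ratio: float


def apply_medium(model: MetabolicModel, medium: Mapping[str, tuple[float, float]]) -> MetabolicModel:
    """Return a copy of the model with exchange bounds set by the medium.

    Exchanges absent from the medium are closed to uptake (lower bound 0)
    with secretion left open; named exchanges receive the given bounds.

    Raises ``KeyError`` if a medium key is not an exchange reaction.
    """
    out = model.copy()
    exchange_ids = {r.id for r in out.exchanges}
    for rxn_id in medium:
        if rxn_id not in exchange_ids:
            raise KeyError(f"{rxn_id!r} is not an exchange reaction of the model")
    for r in out.reactions:
        if not r.is_exchange:
            continue
        if r.id in medium:
            lo, hi = medium[r.id]
            out.set_bounds(r.id, lo, hi)
        else:
            out.set_bounds(r.id, 0.0, max(r.upper_bound, 0.0))
    return out


def _solve_lp(
    c: np.ndarray,
    A_eq: np.ndarray | None,
    b_eq: np.ndarray | None,
    bounds: Sequence[tuple[float, float]],
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options=_HIGHS_OPTS,
    )
    return res


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    direction: str = "max",
) -> FluxSolution:
    """Solve max/min of one reaction's flux over the steady-state polytope."""
    objective_id = objective_id or model.objective_id
    if objective_id is None:
        raise ValueError("no objective reaction specified")
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")

    S = stoichiometric_matrix(model)
    m, n = S.shape
    c = np.zeros(n)
    j = model.reaction_index(objective_id)
    c[j] = -1.0 if direction == "max" else 1.0
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]

    res = _solve_lp(c, S, np.zeros(m), bounds)
    status = _STATUS.get(res.status, "failed")
    if status in ("optimal",):
        fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
        obj = float(res.x[j])
        return FluxSolution("optimal", obj, fluxes)
    if status in ("infeasible", "unbounded"):
        return FluxSolution(status)
    raise SolverError(f"LP solver failed: {res.message}", status=res.status)


def fva(
    model: MetabolicModel,
    objective_fraction: float = 1.0,
    reactions: Iterable[str] | None = None,
    objective_id: str | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-reaction (min, max) flux subject to objective >= fraction * optimum.

    With ``objective_fraction`` 0 the ranges are the plain per-reaction
    min/max over the polytope.
    """
    objective_id = objective_id or model.objective_id
    S = stoichiometric_matrix(model)
    m, n = S.shape
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    b_eq = np.zeros(m)

    A_ub = b_ub = None
    if objective_fraction > 0:
        base = fba(model, objective_id)
        if not base.ok:
            raise InfeasibleScenario(
                f"FVA base problem is {base.status}; cannot constrain objective"
            )
        jobj = model.reaction_index(objective_id)
        row = np.zeros(n)
        row[jobj] = -1.0  # -v_obj <= -fraction * opt
        A_ub = row[None, :]
        b_ub = np.array([-objective_fraction * base.objective_value])

    targets = list(reactions) if reactions is not None else [r.id for r in model.reactions]
    out: dict[str, tuple[float, float]] = {}
    for rxn_id in targets:
        j = model.reaction_index(rxn_id)
        lohi = []
        for sign in (1.0, -1.0):
            c = np.zeros(n)
            c[j] = sign
            res = _solve_lp(c, S, b_eq, bounds, A_ub, b_ub)
            if res.status != 0:
                raise SolverError(
                    f"FVA subproblem for {rxn_id!r} returned {res.status}",
                    status=res.status,
                )
            lohi.append(float(res.x[j]))
        out[rxn_id] = (lohi[0], lohi[1])
    return out


def parsimonious_solution(
    model: MetabolicModel,
    objective_id: str | None = None,
    lexicographic: bool | None = None,
) -> FluxSolution:
    """FBA followed by minimization of total absolute flux at the optimum.

    Among alternate optima this selects the vector minimizing sum |v|
    (futile cycles carry zero flux).  An optional exact lexicographic
    refinement then minimizes each |v_j| in reverse-sorted reaction-id
    order, so that among equal-total optima the lexicographically
    earliest reactions retain the flux; it is enabled by default on
    models with <= 150 reactions, keeping ledger audits deterministic.
    """
    objective_id = objective_id or model.objective_id
    base = fba(model, objective_id)
    if not base.ok:
        return base

    S = stoichiometric_matrix(model)
    m, n = S.shape
    if lexicographic is None:
        lexicographic = n <= 150
    jobj = model.reaction_index(objective_id)

    # variables: [v (n), a (n)] with a >= |v|
    A_eq = np.hstack([S, np.zeros((m, n))])
    b_eq = np.zeros(m)
    # pin the objective at its optimum
    pin = np.zeros(2 * n)
    pin[jobj] = 1.0
    A_eq = np.vstack([A_eq, pin])
    b_eq = np.append(b_eq, base.objective_value)

    I = np.eye(n)
    A_ub = np.vstack(
        [np.hstack([I, -I]), np.hstack([-I, -I])]
    )  # v - a <= 0 ; -v - a <= 0
    b_ub = np.zeros(2 * n)

    vb = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    ab = [(0.0, max(abs(r.lower_bound), abs(r.upper_bound))) for r in model.reactions]
    bounds = vb + ab

    c = np.concatenate([np.zeros(n), np.ones(n)])
    res = _solve_lp(c, A_eq, b_eq, bounds, A_ub, b_ub)
    if res.status != 0:
        raise SolverError(f"pFBA stage-2 LP returned {res.status}", status=res.status)
    x = res.x

    if lexicographic:
        total = float(res.fun)
        slack = 1e-8
        row_total = np.concatenate([np.zeros(n), np.ones(n)])
        A_ub_l = np.vstack([A_ub, row_total[None, :]])
        b_ub_l = np.append(b_ub, total + slack)
        order = sorted(range(n), key=lambda j: model.reactions[j].id, reverse=True)
        for j in order:
            cj = np.zeros(2 * n)
            cj[n + j] = 1.0
            res_j = _solve_lp(cj, A_eq, b_eq, bounds, A_ub_l, b_ub_l)
            if res_j.status != 0:  # numerically tight; keep previous solution
                break
            x = res_j.x
            fix = np.zeros(2 * n)
            fix[n + j] = 1.0
            A_ub_l = np.vstack([A_ub_l, fix[None, :]])
            b_ub_l = np.append(b_ub_l, float(res_j.fun) + slack)

    fluxes = {r.id: float(v) for r, v in zip(model.reactions, x[:n])}
    return FluxSolution("optimal", float(x[jobj]), fluxes)


def knockout_genes(model: MetabolicModel, genes: Iterable[str]) -> MetabolicModel:
    """Copy of the model with all reactions inactivated by the knockout closed."""
    ko = set(genes)
    out = model.copy()
    for r in out.reactions:
        if not r.gpr.is_empty and not r.gpr.evaluate(ko):
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    return out


def single_gene_deletion(
    model: MetabolicModel, genes: Iterable[str] | None = None
) -> list[DeletionResult]:
    """Knock out each gene in turn, re-run FBA, report growth ratios.

    A gene absent from every GPR leaves growth unchanged (ratio 1).  A
    knockout that is infeasible or grows below tolerance reports 0.
    """
    wt = fba(model)
    if not wt.ok or wt.objective_value < GROWTH_EPS:
        raise InfeasibleScenario("wild-type model does not grow; deletion screen undefined")
    wt_growth = wt.objective_value

    results = []
    for g in genes if genes is not None else list(model.genes):
        affected = [
            r.id
            for r in model.reactions
            if not r.gpr.is_empty and g in r.gpr.genes() and not r.gpr.evaluate({g})
        ]
        if not affected:
            results.append(DeletionResult(g, "optimal", wt_growth, 1.0))
            continue
        ko_model = model.copy()
        for rxn_id in affected:
            ko_model.knock_out_reaction(rxn_id)
        sol = fba(ko_model)
        if not sol.ok or sol.objective_value < GROWTH_EPS:
            results.append(DeletionResult(g, sol.status, 0.0, 0.0))
        else:
            ratio = min(max(sol.objective_value / wt_growth, 0.0), 1.0 + 1e-9)
            results.append(DeletionResult(g, "optimal", sol.objective_value, ratio))
    return results


def carbon_exchange_balance(
    model: MetabolicModel,
    solution: FluxSolution,
    objective_carbon: float = 0.0,
) -> dict[str, float]:
    """Carbon bookkeeping for an optimal solution.

    Positive exchange flux exports carbon, negative imports it.  A lumped
    objective drain (biomass) removes ``objective_carbon`` mmol C per
    unit flux.  ``residual`` is (in) - (out) - (drain) and should vanish
    for any mass-consistent model.
    """
    carbon_in = carbon_out = 0.0
    for r in model.exchanges:
        (met_id,) = r.stoichiometry
        ncarbon = model.metabolite(met_id).formula.get("C", 0)
        v = solution.fluxes.get(r.id, 0.0)
        flux_c = v * ncarbon  # stoich coefficient is -1 by convention
        if flux_c > 0:
            carbon_out += flux_c
        else:
            carbon_in -= flux_c
    drain = 0.0
    if model.objective_id is not None:
        drain = objective_carbon * solution.fluxes.get(model.objective_id, 0.0)
    return {
        "carbon_in": carbon_in,
        "carbon_out": carbon_out,
        "objective_drain": drain,
        "residual": carbon_in - carbon_out - drain,
    }
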