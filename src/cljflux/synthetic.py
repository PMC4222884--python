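"""Synthetic benchmark networks with analytically known optima.

Small random stoichiometric networks — parallel source-to-sink chains
with random uptake caps — whose LP optimum is known by construction
(the sum of the caps).  Together with a brute-force vertex-enumeration
oracle they make every engine property testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np

from .errors import UnboundedError
from .model import MetabolicModel, Metabolite, Reaction, build_model, stoichiometric_matrix

__all__ = ["SyntheticNetwork", "random_feasible_network", "brute_force_lp_oracle"]


@dataclass(frozen=True)
class SyntheticNetwork:
    """A generated model plus its planted optimum and the seed used."""

    model: MetabolicModel
    planted_optimum: float
    seed: int


def random_feasible_network(
    n_paths: int, path_length: int, seed: int = 0
) -> SyntheticNetwork:
    """Parallel source->sink chains with random positive uptake caps.

    Each of the ``n_paths`` chains has its own source exchange with a
    random uptake cap drawn from U(0.5, 5); all chains feed one shared
    sink whose exchange is the objective, so the optimum equals the sum
    of the caps.  Reproducible for a given seed.
    """
    if n_paths < 1 or path_length < 1:
        raise ValueError("n_paths and path_length must be >= 1")
    rng = np.random.default_rng(seed)
    caps = rng.uniform(0.5, 5.0, size=n_paths)

    mets: list[Metabolite] = [Metabolite(id="sink_e", compartment="e", formula={"C": 1})]
    rxns: list[Reaction] = []
    for i in range(n_paths):
        chain = [f"src{i}_e"] + [f"m{i}_{s}_c" for s in range(path_length - 1)] + ["sink_e"]
        mets.append(Metabolite(id=chain[0], compartment="e", formula={"C": 1}))
        for s in range(path_length - 1):
            mets.append(Metabolite(id=chain[s + 1], compartment="c", formula={"C": 1}))
        rxns.append(
            Reaction(id=f"EX_src{i}", stoichiometry={chain[0]: -1.0},
                     lower_bound=-float(caps[i]), upper_bound=0.0, is_exchange=True)
        )
        for s in range(path_length):
            rxns.append(
                Reaction(id=f"P{i}_{s}", stoichiometry={chain[s]: -1.0, chain[s + 1]: 1.0},
                         lower_bound=0.0, upper_bound=1000.0)
            )
    rxns.append(
        Reaction(id="EX_sink", stoichiometry={"sink_e": -1.0},
                 lower_bound=0.0, upper_bound=1000.0, is_exchange=True)
    )
    model = build_model(mets, rxns, objective_id="EX_sink")
    return SyntheticNetwork(model, float(caps.sum()), seed)


def brute_force_lp_oracle(
    model: MetabolicModel, objective_id: str | None = None, big: float = 1e6
) -> float:
    """Exact LP optimum by enumerating basic feasible solutions.

    Every vertex of {S v = 0, lb <= v <= ub} has the non-fixed variables
    determined by the fixed-at-bound ones through a full-column-rank
    subsystem; all bound-fixing patterns are enumerated (3^n worst case),
    so the instance must be small (<= 10 reactions).  Infinite bounds are
    clamped at ``big`` and the search repeated at 2x ``big``; an optimum
    that scales with the clamp means the LP is unbounded.

    This routine deliberately shares no code with the simplex-based
    engine; it is the independent oracle the engine is tested against.
    """
    objective_id = objective_id or model.objective_id
    n = len(model.reactions)
    if n > 10:
        raise ValueError("oracle limited to networks with <= 10 reactions")

    lbs = np.array([r.lower_bound for r in model.reactions])
    ubs = np.array([r.upper_bound for r in model.reactions])
    has_inf = bool(np.any(np.isinf(lbs)) or np.any(np.isinf(ubs)))
    v1 = _enumerate_optimum(model, objective_id, np.clip(lbs, -big, big), np.clip(ubs, -big, big))
    if not has_inf:
        if v1 is None:
            raise ValueError("no feasible vertex found")
        return v1
    v2 = _enumerate_optimum(
        model, objective_id, np.clip(lbs, -2 * big, 2 * big), np.clip(ubs, -2 * big, 2 * big)
    )
    if v1 is None or v2 is None:
        raise ValueError("no feasible vertex found")
    if abs(v2 - v1) > 1e-6 * max(1.0, abs(v1)):
        raise UnboundedError("objective grows with the bound clamp; LP unbounded")
    return v1


def _enumerate_optimum(model, objective_id, lbs, ubs) -> float | None:
    S = stoichiometric_matrix(model)
    # drop all-zero rows (metabolites untouched by any reaction)
    S = S[np.any(S != 0, axis=1)]
    n = S.shape[1]
    jobj = model.reaction_index(objective_id)

    best: float | None = None
    idx = list(range(n))
    for kfree in range(n + 1):
        for free in combinations(idx, kfree):
            Sf = S[:, list(free)]
            if kfree and np.linalg.matrix_rank(Sf) < kfree:
                continue  # solution not uniquely determined; a smaller free set covers it
            fixed = [j for j in idx if j not in free]
            choices = []
            for j in fixed:
                if lbs[j] == ubs[j]:
                    choices.append((lbs[j],))
                else:
                    choices.append((lbs[j], ubs[j]))
            for assign in product(*choices):
                v = np.empty(n)
                for j, val in zip(fixed, assign):
                    v[j] = val
                if kfree:
                    rhs = -S[:, fixed] @ np.array(assign)
                    sol, res, rank, _ = np.linalg.lstsq(Sf, rhs, rcond=None)
                    v[list(free)] = sol
                if np.max(np.abs(S @ v)) > 1e-7:
                    continue
                if np.any(v < lbs - 1e-9) or np.any(v > ubs + 1e-9):
                    continue
                val = float(v[jobj])
                if best is None or val > best:
                    best = val
    return best
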