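"""Core domain types for compartmented metabolic networks.

A :class:`MetabolicModel` is a validated container of metabolites,
reactions and genes; its stoichiometric matrix S (rows = metabolites,
columns = reactions) is the object all flux computations operate on.
Conventions follow the constraint-based modeling field: negative
stoichiometric coefficients denote consumption, exchange reactions are
boundary pseudo-reactions touching a single extracellular metabolite,
and negative exchange flux means uptake.
"""

from __future__ import annotations

import copy as _copy
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DanglingReferenceError, DuplicateIdError
from .gpr import GPR, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "BalanceResult",
    "build_model",
    "stoichiometric_matrix",
    "check_balance",
    "evaluate_gpr",
]

#: Elements tracked in formulas / balance audits.
ALLOWED_ELEMENTS = ("C", "H", "O", "N", "P", "S", "Fe")

#: Compartments: c = cytosol, e = extracellular.
COMPARTMENTS = ("c", "e")


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in a fixed compartment.

    ``formula`` maps element symbols to non-negative counts; an empty
    formula marks a lumped species (biomass, carrier proteins) that is
    exempt from elemental bookkeeping.
    """

    id: str
    name: str = ""
    formula: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0
    compartment: str = "c"

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"metabolite {self.id!r}: compartment {self.compartment!r} "
                f"not in {COMPARTMENTS}"
            )
        for el, n in self.formula.items():
            if el not in ALLOWED_ELEMENTS:
                raise ValueError(f"metabolite {self.id!r}: element {el!r} not allowed")
            if n < 0:
                raise ValueError(f"metabolite {self.id!r}: negative count for {el}")

    @property
    def is_lumped(self) -> bool:
        return not self.formula


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds in mmol/gDW/h.

    ``stoichiometry`` maps metabolite id -> coefficient (negative =
    consumed).  ``is_exchange`` marks boundary pseudo-reactions;
    ``balance_exempt`` marks lumped drains (biomass) that intentionally
    do not balance.
    """

    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gpr: GPR = field(default_factory=GPR)
    subsystem: str = ""
    name: str = ""
    is_exchange: bool = False
    balance_exempt: bool = False

    def __post_init__(self):
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        r = replace(self)
        r.stoichiometry = dict(self.stoichiometry)
        return r


class MetabolicModel:
    """Validated metabolic network; build via :func:`build_model`."""

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        genes: Sequence[str],
        objective_id: str | None,
    ):
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self.genes: list[str] = list(genes)
        self.objective_id = objective_id
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- lookup -----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.metabolites), len(self.reactions))

    # -- mutation helpers (used by the engine on copies) ------------------
    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            self.metabolites,
            [r.copy() for r in self.reactions],
            self.genes,
            self.objective_id,
        )

    def set_bounds(self, rxn_id: str, lower: float, upper: float) -> None:
        r = self.reaction(rxn_id)
        if lower > upper:
            raise ValueError(f"{rxn_id}: lower {lower} > upper {upper}")
        r.lower_bound = lower
        r.upper_bound = upper

    def knock_out_reaction(self, rxn_id: str) -> None:
        self.set_bounds(rxn_id, 0.0, 0.0)

    def without_reactions(self, rxn_ids: Iterable[str]) -> "MetabolicModel":
        """New model with the given reactions removed entirely."""
        drop = set(rxn_ids)
        missing = drop - set(self._rxn_index)
        if missing:
            raise DanglingReferenceError(f"cannot remove unknown reactions {sorted(missing)}")
        objective = self.objective_id if self.objective_id not in drop else None
        return MetabolicModel(
            self.metabolites,
            [r.copy() for r in self.reactions if r.id not in drop],
            self.genes,
            objective,
        )

    def add_reaction(self, reaction: Reaction) -> None:
        if reaction.id in self._rxn_index:
            raise DuplicateIdError(f"reaction id {reaction.id!r} already present")
        for met_id in reaction.stoichiometry:
            if met_id not in self._met_index:
                raise DanglingReferenceError(
                    f"reaction {reaction.id!r} references unknown metabolite {met_id!r}"
                )
        self.reactions.append(reaction)
        self._rxn_index[reaction.id] = len(self.reactions) - 1

    def __repr__(self) -> str:  # pragma: no cover
        m, n = self.shape
        return f"<MetabolicModel {m} metabolites x {n} reactions, {len(self.genes)} genes>"


def build_model(
    metabolites: Sequence[Metabolite],
    reactions: Sequence[Reaction],
    genes: Sequence[str] | None = None,
    objective_id: str | None = None,
) -> MetabolicModel:
    """Assemble and validate a model.

    Checks id uniqueness (within and across namespaces relevant to each),
    resolves every stoichiometric and GPR cross-reference, and enforces
    the exchange-reaction convention (exactly one metabolite, in the
    extracellular compartment).

    Raises
    ------
    DuplicateIdError
        if any metabolite/reaction/gene id repeats.
    DanglingReferenceError
        if a reaction cites an unknown metabolite or gene, or the
        objective id does not exist.
    """
    genes = list(genes) if genes is not None else []

    met_ids = [m.id for m in metabolites]
    rxn_ids = [r.id for r in reactions]
    for label, ids in (("metabolite", met_ids), ("reaction", rxn_ids), ("gene", genes)):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise DuplicateIdError(f"duplicate {label} id {i!r}")
            seen.add(i)

    met_set = set(met_ids)
    gene_set = set(genes)
    # genes referenced only in GPRs are accepted and appended to the list
    implicit_genes: list[str] = []
    for r in reactions:
        for met_id in r.stoichiometry:
            if met_id not in met_set:
                raise DanglingReferenceError(
                    f"reaction {r.id!r} references unknown metabolite {met_id!r}"
                )
        for g in sorted(r.gpr.genes()):
            if g not in gene_set:
                implicit_genes.append(g)
                gene_set.add(g)

    met_by_id = {m.id: m for m in metabolites}
    for r in reactions:
        if r.is_exchange:
            if len(r.stoichiometry) != 1:
                raise ValueError(
                    f"exchange {r.id!r} must touch exactly one metabolite"
                )
            (met_id,) = r.stoichiometry
            if met_by_id[met_id].compartment != "e":
                raise ValueError(
                    f"exchange {r.id!r} metabolite {met_id!r} must be extracellular"
                )

    if objective_id is not None and objective_id not in set(rxn_ids):
        raise DanglingReferenceError(f"objective reaction {objective_id!r} not in model")

    return MetabolicModel(metabolites, reactions, genes + implicit_genes, objective_id)


def stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense S with rows = metabolites, columns = reactions (model order)."""
    m, n = model.shape
    S = np.zeros((m, n))
    for j, r in enumerate(model.reactions):
        for met_id, coeff in r.stoichiometry.items():
            S[model._met_index[met_id], j] = coeff
    return S


@dataclass(frozen=True)
class BalanceResult:
    """Outcome of an elemental/charge audit of one reaction.

    ``status`` is ``"balanced"``, ``"unbalanced"``, ``"exempt"`` (exchange
    or flagged lumped drain) or ``"skipped"`` (a participant lacks a
    formula).  ``imbalance`` maps element -> net atom count plus the key
    ``"charge"``; an all-zero map means balanced.
    """

    status: str
    imbalance: dict[str, float] = field(default_factory=dict)

    @property
    def is_violation(self) -> bool:
        return self.status == "unbalanced"


def check_balance(
    reaction: Reaction, metabolite_table: Mapping[str, Metabolite]
) -> BalanceResult:
    """Net per-element and charge bookkeeping for one reaction.

    Exchange reactions and flagged lumped drains are exempt by
    convention.  If any participating metabolite has an empty formula the
    reaction cannot be audited and is skipped with a warning.
    """
    if reaction.is_exchange or reaction.balance_exempt:
        return BalanceResult("exempt")

    lumped = [
        met_id
        for met_id in reaction.stoichiometry
        if metabolite_table[met_id].is_lumped
    ]
    if lumped:
        warnings.warn(
            f"reaction {reaction.id!r}: skipping balance check, lumped "
            f"species without formula: {sorted(lumped)}",
            stacklevel=2,
        )
        return BalanceResult("skipped")

    net: dict[str, float] = {}
    charge = 0.0
    for met_id, coeff in reaction.stoichiometry.items():
        met = metabolite_table[met_id]
        for el, count in met.formula.items():
            net[el] = net.get(el, 0.0) + coeff * count
        charge += coeff * met.charge
    net = {el: v for el, v in net.items() if abs(v) > 1e-9}
    if abs(charge) > 1e-9:
        net["charge"] = charge
    status = "balanced" if not net else "unbalanced"
    return BalanceResult(status, net)


def evaluate_gpr(gpr: GPR | str, knocked_out_genes: Iterable[str] = ()) -> bool:
    """Whether a reaction stays active given the knocked-out gene set."""
    if isinstance(gpr, str):
        gpr = parse_gpr(gpr)
    return gpr.evaluate(knocked_out_genes)


def formula_from_string(s: str) -> dict[str, int]:
    """Parse a Hill-notation formula string like ``"C21H26N7O17P3"``."""
    out: dict[str, int] = {}
    i = 0
    while i < len(s):
        if not s[i].isalpha() or not s[i].isupper():
            raise ValueError(f"bad formula {s!r} at position {i}")
        el = s[i]
        i += 1
        while i < len(s) and s[i].islower():
            el += s[i]
            i += 1
        num = ""
        while i < len(s) and s[i].isdigit():
            num += s[i]
            i += 1
        out[el] = out.get(el, 0) + (int(num) if num else 1)
    return out


def formula_to_string(formula: Mapping[str, int]) -> str:
    """Hill-ish deterministic rendering (C, H, then alphabetical)."""
    order = ["C", "H"] + sorted(el for el in formula if el not in ("C", "H"))
    parts = []
    for el in order:
        n = formula.get(el, 0)
        if n == 0:
            continue
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def _deepcopy_model(model: MetabolicModel) -> MetabolicModel:  # pragma: no cover
    return _copy.deepcopy(model)
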